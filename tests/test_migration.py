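"""Interface detection, depth scoring, scratch areas and closure kinetics."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from nucmorph import migration as mig
from nucmorph import synthetic as syn


def make_stack(cell, tissue, z_step=2.0, px=1.0):
    return mig.MigrationStack(
        cell_channel=cell, tissue_channel=tissue, z_step_um=z_step, px_size_um=px
    )


def match_to_truth(cells, truth):
    """Pair detected cells with truth records by xy proximity."""
    td = np.array(truth.cell_xyz_um)
    md = np.array([[c.x_um, c.y_um] for c in cells])
    d, idx = cKDTree(td[:, :2]).query(md)
    assert d.max() < 3.0
    assert len(set(idx)) == len(idx)
    return idx


class TestDetectInterface:
    def test_step_profile(self):
        tissue = np.zeros((20, 32, 32))
        tissue[10:] = 1.0
        z = mig.detect_interface(tissue, 2.0)
        assert z == pytest.approx(20.0, abs=1.0)  # within half a z-step

    def test_generator_stack_within_one_step(self, migration_fixture):
        _, tissue, truth = migration_fixture
        z = mig.detect_interface(tissue, truth.extra["z_step_um"])
        assert abs(z - truth.interface_z_um) <= truth.extra["z_step_um"]

    def test_all_zero_tissue_rejected(self):
        with pytest.raises(ValueError):
            mig.detect_interface(np.zeros((10, 16, 16)), 2.0)

    def test_too_few_planes_rejected(self):
        with pytest.raises(ValueError):
            mig.detect_interface(np.zeros((2, 16, 16)), 2.0)


class TestScoreCells:
    def test_blob_at_interface_not_embedded(self):
        cell, tissue, truth = syn.gen_migration_stack(
            n_cells=1, depth_distribution=("uniform", -0.4, 0.4), seed=4,
            margin_guard_um=0.0,
        )
        stack = make_stack(cell, tissue)
        cells = mig.score_cells(stack, embed_margin_um=5.0)
        assert len(cells) == 1
        assert abs(cells[0].depth_um) < 2.5
        assert not cells[0].embedded

    def test_deep_blob_embedded(self):
        cell, tissue, truth = syn.gen_migration_stack(
            n_cells=1, depth_distribution=("uniform", 19.0, 21.0), seed=4
        )
        stack = make_stack(cell, tissue)
        cells = mig.score_cells(stack, embed_margin_um=5.0)
        assert len(cells) == 1
        assert cells[0].depth_um == pytest.approx(20.0, abs=2.5)
        assert cells[0].embedded

    def test_truth_recovery_seed11(self, migration_fixture):
        cell, tissue, truth = migration_fixture
        stack = make_stack(cell, tissue)
        cells = mig.score_cells(stack, embed_margin_um=5.0)
        assert len(cells) == 40
        idx = match_to_truth(cells, truth)
        err = np.array(
            [c.depth_um - truth.true_depths_um[i] for c, i in zip(cells, idx)]
        )
        assert np.sqrt((err**2).mean()) < 2.0  # < 1 z-step
        assert all(c.embedded == truth.embedded[i] for c, i in zip(cells, idx))

    def test_depths_negate_when_stack_flipped(self, migration_fixture):
        cell, tissue, _ = migration_fixture
        fwd = mig.score_cells(make_stack(cell, tissue), embed_margin_um=5.0)
        rev = mig.score_cells(
            make_stack(cell[::-1], tissue[::-1]), embed_margin_um=5.0
        )
        a = sorted(c.depth_um for c in fwd)
        b = sorted(-c.depth_um for c in rev)
        assert np.allclose(a, b, atol=1.0)

    def test_xy_translation_invariance(self, migration_fixture):
        cell, tissue, _ = migration_fixture
        c1 = mig.score_cells(make_stack(cell, tissue), embed_margin_um=5.0)
        c2 = mig.score_cells(
            make_stack(np.roll(cell, 7, axis=2), np.roll(tissue, 7, axis=2)),
            embed_margin_um=5.0,
        )
        assert mig.percent_migrated(c1) == mig.percent_migrated(c2)


class TestPercentMigratedAndCumFreq:
    def test_fraction_arithmetic(self):
        cells = [
            mig.CellRecord(0, 0, 0, d, d >= 5)
            for d in [10.0] * 3 + [0.0] * 7
        ]
        assert mig.percent_migrated(cells) == 30.0
        none = [mig.CellRecord(0, 0, 0, 0.0, False) for _ in range(4)]
        assert mig.percent_migrated(none) == 0.0
        with pytest.raises(ValueError):
            mig.percent_migrated([])

    def test_constructed_30_percent(self, migration_fixture):
        cell, tissue, truth = migration_fixture
        cells = mig.score_cells(make_stack(cell, tissue), embed_margin_um=5.0)
        assert mig.percent_migrated(cells) == 30.0

    def test_cumulative_curve(self):
        edges, pct = mig.cumulative_frequency(
            np.array([0.0, 10, 20, 30]), np.array([15.0])
        )
        assert pct[0] == 50.0
        assert pct[-1] == 100.0
        e2, p2 = mig.cumulative_frequency(np.array([7.0]), np.array([0.0, 10.0]))
        assert (p2 == [0.0, 100.0]).all()
        assert np.all(np.diff(p2) >= 0)
        with pytest.raises(ValueError):
            mig.cumulative_frequency(np.array([]), np.array([1.0]))

    def test_curve_always_ends_at_100(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            depths = rng.normal(10, 8, size=rng.integers(1, 50))
            _, pct = mig.cumulative_frequency(depths, np.linspace(-10, 10, 5))
            assert pct[-1] == 100.0


class TestMeanDepthShiftRecovery:
    def test_distribution_shift_recovered(self):
        # the measurement property behind a treated-vs-control depth
        # comparison: a true shift in mean depth is recovered within 1 z-step
        delta = 6.0
        means_a, means_b = [], []
        for seed in range(10):
            ca, ta, _ = syn.gen_migration_stack(
                n_cells=15, depth_distribution=("normal", 8.0, 4.0), seed=seed
            )
            cb, tb, _ = syn.gen_migration_stack(
                n_cells=15, depth_distribution=("normal", 8.0 + delta, 4.0),
                seed=100 + seed,
            )
            da = [c.depth_um for c in mig.score_cells(make_stack(ca, ta))]
            db = [c.depth_um for c in mig.score_cells(make_stack(cb, tb))]
            means_a.append(np.mean(da))
            means_b.append(np.mean(db))
        measured = np.mean(means_b) - np.mean(means_a)
        assert measured == pytest.approx(delta, abs=2.0)


class TestScratch:
    def test_confluent_frame_zero(self):
        conf = np.random.default_rng(1).uniform(0.3, 1.0, (200, 256))
        area, flag = mig.scratch_area(conf)
        assert area == 0.0 and flag

    def test_generator_frame_within_2pct(self):
        frames, truth = syn.gen_scratch_series(
            frame_shape=(500, 512), initial_width_px=100, n_frames=1, seed=0
        )
        area, flag = mig.scratch_area(frames[0])
        assert not flag
        assert area == pytest.approx(50000, rel=0.02)

    def test_rotation_symmetry(self):
        frames, _ = syn.gen_scratch_series(n_frames=1, seed=3)
        a, _ = mig.scratch_area(frames[0])
        b, _ = mig.scratch_area(frames[0][::-1, ::-1])
        assert a == b

    def test_series_truth_tracking(self):
        frames, truth = syn.gen_scratch_series(
            frame_shape=(400, 512), initial_width_px=120,
            closure_px_per_frame=30, n_frames=4, seed=2,
        )
        for f, t in zip(frames, truth.true_scratch_area_px):
            area, flag = mig.scratch_area(f)
            if t == 0:
                assert area == 0.0
            else:
                assert area == pytest.approx(t, rel=0.02)


class TestClosureRate:
    def test_arithmetic_case(self):
        s = mig.ScratchSeries(
            times_h=[0, 4, 8, 12], areas_px2=[100, 75, 50, 25]
        )
        assert mig.closure_rate(s) == pytest.approx(-6.25)

    def test_constant_area_zero_rate(self):
        s = mig.ScratchSeries(times_h=[0, 4, 8], areas_px2=[50, 50, 50])
        assert mig.closure_rate(s) == pytest.approx(0.0, abs=1e-9)

    def test_post_closure_frames_excluded(self):
        s = mig.ScratchSeries(
            times_h=[0, 4, 8, 12, 16], areas_px2=[100, 50, 0, 0, 0]
        )
        assert mig.closure_rate(s) == pytest.approx(-12.5)

    def test_generator_series_slope_within_5pct(self):
        frames, truth = syn.gen_scratch_series(
            frame_shape=(500, 512), initial_width_px=100,
            closure_px_per_frame=25, n_frames=5, seed=0,
        )
        times = np.arange(5) * 4.0
        areas = np.array([mig.scratch_area(f)[0] for f in frames])
        rate = mig.closure_rate(mig.ScratchSeries(times_h=times, areas_px2=areas))
        true_rate = -25 * 500 / 4.0
        assert rate == pytest.approx(true_rate, rel=0.05)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            mig.closure_rate(
                mig.ScratchSeries(times_h=[0, 4], areas_px2=[100, 0])
            )
        with pytest.raises(ValueError):
            mig.ScratchSeries(times_h=[0, 0], areas_px2=[1, 1])
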