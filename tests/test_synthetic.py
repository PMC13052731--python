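"""Generator contracts: determinism, truth completeness, knob monotonicity."""

import numpy as np
import pytest

from nucmorph import synthetic as syn


class TestNucleusField:
    def test_empty_field(self):
        img, truth = syn.gen_nucleus_field(syn.NucleusFieldSpec(n_nuclei=0))
        assert img.sum() == 0
        assert truth.centroids == [] and truth.masks() == []

    def test_deterministic_under_seed(self):
        spec = syn.NucleusFieldSpec(seed=42, n_nuclei=10, noise_sd=0.02)
        img_a, truth_a = syn.gen_nucleus_field(spec)
        img_b, truth_b = syn.gen_nucleus_field(spec)
        assert np.array_equal(img_a, img_b)
        assert np.array_equal(truth_a.label_map, truth_b.label_map)

    def test_truth_completeness(self, condensed_field):
        img, truth = condensed_field
        assert len(truth.centroids) == 25
        assert truth.label_map.max() == 25
        # every label appears exactly once and matches its centroid
        for k, (r, c) in enumerate(truth.centroids, start=1):
            mask = truth.label_map == k
            assert mask.any()
            cr, cc = np.argwhere(mask).mean(axis=0)
            assert abs(cr - r) < 3 and abs(cc - c) < 3

    def test_nuclei_nonoverlapping_and_inside_frame(self, condensed_field):
        img, truth = condensed_field
        masks = truth.masks()
        total = sum(m.sum() for m in masks)
        assert total == np.count_nonzero(truth.label_map)  # disjoint
        border = np.zeros_like(truth.label_map, dtype=bool)
        border[0] = border[-1] = True
        border[:, 0] = border[:, -1] = True
        assert not (truth.label_map[border] > 0).any()

    def test_condensation_controls_variance(self, condensed_field, decondensed_field):
        img1, truth = condensed_field
        img0, _ = decondensed_field
        v1 = np.mean([img1[m].var() for m in truth.masks()])
        v0 = np.mean([img0[m].var() for m in truth.masks()])
        assert v1 > v0

    def test_condensation_monotonic_over_knob(self):
        variances = []
        for c in [0.0, 0.25, 0.5, 0.75, 1.0]:
            spec = syn.NucleusFieldSpec(seed=7, n_nuclei=15, condensation=c)
            img, truth = syn.gen_nucleus_field(spec)
            variances.append(np.mean([img[m].var() for m in truth.masks()]))
        assert all(b > a for a, b in zip(variances, variances[1:]))

    def test_decondensed_interior_uniform(self, decondensed_field):
        img, truth = decondensed_field
        for m in truth.masks()[:5]:
            assert img[m].std() < 1e-9

    def test_placement_error_when_frame_too_small(self):
        spec = syn.NucleusFieldSpec(
            image_shape=(64, 64), n_nuclei=50, radius_px=10
        )
        with pytest.raises(syn.PlacementError):
            syn.gen_nucleus_field(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            syn.NucleusFieldSpec(condensation=1.5)
        with pytest.raises(ValueError):
            syn.NucleusFieldSpec(n_nuclei=-1)
        with pytest.raises(ValueError):
            syn.NucleusFieldSpec(radius_px=2)


class TestStrainSeries:
    def test_zero_strain_is_identity(self):
        spec = syn.NucleusFieldSpec(seed=3, n_nuclei=5)
        base, _ = syn.gen_nucleus_field(spec)
        images, truths = syn.gen_strain_series(spec, [0])
        assert np.array_equal(images[0], base)

    def test_circle_area_preserving_nar(self):
        # axial stretch 1.15 with transverse contraction 1/1.15 -> NAR 1.3225
        spec = syn.NucleusFieldSpec(
            seed=3, n_nuclei=4, axis_ratio_range=(1.0, 1.0)
        )
        _, truths = syn.gen_strain_series(spec, [0, 0.15])
        assert truths[1].true_nar == pytest.approx([1.15**2] * 4, abs=1e-9)

    def test_circle_no_contraction_nar(self):
        spec = syn.NucleusFieldSpec(
            seed=3, n_nuclei=4, axis_ratio_range=(1.0, 1.0)
        )
        _, truths = syn.gen_strain_series(
            spec, [0, 0.15], transverse_contraction=False
        )
        assert truths[1].true_nar == pytest.approx([1.15] * 4, abs=1e-9)

    def test_negative_or_unsorted_strains_rejected(self):
        spec = syn.NucleusFieldSpec(seed=3, n_nuclei=2)
        with pytest.raises(ValueError):
            syn.gen_strain_series(spec, [0, -0.05])
        with pytest.raises(ValueError):
            syn.gen_strain_series(spec, [0, 0.1, 0.05])
        with pytest.raises(ValueError):
            syn.gen_strain_series(spec, [0.03, 0.06])

    def test_truth_per_frame(self):
        spec = syn.NucleusFieldSpec(seed=3, n_nuclei=6)
        strains = [0, 0.06, 0.12]
        images, truths = syn.gen_strain_series(spec, strains)
        assert len(images) == len(truths) == 3
        for t in truths:
            assert len(t.true_nar) == 6 and len(t.centroids) == 6


class TestMigrationStack:
    def test_surface_cells_not_embedded(self):
        cell, tissue, truth = syn.gen_migration_stack(
            n_cells=5, depth_distribution=("uniform", -1.0, 1.0), seed=1,
            margin_guard_um=0.0,
        )
        assert not any(truth.embedded)

    def test_deep_cells_embedded(self):
        cell, tissue, truth = syn.gen_migration_stack(
            n_cells=5, depth_distribution=("uniform", 18.0, 22.0), seed=1
        )
        assert all(truth.embedded)
        assert all(d >= 5.0 for d in truth.true_depths_um)

    def test_forced_embedded_fraction(self, migration_fixture):
        _, _, truth = migration_fixture
        assert sum(truth.embedded) == 12
        assert len(truth.embedded) == 40

    def test_tissue_occupies_below_interface(self, migration_fixture):
        _, tissue, truth = migration_fixture
        z_step = truth.extra["z_step_um"]
        k_iface = int(np.ceil(truth.interface_z_um / z_step))
        assert tissue[k_iface:].min() > 0
        assert tissue[:k_iface].max() == 0

    def test_bad_z_step_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_migration_stack(n_cells=1, z_step_um=0)


class TestScratchSeries:
    def test_no_closure_constant_area(self):
        _, truth = syn.gen_scratch_series(
            closure_px_per_frame=0, n_frames=3, seed=0
        )
        assert len(set(truth.true_scratch_area_px)) == 1

    def test_linear_closure_areas(self):
        _, truth = syn.gen_scratch_series(
            frame_shape=(500, 512), initial_width_px=100,
            closure_px_per_frame=25, n_frames=5, seed=0,
        )
        assert truth.true_scratch_area_px == [50000, 37500 + 500, 25000, 12500 - 500, 0]
        # widths 100, 76, 50, 24, 0 after centre-rounding; frame 0 exact
        assert truth.true_scratch_area_px[0] == 100 * 500

    def test_width_must_fit_frame(self):
        with pytest.raises(ValueError):
            syn.gen_scratch_series(frame_shape=(100, 80), initial_width_px=80)


class TestDeTable:
    def test_no_effects_empty_truth(self):
        _, truth = syn.gen_de_table(n_genes=50, frac_de=0.0, seed=1)
        assert truth.true_de_genes == []

    def test_truth_count_matches_fraction(self):
        table, truth = syn.gen_de_table(n_genes=1000, frac_de=0.1, seed=3)
        assert len(truth.true_de_genes) == 100
        assert len(table) == 1000
        assert table["gene_id"].is_unique

    def test_effect_and_null_separation(self):
        table, truth = syn.gen_de_table(n_genes=500, frac_de=0.2, seed=9)
        de_mask = table["gene_id"].isin(truth.true_de_genes)
        assert (table.loc[de_mask, "padj"] < 0.05).all()
        assert (table.loc[de_mask, "log2fc"].abs() > 1).all()
        assert (table.loc[~de_mask, "padj"] >= 0.05).all()
        assert (table.loc[~de_mask, "log2fc"].abs() < 1).all()
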