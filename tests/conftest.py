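import numpy as np
import pytest

from nucmorph import synthetic as syn


@pytest.fixture(scope="session")
def condensed_field():
    """25 well-separated condensed nuclei (seed 7) with truth."""
    spec = syn.NucleusFieldSpec(seed=7, n_nuclei=25, condensation=1.0)
    return syn.gen_nucleus_field(spec)


@pytest.fixture(scope="session")
def decondensed_field():
    """Same geometry as condensed_field but fully decondensed."""
    spec = syn.NucleusFieldSpec(seed=7, n_nuclei=25, condensation=0.0)
    return syn.gen_nucleus_field(spec)


@pytest.fixture(scope="session")
def migration_fixture():
    """Seed-11 stack: 40 cells, 12 forced embedded (percent migrated 30%)."""
    cell, tissue, truth = syn.gen_migration_stack(
        n_cells=40, seed=11, n_embedded=12
    )
    return cell, tissue, truth


def disc_mask(shape, centre, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2


def ellipse_mask(shape, centre, a, b, theta=0.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr, dc = rr - centre[0], cc - centre[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0
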