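import numpy as np
import pytest
from hypothesis import settings

from protrefine import fixtures

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def helix30():
    return fixtures.make_helix(30)


@pytest.fixture
def helix_axis():
    """Unit vector along the synthetic helix axis (direct geometry)."""
    cas = np.array([r.atom("CA").coords for r in fixtures.make_helix(60).chain()])
    axis = cas[-1] - cas[0]
    return axis / np.linalg.norm(axis)


@pytest.fixture
def two_lobe_model(helix_axis):
    """Two confident lobes, a pLDDT-50 linker, lobes pulled within 10 A.

    The shift of the second lobe along the helix axis keeps the lobes
    geometrically attached, so only the window-average criterion removes
    residues.
    """
    shift = tuple(-5.0 * helix_axis)
    spec = fixtures.FixtureSpec(
        n_residues=60,
        plddt_profile=fixtures.profile_two_lobe_low_linker(),
        segment_offsets=[((34, 59), shift)],
    )
    return fixtures.make_trim_fixture(spec)


@pytest.fixture
def donor_pair():
    return fixtures.make_donor_pair(n_residues=40)
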