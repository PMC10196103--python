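import numpy as np
import pytest

from cranioqst import phantom as ph


@pytest.fixture(scope="session")
def archetype_phantoms():
    """One noise-free-seeded phantom per archetype on the default grid."""
    out = {}
    for t in "QST":
        spec = ph.archetype_spec(t, seed=123)
        out[t] = ph.generate_phantom(spec) + (spec,)
    return out


@pytest.fixture(scope="session")
def desk_cohort():
    """Small jittered cohort on the coarse 64x64 grid for network tests."""
    return ph.generate_cohort(
        12, mixture=(1 / 3, 1 / 3, 1 / 3), seed=42,
        grid_shape=ph.DESK_GRID_SHAPE, spacing=ph.DESK_SPACING,
    )
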