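import numpy as np
import pytest

from lvcoreg.phantom import PhantomSpec, make_exvivo_pair, make_invivo_phantom

# Scaled-down phantom used by most tests: same geometry family as the
# default, coarser grids for speed.
SMALL_KWARGS = dict(
    endo_semiaxes=(40.0, 18.0, 18.0),
    wall_thickness=7.0,
    invivo_voxel=2.0,
    exvivo_voxel=1.0,
    pad_mm=12.0,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(**SMALL_KWARGS, seed=7)


@pytest.fixture(scope="session")
def small_pair(small_spec):
    vol_in, lab_in, lms_in = make_invivo_phantom(small_spec)
    vol_ex, lab_ex, lms_ex, field = make_exvivo_pair(small_spec, lab_in)
    return {
        "spec": small_spec,
        "vol_in": vol_in,
        "lab_in": lab_in,
        "lms_in": lms_in,
        "vol_ex": vol_ex,
        "lab_ex": lab_ex,
        "lms_ex": lms_ex,
        "field": field,
    }


@pytest.fixture(scope="session")
def default_pair():
    """Full-size default phantom pair (the study conditions)."""
    spec = PhantomSpec(seed=1)
    vol_in, lab_in, lms_in = make_invivo_phantom(spec)
    vol_ex, lab_ex, lms_ex, field = make_exvivo_pair(spec, lab_in)
    return {
        "spec": spec,
        "vol_in": vol_in,
        "lab_in": lab_in,
        "lms_in": lms_in,
        "vol_ex": vol_ex,
        "lab_ex": lab_ex,
        "lms_ex": lms_ex,
        "field": field,
    }


class FuncTransform:
    """Adapter exposing an arbitrary point map via the transform protocol."""

    def __init__(self, fn):
        self.fn = fn

    def apply(self, pts):
        return self.fn(np.atleast_2d(np.asarray(pts, dtype=float)))
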