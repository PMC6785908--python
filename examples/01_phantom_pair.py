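"""Generate a paired in-vivo / ex-vivo LV phantom and check its geometry.

The phantom encodes the measured in-vivo -> ex-vivo shape change of an
infarcted left ventricle: cavity axis ratios 0.83 (long) / 0.81 (short) and
regional wall-thickness multipliers 1.29 / 1.05 / 0.98 for healthy, 0-50%
and 50-100% transmural scar.
"""

import numpy as np

from lvcoreg import PhantomSpec, make_exvivo_pair, make_invivo_phantom
from lvcoreg.stats import compartment_volumes

spec = PhantomSpec(seed=1)
vol_in, lab_in, lms_in = make_invivo_phantom(spec)
vol_ex, lab_ex, lms_ex, field = make_exvivo_pair(spec, lab_in)

v_in = compartment_volumes(lab_in)
v_ex = compartment_volumes(lab_ex)
print(f"in-vivo : cavity {v_in.cavity_ml:6.1f} ml  wall {v_in.wall_ml:6.1f} ml  "
      f"scar {v_in.scar_ml:5.1f} ml ({100 * v_in.scar_fraction:.1f}% of wall)")
print(f"ex-vivo : cavity {v_ex.cavity_ml:6.1f} ml  wall {v_ex.wall_ml:6.1f} ml  "
      f"scar {v_ex.scar_ml:5.1f} ml")
print(f"cavity volume ratio ex/in = {v_ex.cavity_ml / v_in.cavity_ml:.3f} "
      f"(analytic 0.83 x 0.81^2 = {0.83 * 0.81**2:.3f})")

rng = np.random.default_rng(0)
pts = lms_in.points + rng.normal(scale=1.0, size=lms_in.points.shape)
det = field.jacobian_determinant(pts)
print(f"forward-warp Jacobian at jittered landmarks: "
      f"min {det.min():.2f} (positive = no folding)")
# The cavity shrinks to ~55% of its in-vivo volume while the wall volume is
# nearly conserved - the deformation every later stage must recover.
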