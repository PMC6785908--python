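"""Run the landmark -> rigid -> affine -> FFD registration chain.

The downsampled ex-vivo label map is the moving image, registered onto the
in-vivo grid.  Voxel DICE of wall and cavity is reported after each stage;
the non-rigid step is what recovers the regional wall-thickness change that
no affine map can represent.
"""

from lvcoreg import PhantomSpec, make_exvivo_pair, make_invivo_phantom
from lvcoreg.registration import (
    RegistrationConfig,
    apply_transform,
    fit_rigid_landmarks,
    register_affine,
    register_ffd,
    register_rigid,
)
from lvcoreg.segmentation import downsample_labels
from lvcoreg.stats import voxel_dice

spec = PhantomSpec(seed=1)
_, lab_in, lms_in = make_invivo_phantom(spec)
_, lab_ex, lms_ex, _ = make_exvivo_pair(spec, lab_in)
ds_ex = downsample_labels(lab_ex, spec.invivo_voxel)

cfg = RegistrationConfig()
landmark, rms = fit_rigid_landmarks(lms_ex, lms_in)
print(f"landmark rigid fit: residual RMS {rms:.2f} mm "
      "(non-zero because the true change includes scaling)")

stages = {"landmark": landmark}
stages["rigid"] = register_rigid(lab_in, ds_ex, stages["landmark"], cfg)
stages["affine"] = register_affine(lab_in, ds_ex, stages["rigid"], cfg)
stages["ffd"] = register_ffd(lab_in, ds_ex, stages["affine"], cfg)

for name, tr in stages.items():
    reg = apply_transform(ds_ex, tr, lab_in)
    print(f"{name:9s}: wall DICE {voxel_dice(reg.wall_mask(), lab_in.wall_mask()):.3f}  "
          f"cavity DICE {voxel_dice(reg.cavity_mask(), lab_in.cavity_mask()):.3f}")
# Wall DICE should rise from ~0.73 (landmark only) to > 0.93 after the FFD.
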