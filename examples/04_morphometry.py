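"""Mesh-projection morphometry: wall thickness, transmurality, nodal DICE.

Each endocardial node projects to its nearest epicardial node; the segment
length is the wall thickness and the fraction of segment samples inside
scar voxels is the transmurality.
"""

import numpy as np

from lvcoreg import PhantomSpec, ground_truth_transmurality, make_exvivo_pair, make_invivo_phantom
from lvcoreg.pipeline import endo_mesh_with_morphometry
from lvcoreg.registration import fit_rigid_landmarks
from lvcoreg.segmentation import downsample_labels
from lvcoreg.stats import thickness_change_by_bin

spec = PhantomSpec(seed=1)
_, lab_in, lms_in = make_invivo_phantom(spec)
_, lab_ex, lms_ex, _ = make_exvivo_pair(spec, lab_in)

endo_in = endo_mesh_with_morphometry(lab_in)
th = np.asarray(endo_in.attrs["thickness_mm"])
flag = np.asarray(endo_in.attrs["scar_flag"], dtype=bool)
print(f"in-vivo endocardium: {len(endo_in)} nodes, "
      f"healthy wall thickness {th[~flag].mean():.2f} mm (generator: 9.95 mm)")

tau = np.asarray(endo_in.attrs["transmurality"])
gt = ground_truth_transmurality(spec, endo_in.vertices)
print(f"transmurality vs ground truth: mean absolute error {np.abs(tau - gt).mean():.3f}")

endo_ex = endo_mesh_with_morphometry(downsample_labels(lab_ex, spec.invivo_voxel))
landmark, _ = fit_rigid_landmarks(lms_ex, lms_in)
table = thickness_change_by_bin(endo_in, endo_ex, align=landmark)
print("\nproportional thickness change by transmurality bin (%):")
print(table.round(1))
# Healthy tissue thickens ~+29%, 0-50% transmural scar ~+5%, dense scar
# ~-2% - the generator's imposed regional multipliers read back by the
# projection morphometry.
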