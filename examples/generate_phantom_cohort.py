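"""Generate a small synthetic bi-ventricular cohort and inspect it.

Each phantom is a 5-class label map (background, LV cavity, LV wall, RV
cavity, RV wall), an MR-like intensity volume and six anatomical landmarks,
with size/pose/shape jittered per subject.
"""

import numpy as np

from cardioshape import PhantomSpec, clinical_measures, make_cohort

cohort = make_cohort(5, PhantomSpec(), variability=1.0, rng_seed=7)

print("subject  LVV(ml)  LVM(g)  RVV(ml)  RVM(g)  apex voxel")
for i, (vol, lab, lm) in enumerate(cohort):
    cm = clinical_measures(lab)
    print(f"{i:7d}  {cm.lvv_ml:7.1f} {cm.lvm_g:7.1f} {cm.rvv_ml:8.1f}"
          f" {cm.rvm_g:7.1f}  {lm.voxel['apex']}")

print("\nVolumes and masses vary subject-to-subject because every phantom's")
print("geometry is independently jittered; the landmarks follow the pose")
print("exactly, so the apex voxel moves with the heart.")
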