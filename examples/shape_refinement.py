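"""Upgrade an artefact-corrupted segmentation to a smooth high-resolution one
by multi-atlas shape refinement.

To isolate the refinement stage this example uses the phantom's own
annotations instead of network predictions: the corrupted labels act as the
initial segmentation and the true landmarks initialise the atlas affines.
"""

from cardioshape import (ArtefactSpec, FusionSpec, PhantomSpec,
                         RegistrationSpec, build_atlas_bank, corrupt, dice,
                         make_cohort, make_phantom, preprocess, PreprocSpec,
                         refine, resample_to)

spec = PhantomSpec()
bank = build_atlas_bank(make_cohort(5, spec, rng_seed=11))
vol, lab, lm = make_phantom(spec)

cvol, clab, meta = corrupt(vol, lab, ArtefactSpec(
    target_z_spacing=10.0, max_shift_mm=5.0, apical_truncation_slices=1,
    rng_seed=5))
corrupted_hr = resample_to(clab, lab)

fused = refine(
    preprocess(resample_to(cvol, vol), PreprocSpec(target_dims=spec.grid_dims)),
    corrupted_hr, lm, bank,
    FusionSpec(patch_radius=1, window_radius=1, h_scale=10.0),
    RegistrationSpec(levels_mm=(20.0,), max_iters=8, smooth_sigma=1.0), L=3)

names = {1: "LVC", 2: "LVW", 3: "RVC", 4: "RVW"}
print("class  corrupted-vs-truth  refined-vs-truth")
for cls, name in names.items():
    print(f"{name:5s}  {dice(corrupted_hr, lab, cls):17.3f}"
          f"  {dice(resample_to(fused, lab), lab, cls):16.3f}")
print("\nThe refined column should beat the corrupted column on every class:")
print("registered smooth atlas shapes vote away the staircase and")
print("misalignment artefacts of the low-resolution input.")
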