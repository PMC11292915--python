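"""Simulate a phantom CT cohort with known ground truth.

Each patient gets a small CT-like volume with one ellipsoidal nodule whose
interior texture depends on the PD-L1 class, a pair of observer masks for
stability analysis, clinical covariates, and a TPS percentage consistent
with the class label.
"""

from radsig.syndata import PhantomConfig, generate_phantom_cohort

cohort = generate_phantom_cohort(PhantomConfig(n_patients=12, seed=7))

print(f"patients:            {cohort.n_patients}")
print(f"volume shape:        {cohort.volumes[0].shape}")
print(f"voxel spacing (mm):  {cohort.volumes[0].spacing}")
print(f"PD-L1 positive:      {int(cohort.labels.sum())} of {cohort.n_patients}")
print(f"TPS range (%):       {cohort.tps.min():.2f} .. {cohort.tps.max():.2f}")
print(f"first-nodule voxels: {cohort.masks_obs1[0].voxel_count()}")
print(f"clinical columns:    {list(cohort.clinical.columns)[:5]} ...")
# The label is, by construction, exactly the TPS >= 1% dichotomization;
# class 1 nodules have rougher, higher-variance interior texture.
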