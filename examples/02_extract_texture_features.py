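"""Extract the radiomics feature row for one tumor volume.

Runs the full filter bank (wavelet sub-bands, Laplacian-of-Gaussian,
exponential, square-root, LBP-3D) and the four feature classes
(first-order, GLCM, GLSZM, NGTDM) over the 3D volume of interest.
"""

from radsig.syndata import PhantomConfig, generate_phantom_cohort
from radsig.texture import extract_all

cohort = generate_phantom_cohort(PhantomConfig(n_patients=1, seed=3))
row = extract_all(cohort.volumes[0], cohort.masks_obs1[0])

print(f"features extracted: {len(row)}")
for name in (
    "original_firstorder_Skewness",
    "exponential_glszm_SmallAreaEmphasis",
    "wavelet_HLL_glcm_ClusterProminence",
    "lbp_3D_k_ngtdm_Busyness",
    "log_sigma_2_0_mm_3D_glszm_ZonePercentage",
):
    print(f"  {name:48s} = {row[name]:.6g}")
# Names follow <filter>_<class>_<feature>; values are per-patient inputs to
# the downstream Z-score / ICC / Pearson / LASSO selection stack.
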