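"""Published reference signatures, usable as worked examples.

These are the coefficient sets of a published CT deep-learning-radiomics
study of PD-L1 expression: an 11-feature radiomics signature (Rad-score)
and a 15-feature deep-learning signature (DLR-score), each a linear
combination ``intercept + Σ coefficient × feature``.  They exercise the
scoring path exactly as a model trained here would, and document the
canonical feature naming the extraction engine emits.
"""

from __future__ import annotations

from .select_sig import SignatureModel

DLR_INTERCEPT = 0.19631901840490795

DLR_COEFFICIENTS: dict[str, float] = {
    "DL_85": -0.029073,
    "DL_87": -0.008362,
    "DL_148": 0.019473,
    "DL_263": -0.001373,
    "DL_304": -0.034845,
    "DL_414": -0.030973,
    "DL_456": -0.005602,
    "DL_642": -0.002396,
    "DL_780": -0.004188,
    "DL_819": 0.009646,
    "DL_899": 0.018088,
    "DL_1011": -0.013829,
    "DL_1038": -0.006451,
    "DL_1252": -0.012642,
    "DL_1681": -0.008234,
}

RAD_COEFFICIENTS: dict[str, float] = {
    "exponential_glszm_SmallAreaEmphasis": 0.002025,
    "lbp_3D_k_ngtdm_Busyness": 0.022456,
    "lbp_3D_m1_glszm_SizeZoneNonUniformity": 0.030649,
    "lbp_3D_m1_glszm_SmallAreaLowGrayLevelEmphasis": 0.028801,
    "lbp_3D_m2_firstorder_Median": 0.009714,
    "log_sigma_2_0_mm_3D_glszm_Zone%": -0.032295,
    "squareroot_firstorder_Skewness": -0.028661,
    "wavelet_HHL_glszm_ZoneVariance": 0.024971,
    "wavelet_HLL_glcm_ClusterProminence": 0.020694,
    "wavelet_LHL_firstorder_Median": -0.002185,
    "wavelet_LLL_firstorder_Kurtosis": 0.019159,
}


def dlr_score_model() -> SignatureModel:
    """The published 15-feature DLR-score as a SignatureModel."""
    return SignatureModel(
        intercept=DLR_INTERCEPT,
        coefficients=dict(DLR_COEFFICIENTS),
        meta={"kind": "published-dlr"},
    )


def rad_score_model() -> SignatureModel:
    """The published 11-feature Rad-score as a SignatureModel."""
    return SignatureModel(
        intercept=DLR_INTERCEPT,
        coefficients=dict(RAD_COEFFICIENTS),
        meta={"kind": "published-rad"},
    )
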