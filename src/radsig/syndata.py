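"""Synthetic phantom and feature cohorts with known ground truth.

Two generators back the test pyramid:

* :func:`generate_phantom_cohort` — small CT-like volumes, each containing
  one ellipsoidal nodule whose interior texture is a class-conditional
  correlated Gaussian field (positive class: shorter correlation length and
  higher variance, which separates co-occurrence/size-zone statistics).
  Paired second-observer masks (morphological perturbation of the first)
  support the ICC stability filter, and clinical covariates carry a logistic
  dependence on the PD-L1 label.  TPS percentages are drawn so that the
  label is exactly the TPS ≥ 1% dichotomization.

* :func:`generate_feature_cohort` — a pure feature-table cohort (correlated
  Gaussian blocks, logistic labels) for exercising the selection stack at
  scale without any image work.

Defaults mirror the study design they emulate: positive fraction ≈ 61/259,
thin-slice anisotropic voxels, nodules in the 5–12 mm radius range, and
chronologically ordered study dates so a 7:3 calendar split is meaningful.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .imagio import ImageVolume, SegmentationMask, write_mask, write_volume

__all__ = [
    "PhantomConfig",
    "PhantomCohort",
    "generate_phantom_cohort",
    "generate_feature_cohort",
    "write_cohort",
    "CLINICAL_COLUMNS",
]

CLINICAL_COLUMNS = [
    "age", "sex", "smoking", "family_history", "CK19", "CEA", "NSE",
    "TNM", "lobulated_shape", "spiculation", "pleural_indentation",
    "vacuolar_sign", "size_mm",
]

_BINARY_CLINICAL = {
    "sex", "smoking", "family_history", "lobulated_shape", "spiculation",
    "pleural_indentation", "vacuolar_sign",
}


@dataclass(frozen=True)
class PhantomConfig:
    """Generating parameters for a phantom cohort.

    ``class_texture_contrast`` scales the positive-class texture shift: the
    nodule field's correlation length shrinks by ``1 + contrast`` and its
    standard deviation grows by ``1 + contrast/2``.  ``clinical_effects``
    maps clinical column → log-odds per unit of the (centered) covariate
    used when drawing the label.
    """

    n_patients: int = 60
    volume_shape: tuple[int, int, int] = (32, 48, 48)
    voxel_spacing: tuple[float, float, float] = (1.5, 0.7, 0.7)
    nodule_radius_range: tuple[float, float] = (5.0, 12.0)
    class_texture_contrast: float = 1.5
    clinical_effects: dict[str, float] = field(
        default_factory=lambda: {"CK19": 0.4, "lobulated_shape": 0.8}
    )
    positive_fraction: float = 61.0 / 259.0
    observer_perturbation: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.nodule_radius_range[0] <= 0:
            raise ValueError("nodule radii must be positive")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")


@dataclass
class PhantomCohort:
    volumes: list[ImageVolume]
    masks_obs1: list[SegmentationMask]
    masks_obs2: list[SegmentationMask]
    clinical: pd.DataFrame
    tps: np.ndarray
    labels: np.ndarray
    study_date: list[date]
    truth: dict

    @property
    def n_patients(self) -> int:
        return len(self.volumes)


def _correlated_field(rng: np.ndarray, shape, corr_len: float, sigma: float) -> np.ndarray:
    """Gaussian white noise smoothed to correlation length, variance-scaled."""
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma=corr_len, mode="reflect")
    sd = sm.std()
    return sm / sd * sigma if sd > 0 else sm


def _draw_tps(rng, label: int, mu_pos=-1.5, mu_neg=-7.0, sd=1.2) -> float:
    """Logistic-normal TPS truncated to the label's side of the 1% cut."""
    thr = np.log(0.01 / 0.99)  # logit of 1%
    mu = mu_pos if label else mu_neg
    if label:
        a, b = (thr - mu) / sd, np.inf
    else:
        a, b = -np.inf, (thr - mu) / sd
    z = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
    return float(100.0 / (1.0 + np.exp(-z)))


def _draw_clinical(rng, n: int) -> pd.DataFrame:
    """Covariate base distributions loosely matching a NSCLC nodule cohort."""
    return pd.DataFrame(
        {
            "age": rng.normal(57.0, 12.0, n).round(1),
            "sex": rng.binomial(1, 0.4, n),
            "smoking": rng.binomial(1, 0.2, n),
            "family_history": rng.binomial(1, 0.18, n),
            "CK19": np.exp(rng.normal(np.log(2.3), 0.45, n)).round(2),
            "CEA": np.exp(rng.normal(np.log(1.9), 0.7, n)).round(2),
            "NSE": np.exp(rng.normal(np.log(11.0), 0.2, n)).round(2),
            "TNM": rng.choice([1, 2, 3, 4], n, p=[0.55, 0.1, 0.1, 0.25]),
            "lobulated_shape": rng.binomial(1, 0.6, n),
            "spiculation": rng.binomial(1, 0.55, n),
            "pleural_indentation": rng.binomial(1, 0.55, n),
            "vacuolar_sign": rng.binomial(1, 0.2, n),
            "size_mm": np.exp(rng.normal(np.log(13.0), 0.4, n)).round(2),
        }
    )


def generate_clinical_cohort(
    n: int,
    clinical_effects: dict[str, float],
    positive_fraction: float,
    rng: np.random.Generator | int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Clinical covariates with a logistic label and a consistent TPS.

    The label's logit is an intercept calibrated to ``positive_fraction``
    plus ``Σ effect × (x − mean(x))`` over the configured covariates —
    effects are log-odds per raw covariate unit, so a logistic fit on the
    raw table recovers them.  Returns (clinical table, labels, tps).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    clinical = _draw_clinical(rng, n)
    eta = np.full(n, np.log(positive_fraction / (1 - positive_fraction)))
    for col, beta in clinical_effects.items():
        x = clinical[col].to_numpy(dtype=float)
        eta += beta * (x - x.mean())
    labels = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    tps = np.array([_draw_tps(rng, int(lb)) for lb in labels])
    return clinical, labels, tps


def generate_phantom_cohort(config: PhantomConfig) -> PhantomCohort:
    """Generate a seeded phantom cohort; byte-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    shape = tuple(config.volume_shape)
    spacing = tuple(config.voxel_spacing)

    clinical, labels, tps = generate_clinical_cohort(
        n, config.clinical_effects, config.positive_fraction, rng
    )

    volumes, masks1, masks2 = [], [], []
    zc, yc, xc = [np.arange(s) for s in shape]
    zz, yy, xx = np.meshgrid(zc, yc, xc, indexing="ij")
    for idx in range(n):
        r_mm = rng.uniform(*config.nodule_radius_range)
        r_vox = np.array([r_mm / s for s in spacing])
        if np.any(2 * r_vox + 4 > np.array(shape)):
            raise ValueError(
                f"patient {idx}: nodule radius {r_mm:.1f} mm does not fit volume {shape}"
            )
        center = np.array(
            [rng.uniform(r_vox[a] + 2, shape[a] - r_vox[a] - 2) for a in range(3)]
        )
        dist2 = (
            ((zz - center[0]) / r_vox[0]) ** 2
            + ((yy - center[1]) / r_vox[1]) ** 2
            + ((xx - center[2]) / r_vox[2]) ** 2
        )
        mask = dist2 <= 1.0

        # lung-like background: smooth low-intensity field around -880 HU
        bg = -880.0 + _correlated_field(rng, shape, corr_len=4.0, sigma=30.0)
        # class-conditional nodule texture
        contrast = config.class_texture_contrast
        if labels[idx]:
            corr_len = 2.0 / (1.0 + contrast)
            sigma = 60.0 * (1.0 + contrast / 2.0)
        else:
            corr_len, sigma = 2.0, 60.0
        tex = 20.0 + _correlated_field(rng, shape, corr_len=max(corr_len, 0.3), sigma=sigma)
        vol = np.where(mask, tex, bg)
        vol = np.clip(vol, -1000.0, 400.0)
        volumes.append(ImageVolume(vol, spacing=spacing))
        masks1.append(SegmentationMask(mask, observer="obs1"))

        if config.observer_perturbation > 0:
            struct = ndimage.generate_binary_structure(3, 1)
            op = ndimage.binary_dilation if rng.uniform() < 0.5 else ndimage.binary_erosion
            m2 = op(mask, structure=struct, iterations=config.observer_perturbation)
            if not m2.any():  # erosion can empty a tiny nodule
                m2 = mask.copy()
        else:
            m2 = mask.copy()
        masks2.append(SegmentationMask(m2, observer="obs2"))

    study_date = [date(2021, 1, 1) + timedelta(days=3 * i) for i in range(n)]
    truth = {
        "config": config,
        "label_model": "logistic on centered clinical_effects covariates",
    }
    return PhantomCohort(
        volumes=volumes,
        masks_obs1=masks1,
        masks_obs2=masks2,
        clinical=clinical,
        tps=tps,
        labels=labels,
        study_date=study_date,
        truth=truth,
    )


def generate_feature_cohort(
    n: int,
    p: int,
    n_informative: int,
    effect: float,
    rho: float = 0.0,
    seed: int = 0,
    block_size: int = 5,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Correlated-block Gaussian features with logistic labels.

    Features are standard normal in blocks of ``block_size`` sharing
    pairwise correlation ``rho``.  The label's logit is
    ``effect × Σ informative features`` — ``effect`` is the log-odds per
    unit of each informative feature.  The informative set is the first
    feature of each of the first ``n_informative`` blocks (so informative
    features are mutually independent when blocks are).
    """
    if n <= 0 or p <= 0:
        raise ValueError("n and p must be positive")
    if n_informative > p:
        raise ValueError("n_informative must not exceed p")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(p / block_size))
    cols = []
    for b in range(n_blocks):
        k = min(block_size, p - b * block_size)
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, k))
        cols.append(np.sqrt(rho) * shared + np.sqrt(1 - rho) * own)
    x = np.hstack(cols)
    informative = [min(b * block_size, p - 1) for b in range(n_informative)]
    informative = sorted(set(informative))[:n_informative]
    logit = effect * x[:, informative].sum(axis=1) if informative else np.zeros(n)
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    names = [f"F_{i}" for i in range(p)]
    table = pd.DataFrame(x, columns=names)
    truth = {"informative": [names[i] for i in informative], "effect": effect, "rho": rho}
    return table, y, truth


def write_cohort(cohort: PhantomCohort, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write volumes/masks as NIfTI and tables as CSV; returns the manifest."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (vol, m1, m2) in enumerate(
        zip(cohort.volumes, cohort.masks_obs1, cohort.masks_obs2)
    ):
        pid = f"P{i:04d}"
        vp = os.path.join(out_dir, f"{pid}_image.nii.gz")
        p1 = os.path.join(out_dir, f"{pid}_mask_obs1.nii.gz")
        p2 = os.path.join(out_dir, f"{pid}_mask_obs2.nii.gz")
        write_volume(vol, vp)
        write_mask(m1, vol, p1)
        write_mask(m2, vol, p2)
        rows.append(
            {
                "patient_id": pid,
                "date": cohort.study_date[i].isoformat(),
                "image": vp,
                "mask_obs1": p1,
                "mask_obs2": p2,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    clin = cohort.clinical.copy()
    clin.insert(0, "patient_id", manifest["patient_id"])
    clin["tps"] = cohort.tps
    clin.to_csv(os.path.join(out_dir, "clinical.csv"), index=False)
    return manifest
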