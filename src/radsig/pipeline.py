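"""Full-study orchestration: simulate/ingest → extract → chronological
split → train the three models (clinical, Rad-score, DLR-score) → evaluate.

Every stage respects the leakage guard: validation patients never influence
normalization parameters, the ICC stability filter, correlation pruning, the
CV penalty, the clinical screen, or the operating cutoff (chosen on the
training cohort by the Youden index).
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evalstats
from .embed import embed as _embed_image
from .embed import feature_names, make_stub_embedder
from .clinmodel import build_clinical_model, dichotomize_tps
from .imagio import crop_resize, largest_tumor_slice, minmax_normalize
from .select_sig import (
    SelectionConfig,
    SignatureModel,
    build_signature,
    score,
    zscore_apply,
)
from .syndata import PhantomCohort, PhantomConfig, generate_phantom_cohort
from .texture import FeatureConfig, extract_all

__all__ = ["RunConfig", "chronological_split", "extract_features", "run_study"]


@dataclass
class RunConfig:
    """Configuration for a complete study run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    embedder_seed: int = 0
    embedder_dim: int = 2048
    split_ratio: float = 0.7
    split_date_threshold: str | None = None  # ISO date: calendar-cut mode
    icc_subset_size: int = 30
    top_k_dl: int = 15
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split_ratio must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            for key in ("volume_shape", "voxel_spacing", "nodule_radius_range"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            kwargs["phantom"] = PhantomConfig(**ph)
        if "features" in raw:
            fe = dict(raw["features"])
            if "filters" in fe:
                fe["filters"] = tuple(fe["filters"])
            kwargs["features"] = FeatureConfig(**fe)
        if "selection" in raw:
            kwargs["selection"] = SelectionConfig(**raw["selection"])
        for key in (
            "embedder_seed", "embedder_dim", "split_ratio",
            "split_date_threshold", "icc_subset_size", "top_k_dl",
            "out_dir", "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def digest(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        d = {k: repr(v) for k, v in vars(self).items() if k != "out_dir"}
        return hashlib.sha256(repr(sorted(d.items())).encode()).hexdigest()[:12]


def chronological_split(
    manifest: pd.DataFrame,
    ratio: float = 0.7,
    date_threshold: str | None = None,
) -> tuple[list, list]:
    """Chronological train/validation split.

    Ratio mode sorts by date (ties by patient id) and sends the first
    ``ceil(ratio · n)`` patients to training.  Date-threshold mode assigns
    patients strictly before the threshold date to training — the calendar
    cut used when cohort sizes are fixed by the study timeline rather than
    an exact ratio.
    """
    if "date" not in manifest or manifest["date"].isna().any():
        raise ValueError("manifest must carry a date for every patient")
    df = manifest.sort_values(["date", "patient_id"], kind="stable")
    ids = df["patient_id"].tolist()
    if date_threshold is not None:
        train = df.loc[df["date"] < date_threshold, "patient_id"].tolist()
        val = [i for i in ids if i not in set(train)]
    else:
        n_train = math.ceil(ratio * len(ids))
        train, val = ids[:n_train], ids[n_train:]
    return train, val


def _dl_crop(vol, mask) -> np.ndarray:
    """Largest-tumor-slice → min-max [−1,1] → crop+resize 224×224."""
    k = largest_tumor_slice(mask)
    sl = minmax_normalize(vol.data[k])
    return crop_resize(sl, mask.data[k])


def extract_features(
    cohort: PhantomCohort,
    feature_config: FeatureConfig,
    embedder,
    observer: str = "obs1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Radiomics and DL feature tables for every patient in a cohort."""
    masks = cohort.masks_obs1 if observer == "obs1" else cohort.masks_obs2
    rad_rows, dl_rows = [], []
    names = feature_names(embedder.dim)
    for vol, mask in zip(cohort.volumes, masks):
        rad_rows.append(extract_all(vol, mask, feature_config))
        vec = _embed_image(_dl_crop(vol, mask), embedder)
        dl_rows.append(dict(zip(names, vec)))
    idx = pd.RangeIndex(len(rad_rows))
    return pd.DataFrame(rad_rows, index=idx), pd.DataFrame(dl_rows, index=idx)


def transform_and_score(model: SignatureModel, raw_table: pd.DataFrame) -> np.ndarray:
    """Normalize a raw feature table with the model's training parameters
    and evaluate the linear signature."""
    if model.normalization:
        table = zscore_apply(raw_table, model.normalization)
    else:
        table = raw_table
    return score(model, table)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _evaluate_model(name, s_train, s_val, y_train, y_val) -> dict:
    roc_tr = evalstats.roc_auc(s_train, y_train)
    roc_va = evalstats.roc_auc(s_val, y_val)
    cut = evalstats.youden_cutoff(roc_tr)
    cm_va = evalstats.confusion_at_cutoff(s_val, y_val, cut.cutoff)
    return {
        "model": name,
        "train": {
            "auc": roc_tr.auc, "auc_ci": list(roc_tr.ci),
            "auc_se": float(np.sqrt(roc_tr.variance)),
            "cutoff": cut.cutoff, "youden_j": cut.youden_j,
            **cut.metrics.as_dict(),
        },
        "validation": {
            "auc": roc_va.auc, "auc_ci": list(roc_va.ci),
            "auc_se": float(np.sqrt(roc_va.variance)),
            "cutoff": cut.cutoff, **cm_va.as_dict(),
        },
    }


def run_study(config: RunConfig) -> dict:
    """Execute the complete phantom study; returns the report bundle.

    Deterministic for a fixed config.  If ``config.out_dir`` is set, model
    JSONs and the report are written there.
    """
    cohort = generate_phantom_cohort(config.phantom)
    n = cohort.n_patients
    labels = dichotomize_tps(cohort.tps)
    assert np.array_equal(labels, cohort.labels), "TPS dichotomization must reproduce labels"

    manifest = pd.DataFrame(
        {"patient_id": [f"P{i:04d}" for i in range(n)],
         "date": [d.isoformat() for d in cohort.study_date]}
    )
    train_ids, val_ids = chronological_split(
        manifest, config.split_ratio, config.split_date_threshold
    )
    pid_to_idx = {p: i for i, p in enumerate(manifest["patient_id"])}
    tr = np.array([pid_to_idx[p] for p in train_ids])
    va = np.array([pid_to_idx[p] for p in val_ids])
    y_tr, y_va = labels[tr], labels[va]

    embedder = make_stub_embedder(config.embedder_seed, config.embedder_dim)
    rad, dl = extract_features(cohort, config.features, embedder, observer="obs1")

    # inter-observer stability subset: training patients only
    rng = np.random.default_rng(config.seed)
    sub = rng.choice(tr, size=min(config.icc_subset_size, len(tr)), replace=False)
    sub_cohort = PhantomCohort(
        volumes=[cohort.volumes[i] for i in sub],
        masks_obs1=[cohort.masks_obs1[i] for i in sub],
        masks_obs2=[cohort.masks_obs2[i] for i in sub],
        clinical=cohort.clinical.iloc[sub],
        tps=cohort.tps[sub],
        labels=cohort.labels[sub],
        study_date=[cohort.study_date[i] for i in sub],
        truth={},
    )
    rad2, dl2 = extract_features(sub_cohort, config.features, embedder, observer="obs2")
    rad1 = rad.iloc[sub].reset_index(drop=True)
    dl1 = dl.iloc[sub].reset_index(drop=True)

    sel = config.selection
    rad_model = build_signature(rad.iloc[tr], y_tr, sel, icc_tables=(rad1, rad2))
    dl_sel = SelectionConfig(
        icc_threshold=sel.icc_threshold, pearson_threshold=sel.pearson_threshold,
        cv_folds=sel.cv_folds, n_lambda=sel.n_lambda,
        lambda_min_ratio=sel.lambda_min_ratio, top_k=config.top_k_dl,
        one_se_rule=sel.one_se_rule, seed=sel.seed,
    )
    dlr_model = build_signature(dl.iloc[tr], y_tr, dl_sel, icc_tables=(dl1, dl2))
    clin_model, screen = build_clinical_model(cohort.clinical.iloc[tr], y_tr)

    scores = {
        "clinical": (
            score(clin_model, cohort.clinical.iloc[tr]),
            score(clin_model, cohort.clinical.iloc[va]),
        ),
        "rad_score": (
            transform_and_score(rad_model, rad.iloc[tr]),
            transform_and_score(rad_model, rad.iloc[va]),
        ),
        "dlr_score": (
            transform_and_score(dlr_model, dl.iloc[tr]),
            transform_and_score(dlr_model, dl.iloc[va]),
        ),
    }

    report: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_patients": n,
        "n_train": len(tr),
        "n_validation": len(va),
        "prevalence_train": float(y_tr.mean()),
        "prevalence_validation": float(y_va.mean()),
        "models": {},
        "delong": {},
    }
    for name, (s_tr, s_va) in scores.items():
        report["models"][name] = _evaluate_model(name, s_tr, s_va, y_tr, y_va)
    for other in ("clinical", "rad_score"):
        for cohort_name, idx_y, pick in (
            ("train", y_tr, 0), ("validation", y_va, 1),
        ):
            try:
                z, p = evalstats.delong_test(
                    scores["dlr_score"][pick], scores[other][pick], idx_y
                )
                report["delong"][f"dlr_vs_{other}_{cohort_name}"] = {"z": z, "p": p}
            except ValueError as exc:
                report["delong"][f"dlr_vs_{other}_{cohort_name}"] = {"error": str(exc)}

    # calibration + decision curve for the DLR model on the training cohort
    p_tr = _expit(scores["dlr_score"][0])
    try:
        cal = evalstats.hosmer_lemeshow(p_tr, y_tr, groups=min(10, len(tr) // 2))
        report["calibration_dlr_train"] = {
            "hl_statistic": cal.hl_statistic, "hl_p": cal.hl_p, "df": cal.df,
        }
    except ValueError as exc:
        report["calibration_dlr_train"] = {"error": str(exc)}
    dca = evalstats.decision_curve(p_tr, y_tr)
    report["decision_curve_dlr_train"] = {
        "thresholds": dca.thresholds.tolist(),
        "net_benefit": dca.net_benefit.tolist(),
        "treat_all": dca.treat_all.tolist(),
    }
    report["clinical_screen"] = {
        v: {"test": screen.loc[v, "test"], "p": float(screen.loc[v, "p"]),
            "selected": bool(screen.loc[v, "selected"])}
        for v in screen.index
    }

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        rad_model.to_json(os.path.join(config.out_dir, "rad_model.json"))
        dlr_model.to_json(os.path.join(config.out_dir, "dlr_model.json"))
        clin_model.to_json(os.path.join(config.out_dir, "clinical_model.json"))
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        _table3_like(report).to_csv(
            os.path.join(config.out_dir, "evaluation.csv"), index=False
        )
    report["_models"] = {
        "clinical": clin_model, "rad_score": rad_model, "dlr_score": dlr_model,
    }
    return report


def _table3_like(report: dict) -> pd.DataFrame:
    rows = []
    for name, res in report["models"].items():
        for cohort_name in ("train", "validation"):
            r = res[cohort_name]
            rows.append(
                {
                    "model": name, "cohort": cohort_name, "AUC": r["auc"],
                    "AUC_CI_low": r["auc_ci"][0], "AUC_CI_high": r["auc_ci"][1],
                    "cutoff": r["cutoff"], "sensitivity": r["sensitivity"],
                    "specificity": r["specificity"], "PPV": r["PPV"],
                    "NPV": r["NPV"], "accuracy": r["accuracy"],
                }
            )
    return pd.DataFrame(rows)
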