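"""Feature standardization, stability/correlation filtering, LASSO
selection with cross-validation, and linear signature scoring.

The selection stack mirrors the radiomics-signature recipe: Z-score
normalization fitted on the training cohort only, an inter-observer
ICC(2,1) stability filter (features with ICC ≤ 0.75 dropped), greedy
Pearson pruning of highly correlated pairs (|r| > 0.90), an ℓ1-penalized
logistic regression solved by cyclic coordinate descent over an IRLS
quadratic approximation with 5-fold stratified cross-validation for the
penalty, optional top-k retention, and a linear score
``intercept + Σ coefficient × feature``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionConfig",
    "SignatureModel",
    "zscore_fit",
    "zscore_apply",
    "icc_2_1",
    "icc_filter",
    "pearson_prune",
    "lasso_path",
    "lambda_max",
    "cv_select_lambda",
    "top_k_retain",
    "score",
    "build_signature",
]


@dataclass(frozen=True)
class SelectionConfig:
    icc_threshold: float = 0.75
    pearson_threshold: float = 0.90
    cv_folds: int = 5
    n_lambda: int = 40
    lambda_min_ratio: float | None = None
    top_k: int | None = None
    one_se_rule: bool = False
    refit_after_topk: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.icc_threshold < 1) or not (0 < self.pearson_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")


@dataclass
class SignatureModel:
    """Linear signature: intercept + named coefficients, with the training
    normalization parameters needed to apply it to new patients."""

    intercept: float
    coefficients: dict[str, float]
    normalization: dict[str, tuple[float, float]] = field(default_factory=dict)
    lam: float | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "normalization": {k: list(v) for k, v in self.normalization.items()},
            "lambda": self.lam,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SignatureModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            normalization={k: tuple(v) for k, v in d.get("normalization", {}).items()},
            lam=d.get("lambda"),
            meta=d.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# normalization

def zscore_fit(train: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Per-feature (mean, sd) from the training table; sd uses n−1.

    Constant features are dropped with a warning (their sd is zero).
    """
    if len(train) < 2:
        raise ValueError("need at least 2 patients to fit normalization")
    params: dict[str, tuple[float, float]] = {}
    for col in train.columns:
        x = train[col].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"dropping constant/degenerate feature {col!r}")
            continue
        params[col] = (float(x.mean()), sd)
    return params


def zscore_apply(table: pd.DataFrame, params: dict[str, tuple[float, float]]) -> pd.DataFrame:
    cols = {c: (table[c].to_numpy(dtype=float) - m) / s for c, (m, s) in params.items()}
    return pd.DataFrame(cols, index=table.index)


# ---------------------------------------------------------------------------
# ICC(2,1)

def icc_2_1(ratings: np.ndarray) -> float:
    """Two-way random effects, absolute agreement, single rater.

    ``ratings`` is subjects × raters.  With mean squares for rows (MSR),
    columns (MSC) and error (MSE):

        ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n)
    """
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ssr = k * np.sum((row_m - grand) ** 2)
    ssc = n * np.sum((col_m - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if ssr <= 1e-300 or denom <= 0:
        warnings.warn("zero between-subject variance; ICC set to 0")
        return 0.0
    return float((msr - mse) / denom)


def icc_filter(
    table_obs1: pd.DataFrame, table_obs2: pd.DataFrame, threshold: float = 0.75
) -> pd.DataFrame:
    """Per-feature ICC(2,1) across two observers, with a pass flag."""
    common = [c for c in table_obs1.columns if c in table_obs2.columns]
    rows = []
    for col in common:
        a = table_obs1[col].to_numpy(dtype=float)
        b = table_obs2[col].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            est = 0.0
        else:
            est = icc_2_1(np.column_stack([a[ok], b[ok]]))
        rows.append({"feature": col, "icc": est, "stable": est > threshold})
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# correlation pruning

def pearson_prune(
    table: pd.DataFrame, threshold: float = 0.90, ranking: list[str] | None = None
) -> list[str]:
    """Greedy pruning: scan features in priority order, drop a feature if it
    correlates with |r| > threshold with any already-retained feature."""
    if ranking is None:
        ranking = list(table.columns)
    x = table[ranking].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr))
    retained_idx: list[int] = []
    for j in range(len(ranking)):
        if all(abs(corr[j, i]) <= threshold for i in retained_idx):
            retained_idx.append(j)
    return [ranking[j] for j in retained_idx]


def label_correlation_ranking(table: pd.DataFrame, y: np.ndarray) -> list[str]:
    """Features ordered by |point-biserial correlation with the label|,
    descending; canonical name order breaks ties."""
    yv = np.asarray(y, dtype=float)
    scores = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        sx, sy = x.std(), yv.std()
        r = 0.0 if sx == 0 or sy == 0 else float(np.corrcoef(x, yv)[0, 1])
        scores[col] = abs(r)
    return sorted(table.columns, key=lambda c: (-scores[c], c))


# ---------------------------------------------------------------------------
# LASSO by cyclic coordinate descent

def _soft(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def lambda_max(x: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero:
    ``max_j |x_jᵀ (y − ȳ)| / n``."""
    n = len(y)
    r = y - y.mean()
    return float(np.max(np.abs(x.T @ r)) / n)


def _cd_weighted(x, wn, resid, beta, b0, lam, col_ss, tol, max_sweeps):
    """Cyclic coordinate descent with active-set screening.

    Sweeps run over the current active set until stable; a vectorized KKT
    check over the remaining features then either finishes or grows the
    set.  Equivalent to full cyclic sweeps, much faster when most
    coefficients stay at zero.  Mutates resid/beta in place; returns b0 and
    the sweep count (-1 on non-convergence).
    """
    p = len(beta)
    xw = x * wn[:, None]
    active = list(np.flatnonzero(beta)) or list(range(min(p, 1)))
    sweeps = 0
    while sweeps < max_sweeps:
        delta = 0.0
        for j in active:
            old = beta[j]
            zj = xw[:, j] @ resid + col_ss[j] * old
            new = _soft(zj, lam) / col_ss[j]
            if new != old:
                resid -= x[:, j] * (new - old)
                beta[j] = new
                delta = max(delta, abs(new - old))
        ob = b0
        b0 = ob + (wn @ resid) / wn.sum()
        resid -= b0 - ob
        delta = max(delta, abs(b0 - ob))
        sweeps += 1
        if delta < tol:
            grad = xw.T @ resid  # KKT over everything, vectorized
            inactive = np.setdiff1d(
                np.flatnonzero(np.abs(grad) > lam * (1 + 1e-9)),
                np.array(active, dtype=int),
            )
            if inactive.size == 0:
                return b0, sweeps
            active = sorted(set(active) | set(inactive.tolist()))
    return b0, -1


def lasso_path(
    x: np.ndarray,
    y: np.ndarray,
    lam: float,
    family: str = "binomial",
    beta0: np.ndarray | None = None,
    intercept0: float | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
) -> tuple[np.ndarray, float]:
    """ℓ1-penalized regression at one penalty value.

    Gaussian family minimizes ``(1/2n)‖y − b0 − Xβ‖² + λ‖β‖₁`` by cyclic
    coordinate descent; the binomial family wraps the same descent in an
    IRLS quadratic approximation of the logistic log-likelihood.  The
    intercept is never penalized.  Convergence: max coefficient change
    below ``tol``; exceeding ``max_sweeps`` raises with diagnostics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN in design or response")
    n, p = x.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    if family == "gaussian":
        b0 = float(y.mean()) if intercept0 is None else intercept0
        col_ss = (x**2).sum(axis=0) / n
        resid = y - b0 - x @ beta
        for sweep in range(max_sweeps):
            delta = 0.0
            for j in range(p):
                old = beta[j]
                zj = (x[:, j] @ resid) / n + col_ss[j] * old
                new = _soft(zj, lam) / col_ss[j]
                if new != old:
                    resid -= x[:, j] * (new - old)
                    beta[j] = new
                    delta = max(delta, abs(new - old))
            ob = b0
            b0 += resid.mean()
            resid -= b0 - ob
            delta = max(delta, abs(b0 - ob))
            if delta < tol:
                return beta, b0
        raise RuntimeError(
            f"gaussian LASSO did not converge in {max_sweeps} sweeps (lam={lam})"
        )
    if family != "binomial":
        raise ValueError(f"unknown family {family!r}")

    pbar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    b0 = float(np.log(pbar / (1 - pbar))) if intercept0 is None else intercept0
    for outer in range(100):
        eta = b0 + x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        # weighted coordinate descent on the quadratic approximation
        wn = w / n
        col_ss = (x**2 * wn[:, None]).sum(axis=0)
        resid = z - b0 - x @ beta
        beta_prev = beta.copy()
        b0_prev = b0
        b0, sweeps = _cd_weighted(x, wn, resid, beta, b0, lam, col_ss, tol, max_sweeps)
        if sweeps < 0:
            raise RuntimeError(
                f"coordinate descent did not converge in {max_sweeps} sweeps "
                f"(lam={lam}, outer={outer})"
            )
        if max(np.max(np.abs(beta - beta_prev)), abs(b0 - b0_prev)) < tol * 10:
            return beta, b0
    return beta, b0


def binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Mean binomial deviance (−2 × mean log-likelihood)."""
    eta = np.clip(eta, -30, 30)
    ll = y * eta - np.log1p(np.exp(eta))
    return float(-2.0 * np.mean(ll))


def _lambda_grid(x, y, n_lambda, min_ratio):
    lmax = lambda_max(x, y)
    if min_ratio is None:
        # glmnet's convention: a shallower path when p exceeds n
        min_ratio = 1e-2 if x.shape[1] >= x.shape[0] else 1e-3
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def cv_select_lambda(
    x: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    grid: np.ndarray | None = None,
    seed: int = 0,
    one_se_rule: bool = False,
    n_lambda: int = 40,
    lambda_min_ratio: float | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose the penalty minimizing mean CV binomial deviance.

    Folds are stratified by label and seeded.  Returns the chosen λ and the
    CV curve (λ, mean deviance, SE).  With ``one_se_rule`` the largest λ
    within one standard error of the minimum is chosen instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min((y == 1).sum(), (y == 0).sum()) < folds:
        raise ValueError(
            f"cannot stratify {folds} folds: a fold would contain one class; "
            "use fewer folds"
        )
    if grid is None:
        grid = _lambda_grid(x, y, n_lambda, lambda_min_ratio)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(grid)))
    for f, (tr, te) in enumerate(skf.split(x, y)):
        beta, b0 = None, None
        for g, lam in enumerate(grid):  # warm start down the path
            beta, b0 = lasso_path(x[tr], y[tr], lam, beta0=beta, intercept0=b0)
            dev[f, g] = binomial_deviance(y[te], b0 + x[te] @ beta)
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean))
    if one_se_rule:
        ok = np.flatnonzero(mean <= mean[best] + se[best])
        best = int(ok[0])  # grid is descending: first = largest λ
    curve = pd.DataFrame({"lam": grid, "mean_deviance": mean, "se": se})
    return float(grid[best]), curve


def top_k_retain(model: SignatureModel, k: int = 15) -> SignatureModel:
    """Keep the k coefficients largest in absolute value; no refit.

    Ties at rank k are broken by canonical (sorted) feature-name order —
    the later name is dropped.  A model with ≤ k nonzero coefficients is
    returned unchanged.
    """
    nz = {f: c for f, c in model.coefficients.items() if c != 0.0}
    if len(nz) <= k:
        return model
    order = sorted(nz, key=lambda f: (-abs(nz[f]), f))
    keep = set(order[:k])
    return SignatureModel(
        intercept=model.intercept,
        coefficients={f: c for f, c in model.coefficients.items() if f in keep},
        normalization=model.normalization,
        lam=model.lam,
        meta={**model.meta, "top_k": k},
    )


_NAME_ALIASES = {"Zone%": "ZonePercentage"}


def canonical_feature_name(name: str) -> str:
    for alias, canon in _NAME_ALIASES.items():
        if name.endswith(alias):
            return name[: -len(alias)] + canon
    return name


def score(model: SignatureModel, table: pd.DataFrame) -> np.ndarray:
    """Linear signature score ``intercept + Σ coef × feature`` per patient.

    The table must already be on the model's normalized scale (or raw, if
    the model carries no normalization).  A missing feature column raises an
    error naming it.
    """
    out = np.full(len(table), model.intercept, dtype=float)
    cols = {canonical_feature_name(c): c for c in table.columns}
    for feat, coef in model.coefficients.items():
        key = canonical_feature_name(feat)
        if key not in cols:
            raise KeyError(f"feature {feat!r} missing from the table")
        out += coef * table[cols[key]].to_numpy(dtype=float)
    return out


def build_signature(
    train: pd.DataFrame,
    y: np.ndarray,
    config: SelectionConfig | None = None,
    icc_tables: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> SignatureModel:
    """Full selection stack on the training cohort only.

    Z-score fit → optional ICC stability filter (dual-observer feature
    tables, typically a ~30-patient subset) → Pearson pruning in
    label-correlation priority order → 5-fold CV LASSO → optional top-k
    truncation.  Validation data never enters any stage.
    """
    if config is None:
        config = SelectionConfig()
    y = np.asarray(y, dtype=float)
    table = train
    if icc_tables is not None:
        iccres = icc_filter(*icc_tables, threshold=config.icc_threshold)
        stable = [c for c in table.columns if c in iccres.index and iccres.loc[c, "stable"]]
        table = table[stable]
    table = table.loc[:, table.notna().all(axis=0)]
    params = zscore_fit(table)
    table = zscore_apply(table, params)
    ranking = label_correlation_ranking(table, y)
    retained = pearson_prune(table, config.pearson_threshold, ranking)
    table = table[retained]
    x = table.to_numpy(dtype=float)
    lam, curve = cv_select_lambda(
        x,
        y,
        folds=config.cv_folds,
        seed=config.seed,
        one_se_rule=config.one_se_rule,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    beta, b0 = lasso_path(x, y, lam)
    coefs = {f: float(b) for f, b in zip(retained, beta) if b != 0.0}
    model = SignatureModel(
        intercept=float(b0),
        coefficients=coefs,
        normalization={f: params[f] for f in coefs},
        lam=lam,
        meta={"n_train": len(train), "n_candidates": len(retained)},
    )
    if config.top_k is not None:
        model = top_k_retain(model, config.top_k)
        if config.refit_after_topk and model.coefficients:
            keep = list(model.coefficients)
            xk = table[keep].to_numpy(dtype=float)
            beta, b0 = lasso_path(xk, y, lam)
            model.coefficients = {f: float(b) for f, b in zip(keep, beta) if b != 0.0}
            model.intercept = float(b0)
    return model
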