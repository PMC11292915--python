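"""Clinical model: TPS dichotomization, univariate screening, and
multivariate logistic regression.

The screen follows the usual two-track rule: continuous variables get a
two-sample t-test when both classes look normal (Shapiro–Wilk at 0.05),
otherwise Mann–Whitney; categorical variables get Pearson χ² unless any
expected cell is below 5, in which case Fisher's exact test.  Variables
with p < α enter a multivariate logistic regression whose linear predictor
is the clinical score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .select_sig import SignatureModel

__all__ = [
    "dichotomize_tps",
    "univariate_screen",
    "logistic_fit",
    "build_clinical_model",
    "LogisticFit",
]


def dichotomize_tps(tps) -> np.ndarray:
    """PD-L1 label from the tumor proportion score: positive iff TPS ≥ 1%."""
    arr = np.asarray(tps, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("TPS must lie in [0, 100]")
    out = (arr >= 1.0).astype(int)
    return out if out.shape else int(out)


def _is_categorical(x: np.ndarray, max_levels: int = 6) -> bool:
    return len(np.unique(x)) <= max_levels and np.allclose(x, np.round(x))


def univariate_screen(
    table: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-variable test, statistic and p-value; ``selected`` = p < alpha."""
    y = np.asarray(labels).astype(int)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 patients per class")
    rows = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            warnings.warn(f"variable {col!r} is constant; excluded from the screen")
            continue
        a, b = x[y == 1], x[y == 0]
        if _is_categorical(x):
            levels = np.unique(x)
            tab = np.array([[(x[y == g] == lv).sum() for lv in levels] for g in (0, 1)])
            expected = stats.contingency.expected_freq(tab)
            if (expected < 5).any():
                if tab.shape == (2, 2):
                    stat, p = stats.fisher_exact(tab)
                    test = "fisher"
                else:
                    stat, p, *_ = stats.chi2_contingency(tab, correction=False)
                    test = "chi2"  # Fisher undefined beyond 2×2; fall back
            else:
                stat, p, *_ = stats.chi2_contingency(tab, correction=False)
                test = "chi2"
        else:
            normal = all(
                len(g) >= 3 and stats.shapiro(g).pvalue > 0.05 for g in (a, b)
            )
            if normal:
                stat, p = stats.ttest_ind(a, b)
                test = "t"
            else:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                test = "mannwhitney"
        rows.append(
            {"variable": col, "test": test, "statistic": float(stat),
             "p": float(p), "selected": bool(p < alpha)}
        )
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class LogisticFit:
    """Multivariate logistic regression with Wald inference."""

    variables: list[str]
    coefficients: np.ndarray  # includes intercept first
    standard_errors: np.ndarray
    p_values: np.ndarray
    converged: bool
    summary: pd.DataFrame = field(repr=False, default=None)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients[1:])

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.variables].to_numpy(dtype=float)
        return self.coefficients[0] + x @ self.coefficients[1:]


def logistic_fit(x: pd.DataFrame, y: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton/IRLS) with OR and
    95% Wald confidence intervals.

    Raises on perfect separation and on collinear design columns.
    """
    y = np.asarray(y, dtype=float)
    variables = list(x.columns)
    design = sm.add_constant(x.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("collinear design: drop redundant columns")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("more parameters than patients")
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200, tol=1e-10)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise ValueError(
                "perfect separation detected; consider a penalized fit"
            ) from exc
    coefs = np.asarray(res.params)
    ses = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    lo = np.exp(coefs[1:] - 1.96 * ses[1:])
    hi = np.exp(coefs[1:] + 1.96 * ses[1:])
    summary = pd.DataFrame(
        {
            "coef": coefs[1:],
            "se": ses[1:],
            "OR": np.exp(coefs[1:]),
            "CI_low": lo,
            "CI_high": hi,
            "p": pvals[1:],
        },
        index=variables,
    )
    return LogisticFit(
        variables=variables,
        coefficients=coefs,
        standard_errors=ses,
        p_values=pvals,
        converged=bool(res.mle_retvals.get("converged", True)),
        summary=summary,
    )


def build_clinical_model(
    records: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> tuple[SignatureModel, pd.DataFrame]:
    """Univariate screen → multivariate logistic fit → clinical score.

    Returns the clinical signature (logistic linear predictor as a
    SignatureModel) and the screening table.  If no variable passes the
    screen, falls back to an intercept-only model with a warning.
    """
    screen = univariate_screen(records, labels, alpha=alpha)
    chosen = [v for v in screen.index if screen.loc[v, "selected"]]
    if not chosen:
        warnings.warn("no clinical variable passed the univariate screen; "
                      "falling back to intercept-only")
        prev = float(np.mean(labels))
        prev = min(max(prev, 1e-6), 1 - 1e-6)
        model = SignatureModel(
            intercept=float(np.log(prev / (1 - prev))), coefficients={},
            meta={"screen": "empty"},
        )
        return model, screen
    fit = logistic_fit(records[chosen], labels)
    model = SignatureModel(
        intercept=float(fit.coefficients[0]),
        coefficients={v: float(c) for v, c in zip(chosen, fit.coefficients[1:])},
        meta={"kind": "clinical", "alpha": alpha},
    )
    return model, screen
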