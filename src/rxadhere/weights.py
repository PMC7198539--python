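"""Propensity scores, stabilized IPTW weights and covariate balance.

The propensity of brand initiation is estimated by logistic regression on
the baseline covariates (sex, age continuous, CMU status, polypharmacy,
Charlson class, fracture history, year of initiation, administration
frequency, prescriber specialty) with a year x frequency interaction.
Stabilized weights multiply the inverse propensity of the received
treatment by the marginal (empirical) treatment prevalence, so the weighted
pseudo-population keeps the original group shares and the mean weight is ~1.

Balance is assessed with standardized differences; |d| <= 0.10 is the
conventional negligible-imbalance threshold.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .adherence import ContractViolationError

logger = logging.getLogger(__name__)

BALANCE_THRESHOLD = 0.10

DEFAULT_FORMULA = (
    "brand ~ C(sex) + age + cmu + polypharmacy + C(charlson_class) "
    "+ fracture_history + C(year) * C(frequency) + C(specialty)"
)


class EstimationError(RuntimeError):
    """A model failed to converge or the design is degenerate."""


@dataclass
class PropensityModelSpec:
    """Covariate specification of the treatment (brand) propensity model."""

    formula: str = DEFAULT_FORMULA
    drop_missing_specialty: bool = True

    #: model covariates reported in the balance diagnostics: (name, kind);
    #: age enters both continuous and in classes. ALD is deliberately absent:
    #: it is a baseline-table variable, not a propensity-model covariate.
    balance_covariates: list[tuple[str, str]] = field(default_factory=lambda: [
        ("age", "continuous"),
        ("age_class", "categorical"),
        ("sex", "categorical"),
        ("cmu", "binary"),
        ("polypharmacy", "binary"),
        ("fracture_history", "binary"),
        ("charlson_class", "categorical"),
        ("year", "categorical"),
        ("frequency", "categorical"),
        ("specialty", "categorical"),
    ])


def _prepare(cohort: pd.DataFrame, spec: PropensityModelSpec) -> tuple[pd.DataFrame, int]:
    df = cohort.copy()
    df["brand"] = (df["group"] == "brand").astype(int)
    n0 = len(df)
    if spec.drop_missing_specialty and "specialty" in df:
        missing = df["specialty"].isna() | (df["specialty"] == "unknown")
        df = df[~missing]
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("propensity model: dropped %d patients with missing "
                    "prescriber specialty", n_dropped)
    return df.reset_index(drop=True), n_dropped


def fit_propensity(cohort: pd.DataFrame,
                   spec: PropensityModelSpec | None = None,
                   ) -> tuple[pd.DataFrame, int, object]:
    """Fit the brand-propensity logistic model.

    Returns (cohort rows used, with a ``propensity`` column; n dropped for
    missing specialty; fitted results). Raises :class:`EstimationError` on
    non-convergence or separation, naming the most extreme covariate.
    """
    spec = spec or PropensityModelSpec()
    df, n_dropped = _prepare(cohort, spec)
    if df["brand"].nunique() < 2:
        raise EstimationError("propensity model: only one treatment group present")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # IRLS overflow in sparse cells
            model = smf.glm(spec.formula, data=df, family=sm.families.Binomial())
            result = model.fit(maxiter=200)
    except Exception as exc:  # statsmodels raises plain errors on bad designs
        raise EstimationError(f"propensity model failed: {exc}") from exc

    params = result.params
    if not np.all(np.isfinite(params)):
        bad = params.index[~np.isfinite(params)][0]
        raise EstimationError(f"propensity model did not converge (term {bad!r})")
    extreme = params.drop(labels=["Intercept"], errors="ignore").abs()
    scores = np.asarray(result.fittedvalues)
    eps = 1e-8
    y = df["brand"].to_numpy()
    # complete separation: every fitted probability is at its own outcome
    if len(extreme) and (scores[y == 1] > 1 - eps).all() and (scores[y == 0] < eps).all():
        worst = extreme.idxmax()
        raise EstimationError(
            f"perfect separation in propensity model (term {worst!r}, "
            f"|coef| = {extreme.max():.1f})")
    n_extreme = int(((scores < eps) | (scores > 1 - eps)).sum())
    if n_extreme:
        logger.warning(
            "propensity model: %d fitted probabilities at the boundary "
            "(quasi-separation in sparse cells); scores clipped", n_extreme)
    df = df.copy()
    df["propensity"] = np.clip(scores, eps, 1 - eps)
    return df, n_dropped, result


def stabilized_weight(score: np.ndarray | float, brand: np.ndarray | int,
                      marginal: float) -> np.ndarray | float:
    """Stabilized IPTW weight: P(brand)/e for treated, (1-P)/(1-e) for controls."""
    score_arr = np.asarray(score, dtype=float)
    if np.any(score_arr <= 0.0) or np.any(score_arr >= 1.0):
        raise ContractViolationError("propensity scores must lie strictly in (0,1)")
    brand_arr = np.asarray(brand)
    w = np.where(brand_arr == 1, marginal / score_arr,
                 (1.0 - marginal) / (1.0 - score_arr))
    return float(w) if np.isscalar(score) or w.ndim == 0 else w


def compute_weights(cohort: pd.DataFrame,
                    spec: PropensityModelSpec | None = None,
                    ) -> tuple[pd.DataFrame, int, object]:
    """Fit the propensity model and attach stabilized weights (``sw``).

    The stabilizing marginal is the empirical brand share of the rows used.
    """
    df, n_dropped, result = fit_propensity(cohort, spec)
    marginal = df["brand"].mean()
    df["sw"] = stabilized_weight(df["propensity"].to_numpy(),
                                 df["brand"].to_numpy(), marginal)
    return df, n_dropped, result


# ---------------------------------------------------------------------------
# Balance diagnostics
# ---------------------------------------------------------------------------

def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = float(np.average(x, weights=w))
    v = float(np.average((x - m) ** 2, weights=w))
    return m, v


def standardized_difference(x: pd.Series | np.ndarray, group: pd.Series | np.ndarray,
                            weights: Optional[np.ndarray] = None,
                            binary: Optional[bool] = None) -> float:
    """Standardized difference of a continuous or binary covariate.

    Continuous: (m1-m2)/sqrt((s1^2+s2^2)/2); binary uses p(1-p) variances.
    ``group`` is any two-level label; the first level in sorted order is
    taken as group 1. Zero pooled variance with unequal means returns inf.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(group)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ContractViolationError("standardized difference needs exactly 2 groups")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if binary is None:
        binary = set(np.unique(x)) <= {0.0, 1.0}
    stats = []
    for lev in levels:
        mask = g == lev
        m, v = _weighted_mean_var(x[mask], w[mask])
        if binary:
            v = m * (1.0 - m)
        stats.append((m, v))
    (m1, v1), (m2, v2) = stats
    pooled = (v1 + v2) / 2.0
    if pooled <= 0:
        return 0.0 if m1 == m2 else math.inf  # flagged by the caller
    return (m1 - m2) / math.sqrt(pooled)


def balance_report(cohort: pd.DataFrame, weights: Optional[np.ndarray] = None,
                   spec: PropensityModelSpec | None = None,
                   threshold: float = BALANCE_THRESHOLD) -> pd.DataFrame:
    """Pre/post-weighting standardized differences for the model covariates.

    Categorical covariates get one row per level (level indicator vs group);
    age is reported both continuous and as 10-year classes.
    """
    spec = spec or PropensityModelSpec()
    df = cohort.copy()
    if "age_class" not in df and "age" in df:
        df["age_class"] = pd.cut(df["age"], bins=[0, 60, 70, 80, np.inf],
                                 labels=["50-59", "60-69", "70-79", "80+"],
                                 right=False)
    g = df["group"].to_numpy()
    rows = []
    for name, kind in spec.balance_covariates:
        if name not in df:
            continue
        if kind in ("continuous", "binary"):
            x = df[name].astype(float).to_numpy()
            d_un = standardized_difference(x, g, None, binary=(kind == "binary"))
            d_w = (standardized_difference(x, g, weights, binary=(kind == "binary"))
                   if weights is not None else np.nan)
            rows.append({"covariate": name, "level": "", "d_unweighted": d_un,
                         "d_weighted": d_w})
        else:
            for lev in sorted(df[name].dropna().astype(str).unique()):
                x = (df[name].astype(str) == lev).astype(float).to_numpy()
                d_un = standardized_difference(x, g, None, binary=True)
                d_w = (standardized_difference(x, g, weights, binary=True)
                       if weights is not None else np.nan)
                rows.append({"covariate": name, "level": lev,
                             "d_unweighted": d_un, "d_weighted": d_w})
    report = pd.DataFrame(rows)
    report["balanced"] = report["d_weighted"].abs() <= threshold
    report["flag_infinite"] = ~np.isfinite(report["d_unweighted"].astype(float))
    return report


# ---------------------------------------------------------------------------
# Optional graphical diagnostics (require matplotlib)
# ---------------------------------------------------------------------------

def plot_balance(report: pd.DataFrame, path=None, threshold: float = BALANCE_THRESHOLD):
    """Love plot: pre/post-weighting |standardized difference| per covariate."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = report[np.isfinite(report["d_unweighted"])].copy()
    labels = rep["covariate"] + np.where(rep["level"].astype(str) != "",
                                         " = " + rep["level"].astype(str), "")
    y = np.arange(len(rep))
    fig, ax = plt.subplots(figsize=(7, 0.3 * len(rep) + 1.5))
    ax.scatter(rep["d_unweighted"].abs(), y, label="unweighted", marker="o")
    if rep["d_weighted"].notna().any():
        ax.scatter(rep["d_weighted"].abs(), y, label="weighted", marker="x")
    ax.axvline(threshold, ls="--", color="grey")
    ax.set_yticks(y, labels)
    ax.set_xlabel("|standardized difference|")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_continuous_balance(cohort: pd.DataFrame, covariate: str,
                            weights: Optional[np.ndarray] = None, path=None):
    """Side-by-side boxplots, weighted ECDFs and an empirical QQ-plot of a
    continuous covariate across the two treatment groups."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = cohort["group"].to_numpy()
    x = cohort[covariate].astype(float).to_numpy()
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    groups = sorted(np.unique(g))
    axes[0].boxplot([x[g == lev] for lev in groups], tick_labels=groups)
    axes[0].set_title(f"{covariate}: boxplot")
    for lev in groups:
        xs = np.sort(x[g == lev])
        ws = w[g == lev][np.argsort(x[g == lev])]
        axes[1].step(xs, np.cumsum(ws) / ws.sum(), where="post", label=lev)
    axes[1].legend()
    axes[1].set_title("weighted ECDF")
    qs = np.linspace(0.01, 0.99, 99)
    axes[2].plot(np.quantile(x[g == groups[0]], qs),
                 np.quantile(x[g == groups[1]], qs), ".")
    lims = [x.min(), x.max()]
    axes[2].plot(lims, lims, "--", color="grey")
    axes[2].set_title("empirical QQ")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
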