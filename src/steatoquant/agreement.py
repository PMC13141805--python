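"""Rater-agreement statistics for automated vs. pathologist steatosis scores.

Continuous agreement: Pearson r (with Fisher-z CI and R^2 = r^2), Spearman
rho, RMSE, Bland-Altman limits of agreement, and the fraction of cases where
the automated score falls within a +/-5 percentage-point tolerance of the
mean pathologist score. Ordinal agreement: quadratically weighted Cohen's
kappa over the steatosis bins, with Landis-Koch interpretation bands.

Raters may cover different subsets of cases; pairwise statistics use pairwise
deletion. Averaging n independent raters shrinks the error SD of the
reference by sqrt(1/n), which is why consensus correlations exceed
single-rater ones.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import CATEGORY_LABELS, bin_category


class UndefinedStatisticError(ValueError):
    """Statistic is undefined for the given data (e.g., zero variance)."""


def _pair(x, y, min_n: int = 1):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and congruent")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < min_n:
        raise UndefinedStatisticError(
            f"need at least {min_n} overlapping pairs, got {x.size}"
        )
    return x, y


# ---------------------------------------------------------------------------
# continuous agreement
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PearsonResult:
    r: float
    ci95: tuple[float, float]
    r2: float
    p: float
    n: int


def pearson(x, y) -> PearsonResult:
    """Product-moment correlation with Fisher-z 95% CI and R^2 = r^2."""
    x, y = _pair(x, y, min_n=3)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    n = x.size
    if abs(r) >= 1.0:
        ci = (r, r)
    else:
        z = np.arctanh(r)
        half = 1.96 / math.sqrt(n - 3) if n > 3 else np.inf
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return PearsonResult(r=r, ci95=ci, r2=r * r, p=float(res.pvalue), n=n)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on mid-ranks) and two-sided p."""
    x, y = _pair(x, y, min_n=3)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedStatisticError("all-tied input; rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def rmse(x, y) -> float:
    """Root mean square difference, in the units of the scores (%)."""
    x, y = _pair(x, y, min_n=1)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def bland_altman(x, y) -> tuple[float, float, float, pd.DataFrame]:
    """Bias and 1.96-SD limits of agreement for paired measurements.

    Differences are ``x - y``; the per-case table pairs each difference with
    the mean of the two measurements (the plot abscissa). SD uses n-1.
    """
    x, y = _pair(x, y, min_n=2)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    table = pd.DataFrame({"reference": (x + y) / 2.0, "difference": d})
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, table


def tolerance_rate(
    ai, ratings: np.ndarray, tol: float = 5.0
) -> tuple[float, int, int]:
    """Fraction of cases where AI is within ``tol`` percentage points of the
    mean available-rater score (boundary inclusive).

    ``ratings`` is (n_cases, n_raters) with NaN for missing. Cases with no
    rater are excluded; returns (rate, n_used, n_excluded).
    """
    ai = np.asarray(ai, dtype=float)
    ratings = np.atleast_2d(np.asarray(ratings, dtype=float))
    if ratings.shape[0] != ai.size:
        raise ValueError("ai and ratings row counts differ")
    have = ~np.all(np.isnan(ratings), axis=1)
    n_excluded = int((~have).sum())
    if not have.any():
        raise UndefinedStatisticError("no case has any rater")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(ratings[have], axis=1)
    within = np.abs(ai[have] - means) <= tol
    return float(within.mean()), int(have.sum()), n_excluded


def range_classification(ai, ratings: np.ndarray) -> dict[str, int]:
    """Count cases where AI is above, below, or within the rater range.

    Within is inclusive at both extremes; cases with no rater are skipped.
    """
    ai = np.asarray(ai, dtype=float)
    ratings = np.atleast_2d(np.asarray(ratings, dtype=float))
    counts = {"higher": 0, "lower": 0, "within": 0}
    for a, row in zip(ai, ratings):
        row = row[~np.isnan(row)]
        if row.size == 0:
            continue
        if a > row.max():
            counts["higher"] += 1
        elif a < row.min():
            counts["lower"] += 1
        else:
            counts["within"] += 1
    return counts


def normality_test(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation via scipy)."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("zero variance; normality test undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def variance_reduction_factor(n_raters: int) -> float:
    """Noise SD of an n-rater mean relative to one rater: sqrt(1/n).

    With independent rater errors, Var(mean) = Var(individual)/n; for three
    raters the factor is sqrt(1/3) ~ 0.58, which is why consensus reference
    scores correlate more strongly with any external measure.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    return math.sqrt(1.0 / n_raters)


# ---------------------------------------------------------------------------
# ordinal agreement: quadratically weighted Cohen's kappa
# ---------------------------------------------------------------------------

def quadratic_weights(k: int) -> np.ndarray:
    """Disagreement weights w_ij = (i-j)^2 / (k-1)^2 for k ordered bins."""
    if k < 2:
        raise ValueError("need at least 2 categories")
    idx = np.arange(k)
    return (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2


def _to_indices(a, bins) -> np.ndarray:
    lookup = {b: i for i, b in enumerate(bins)}
    try:
        return np.array([lookup[v] for v in a], dtype=int)
    except KeyError as exc:
        raise ValueError(f"category {exc.args[0]!r} not in bins {list(bins)}") from exc


def weighted_kappa(
    a,
    b,
    bins=None,
    ci_method: str = "asymptotic",
    seed: int = 0,
    n_boot: int = 2000,
) -> tuple[float, tuple[float, float]]:
    """Cohen's kappa with quadratic disagreement weights, plus a 95% CI.

    ``a`` and ``b`` are categorical vectors over the same ordered ``bins``
    (default: the steatosis bins). kappa = 1 - sum(w O) / sum(w E) with O the
    observed joint proportions and E the product of the marginals. The CI is
    the large-sample (Fleiss-Cohen-Everitt) one by default; a seeded bootstrap
    over cases is available with ``ci_method="bootstrap"`` (preferable for
    sparse tables).

    Raises :class:`UndefinedStatisticError` when either rater is constant
    (degenerate marginals).
    """
    bins = list(bins) if bins is not None else CATEGORY_LABELS
    ai = _to_indices(a, bins)
    bi = _to_indices(b, bins)
    if ai.shape != bi.shape or ai.ndim != 1:
        raise ValueError("rater vectors must be 1-D and congruent")
    n = ai.size
    if n < 2:
        raise UndefinedStatisticError("need at least 2 rated cases")
    if np.unique(ai).size < 2 or np.unique(bi).size < 2:
        raise UndefinedStatisticError(
            "a rater is constant; weighted kappa is undefined"
        )
    k = len(bins)
    kappa = _kappa_value(ai, bi, k)

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            ra, rb = ai[idx], bi[idx]
            if np.unique(ra).size < 2 or np.unique(rb).size < 2:
                continue
            vals.append(_kappa_value(ra, rb, k))
        if not vals:
            raise UndefinedStatisticError("bootstrap produced no valid resamples")
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return kappa, (float(lo), float(hi))
    if ci_method != "asymptotic":
        raise ValueError("ci_method must be 'asymptotic' or 'bootstrap'")

    se = _kappa_se(ai, bi, k, kappa)
    lo = max(-1.0, kappa - 1.96 * se)
    hi = min(1.0, kappa + 1.96 * se)
    return kappa, (lo, hi)


def _joint_proportions(ai: np.ndarray, bi: np.ndarray, k: int) -> np.ndarray:
    obs = np.zeros((k, k))
    np.add.at(obs, (ai, bi), 1.0)
    return obs / ai.size


def _kappa_value(ai: np.ndarray, bi: np.ndarray, k: int) -> float:
    w = quadratic_weights(k)
    obs = _joint_proportions(ai, bi, k)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    denom = (w * exp).sum()
    if denom == 0:
        raise UndefinedStatisticError("degenerate marginals; kappa undefined")
    return float(1.0 - (w * obs).sum() / denom)


def _kappa_se(ai: np.ndarray, bi: np.ndarray, k: int, kappa: float) -> float:
    """Large-sample SE for weighted kappa (Fleiss, Cohen & Everitt 1969)."""
    n = ai.size
    v = 1.0 - quadratic_weights(k)  # agreement weights
    obs = _joint_proportions(ai, bi, k)
    p_row = obs.sum(axis=1)
    p_col = obs.sum(axis=0)
    exp = np.outer(p_row, p_col)
    p_o = (v * obs).sum()
    p_e = (v * exp).sum()
    if p_e >= 1.0:
        return 0.0
    v_row = v @ p_col          # average agreement weight of row i
    v_col = p_row @ v          # average agreement weight of column j
    term = (v - (v_row[:, None] + v_col[None, :]) * (1.0 - kappa)) ** 2
    var = ((obs * term).sum() - (kappa - p_e * (1.0 - kappa)) ** 2) / (
        n * (1.0 - p_e) ** 2
    )
    return math.sqrt(max(var, 0.0))


#: Landis-Koch verbal bands for kappa.
_KAPPA_BANDS = [
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
]


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch interpretation band for a kappa value in [-1, 1]."""
    if not (-1.0 <= kappa <= 1.0):
        raise ValueError(f"kappa out of range [-1, 1]: {kappa}")
    if kappa < 0:
        return "poor (less than chance)"
    for upper, label in _KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "almost perfect"


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def ratings_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long (case_id, rater, score_pct) table to cases x raters."""
    required = {"case_id", "rater", "score_pct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    scores = pd.to_numeric(table["score_pct"], errors="coerce")
    if scores.isna().any():
        bad = table.index[scores.isna()][0]
        raise ValueError(f"non-numeric score_pct at row {bad}")
    if (scores < 0).any() or (scores > 100).any():
        raise ValueError("score_pct must be within [0, 100]")
    wide = table.assign(score_pct=scores).pivot_table(
        index="case_id", columns="rater", values="score_pct", aggfunc="first"
    )
    return wide.sort_index()


def pairwise_agreement(
    wide: pd.DataFrame,
    bins=None,
    ci_method: str = "asymptotic",
    seed: int = 0,
) -> dict:
    """All pairwise rater statistics from a cases x raters score table.

    Continuous scores are binned with :func:`bin_category` before kappa (the
    ordinal statistic is defined on categories). Pairwise deletion handles
    missing raters.
    """
    bins = list(bins) if bins is not None else CATEGORY_LABELS
    raters = list(wide.columns)
    if len(raters) < 2:
        raise ValueError("need at least 2 raters")
    pairs = {}
    for i, ra in enumerate(raters):
        for rb in raters[i + 1 :]:
            sub = wide[[ra, rb]].dropna()
            if len(sub) < 2:
                continue
            x = sub[ra].to_numpy()
            y = sub[rb].to_numpy()
            entry: dict = {"n": int(len(sub))}
            try:
                pr = pearson(x, y)
                entry.update(
                    pearson_r=pr.r, r_ci95=list(pr.ci95), R2=pr.r2, p=pr.p
                )
                rho, _ = spearman(x, y)
                entry["spearman_rho"] = rho
            except UndefinedStatisticError as exc:
                entry["correlation_error"] = str(exc)
            entry["rmse"] = rmse(x, y)
            try:
                ka, ci = weighted_kappa(
                    [bin_category(v) for v in x],
                    [bin_category(v) for v in y],
                    bins=bins, ci_method=ci_method, seed=seed,
                )
                entry.update(
                    weighted_kappa=ka, kappa_ci95=list(ci),
                    kappa_band=interpret_kappa(ka),
                )
            except UndefinedStatisticError as exc:
                entry["kappa_error"] = str(exc)
            bias, lo, hi, _ = bland_altman(x, y)
            entry["bland_altman"] = {"bias": bias, "loa_low": lo, "loa_high": hi}
            pairs[f"{ra} vs {rb}"] = entry
    return pairs


def agreement_report(
    wide: pd.DataFrame,
    ai_rater: str | None = None,
    bins=None,
    tol: float = 5.0,
    ci_method: str = "asymptotic",
    seed: int = 0,
) -> dict:
    """Full agreement report: pairwise stats plus AI-vs-consensus metrics.

    When ``ai_rater`` names a column, the report adds that rater's agreement
    with the mean of the remaining raters: correlation, Bland-Altman,
    tolerance rate at ``tol`` percentage points, and range classification.
    """
    report: dict = {
        "raters": list(map(str, wide.columns)),
        "n_cases": int(len(wide)),
        "pairwise": pairwise_agreement(wide, bins=bins, ci_method=ci_method, seed=seed),
    }
    if ai_rater is not None:
        if ai_rater not in wide.columns:
            raise ValueError(f"rater {ai_rater!r} not in table")
        others = [c for c in wide.columns if c != ai_rater]
        if not others:
            raise ValueError("need at least one non-AI rater")
        sub = wide[wide[ai_rater].notna()]
        ai = sub[ai_rater].to_numpy()
        others_mat = sub[others].to_numpy()
        have = ~np.all(np.isnan(others_mat), axis=1)
        vs_mean: dict = {}
        if have.sum() >= 3:
            with np.errstate(invalid="ignore"):
                mean_scores = np.nanmean(others_mat[have], axis=1)
            try:
                pr = pearson(ai[have], mean_scores)
                rho, _ = spearman(ai[have], mean_scores)
                vs_mean.update(
                    pearson_r=pr.r, R2=pr.r2, r_ci95=list(pr.ci95), p=pr.p,
                    spearman_rho=rho,
                )
            except UndefinedStatisticError as exc:
                vs_mean["correlation_error"] = str(exc)
            vs_mean["rmse"] = rmse(ai[have], mean_scores)
            bias, lo, hi, _ = bland_altman(ai[have], mean_scores)
            vs_mean["bland_altman"] = {"bias": bias, "loa_low": lo, "loa_high": hi}
        rate, n_used, n_excl = tolerance_rate(ai, others_mat, tol=tol)
        vs_mean["tolerance_rate"] = rate
        vs_mean["tolerance_pp"] = tol
        vs_mean["n_cases_used"] = n_used
        vs_mean["n_cases_excluded"] = n_excl
        vs_mean["range_classification"] = range_classification(ai, others_mat)
        report["ai_vs_mean"] = vs_mean
        report["ai_rater"] = ai_rater
    return report
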