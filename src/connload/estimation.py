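"""Estimation statistics: effect sizes, BCa bootstrap intervals, rank tests,
FDR, and 2x2 chi-square tests for demographics tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EstimationResult",
    "cohen_d",
    "auroc",
    "bca_ci",
    "bca_interval",
    "rank_sum_one_tailed",
    "kruskal_wallis",
    "bh_fdr",
    "chi_square_2x2",
    "estimate_contrast",
    "demographics_tests",
]


@dataclass
class EstimationResult:
    """Pairwise contrast summary: effect sizes with BCa CIs and rank-test p."""

    cohen_d: float
    cohen_d_ci: tuple[float, float]
    auroc: float
    auroc_ci: tuple[float, float]
    p_value: float
    n_bootstrap: int
    seed: int | None


def cohen_d(x, y) -> float:
    """Standardized mean difference with the degrees-of-freedom-pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("cohen_d needs at least 2 observations per sample")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    diff = x.mean() - y.mean()
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        raise ValueError("zero pooled SD with unequal means: d is undefined")
    return float(diff / np.sqrt(pooled_var))


def auroc(cases, controls) -> float:
    """Probability a random case outranks a random control; ties count 0.5.

    Equals the Mann-Whitney U statistic of the cases divided by the number
    of case/control pairs.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    u = ranks[: cases.size].sum() - cases.size * (cases.size + 1) / 2
    return float(u / (cases.size * controls.size))


def _jackknife(statistic, x, y):
    vals = []
    for i in range(x.size):
        vals.append(statistic(np.delete(x, i), y) if y is not None else statistic(np.delete(x, i)))
    if y is not None:
        for i in range(y.size):
            vals.append(statistic(x, np.delete(y, i)))
    return np.asarray(vals, dtype=float)


def bca_interval(
    boot: np.ndarray, z0: float, accel: float, level: float = 0.95
) -> tuple[float, float]:
    """Map bias correction z0 and acceleration onto bootstrap quantiles.

    With z0 = 0 and accel = 0 this is exactly the percentile interval.
    """
    alpha = (1.0 - level) / 2.0
    z_lo, z_hi = stats.norm.ppf([alpha, 1.0 - alpha])
    a_lo = stats.norm.cdf(z0 + (z0 + z_lo) / (1.0 - accel * (z0 + z_lo)))
    a_hi = stats.norm.cdf(z0 + (z0 + z_hi) / (1.0 - accel * (z0 + z_hi)))
    lo, hi = np.quantile(boot, [a_lo, a_hi])
    return float(lo), float(hi)


def bca_ci(
    statistic,
    x,
    y=None,
    n_bootstrap: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    Samples are resampled with replacement (independently per group for a
    two-sample statistic).  The bias correction z0 comes from the fraction
    of bootstrap replicates below the point estimate; the acceleration from
    the skewness of the jackknife (leave-one-out over both samples jointly).
    """
    x = np.asarray(x, dtype=float)
    y = None if y is None else np.asarray(y, dtype=float)
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    rng = np.random.default_rng(seed)
    theta = statistic(x) if y is None else statistic(x, y)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        xb = x[rng.integers(0, x.size, x.size)]
        if y is None:
            boot[b] = statistic(xb)
        else:
            yb = y[rng.integers(0, y.size, y.size)]
            boot[b] = statistic(xb, yb)
    if np.all(boot == boot[0]):
        warnings.warn("degenerate bootstrap distribution; interval collapses")
        return float(boot[0]), float(boot[0])
    frac_below = np.mean(boot < theta)
    if frac_below == 0 or frac_below == 1:
        warnings.warn("point estimate outside bootstrap range; z0 clipped")
        frac_below = np.clip(frac_below, 0.5 / n_bootstrap, 1 - 0.5 / n_bootstrap)
    z0 = float(stats.norm.ppf(frac_below))
    jack = _jackknife(statistic, x, y)
    dev = jack.mean() - jack
    denom = np.sum(dev**2) ** 1.5
    accel = 0.0 if denom == 0 else float(np.sum(dev**3) / (6.0 * denom))
    return bca_interval(boot, z0, accel, level)


def rank_sum_one_tailed(x, y, direction: str) -> tuple[float, float]:
    """One-tailed Wilcoxon rank-sum (Mann-Whitney) test of x against y.

    ``direction`` is ``"greater"`` or ``"less"`` (x versus y).  Uses exact
    enumeration for small tie-free samples (both sizes <= 10), otherwise
    the normal approximation with midranks and tie correction.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # every pair tied: no evidence against the null in either direction
        u = x.size * y.size / 2.0
        return float(u), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=direction, method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*samples) -> tuple[float, float]:
    """Kruskal-Wallis H with midrank tie correction and chi-square p."""
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(arrays)
    if pooled.size < 5:
        raise ValueError("need at least 5 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_square_2x2(table, continuity_correction: bool = True) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, Yates-corrected by default.

    The correction subtracts 0.5 from each |observed - expected| before
    squaring and clamps at zero when |O - E| <= 0.5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs < 0) or obs.sum() == 0:
        raise ValueError("cells must be nonnegative with a positive total")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row or column margin")
    expected = row * col / obs.sum()
    dev = np.abs(obs - expected)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def estimate_contrast(
    x,
    y,
    direction: str = "greater",
    n_bootstrap: int = 5000,
    seed: int | None = None,
) -> EstimationResult:
    """Full pairwise contrast: Cohen d and AUROC with 95% BCa CIs, plus the
    one-tailed rank-sum p-value (x tested against y in ``direction``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = cohen_d(x, y)
    a = auroc(x, y)
    seed_seq = np.random.SeedSequence(seed)
    s1, s2 = seed_seq.spawn(2)
    d_ci = bca_ci(cohen_d, x, y, n_bootstrap=n_bootstrap, seed=s1)
    a_ci = bca_ci(auroc, x, y, n_bootstrap=n_bootstrap, seed=s2)
    _, p = rank_sum_one_tailed(x, y, direction)
    return EstimationResult(d, d_ci, a, a_ci, p, n_bootstrap, seed)


def demographics_tests(manifest_table: pd.DataFrame) -> pd.DataFrame:
    """Chi-square tests on 2x2 group-by-category demographics tables.

    Compares the two patient groups on every available binary column among
    sex, side, hs (hippocampal sclerosis), and outcome.
    """
    df = manifest_table
    groups = ("FBTCS+", "FBTCS-")
    binary_specs = {
        "sex": ("M", "F"),
        "side": ("left", "right"),
        "hs": ("yes", "no"),
        "outcome": ("seizure_free", "not_seizure_free"),
    }
    rows = []
    for col, (lvl_a, lvl_b) in binary_specs.items():
        if col not in df.columns:
            continue
        sub = df[df["group"].isin(groups)]
        table = [
            [
                int(((sub["group"] == g) & (sub[col].astype(str) == lvl)).sum())
                for lvl in (lvl_a, lvl_b)
            ]
            for g in groups
        ]
        if any(sum(r) == 0 for r in table):
            continue
        chi2, p = chi_square_2x2(table)
        rows.append(
            {
                "variable": col,
                "groups": f"{groups[0]} vs {groups[1]}",
                "table": table,
                "chi2": round(chi2, 2),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
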