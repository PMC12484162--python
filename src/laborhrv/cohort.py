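"""Cohort-level statistics: exclusions, normality gate, Spearman tables.

The cohort is a :class:`pandas.DataFrame` with one row per subject and
documented columns (see :data:`COHORT_COLUMNS`).  Analysis follows the
study logic: subjects delivering for non-physiological reasons (induction,
cesarean) or with poorly detectable R peaks are excluded; time to delivery
is gestational age at delivery minus gestational age at recording (decimal
weeks); distributions are screened with a Monte-Carlo Lilliefors test; and
associations are quantified with Spearman rank correlation, with 95%
confidence intervals from the Fisher z transform using the Bonett–Wright
standard error.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COHORT_COLUMNS", "METRIC_COLUMNS", "OUTCOME_COLUMNS",
    "CorrelationResult",
    "apply_exclusions", "time_to_delivery",
    "lilliefors_null", "lilliefors_test",
    "spearman_with_ci", "correlation_table", "demographics_summary",
    "format_correlation_table",
]

#: Canonical cohort-table columns.
COHORT_COLUMNS = [
    "subject_id", "age", "bmi", "ga_recording", "ga_delivery", "ttd",
    "delivery_mode", "quality_ok",
    "mean_rr", "sdnn", "rmssd", "vlf_ln", "lf_ln", "hf_ln", "lf_hf",
]

#: HRV metric columns correlated against each outcome, in report order.
METRIC_COLUMNS = ["mean_rr", "sdnn", "rmssd", "vlf_ln", "lf_ln", "hf_ln", "lf_hf"]
_METRIC_LABELS = {
    "mean_rr": "RR (ms)", "sdnn": "SDNN (ms)", "rmssd": "RMSSD (ms)",
    "vlf_ln": "VLF (Ln)", "lf_ln": "LF (Ln)", "hf_ln": "HF (Ln)",
    "lf_hf": "LF/HF",
}

#: Gestational outcomes; time to delivery is the primary one.
OUTCOME_COLUMNS = ["ga_recording", "ga_delivery", "ttd"]
PRIMARY_OUTCOME = "ttd"


@dataclass
class CorrelationResult:
    """Spearman rho with p-value and 95% CI for one (metric, outcome) pair."""

    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    method_notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.r <= 1.0 + 1e-9):
            raise ValueError("rho must lie in [-1, 1]")
        if not (self.ci_low - 1e-9 <= self.r <= self.ci_high + 1e-9):
            raise ValueError("CI must contain the point estimate")


# --------------------------------------------------------------------------
# exclusions and time to delivery
# --------------------------------------------------------------------------

def apply_exclusions(cohort: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Remove non-physiological deliveries and quality failures.

    A subject is excluded if delivery was induced or by cesarean section,
    or if ``quality_ok`` is False (poorly detectable R peaks).  Each
    subject is counted under a single reason, delivery mode taking
    precedence, so the log adds up to the number removed.  The operation
    is idempotent and order-independent.
    """
    mode = cohort["delivery_mode"]
    quality = cohort["quality_ok"].astype(bool)
    induced = mode == "induced"
    cesarean = mode == "cesarean"
    poor = ~quality & ~(induced | cesarean)
    keep = ~(induced | cesarean) & quality
    log = {
        "induced": int(induced.sum()),
        "cesarean": int(cesarean.sum()),
        "poorly detectable R peaks": int(poor.sum()),
    }
    kept = cohort.loc[keep].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("no subjects remain after exclusions")
    return kept, log


def time_to_delivery(ga_delivery, ga_recording):
    """GA at delivery minus GA at recording, in decimal weeks.

    Accepts scalars or arrays; a negative difference indicates a data-entry
    error and raises.
    """
    diff = np.asarray(ga_delivery, dtype=float) - np.asarray(ga_recording, dtype=float)
    if np.any(diff < 0):
        raise ValueError("GA at delivery precedes GA at recording")
    if diff.ndim == 0:
        return float(diff)
    return diff


# --------------------------------------------------------------------------
# Lilliefors normality test
# --------------------------------------------------------------------------

def _lilliefors_statistic(x: np.ndarray) -> float:
    """KS distance to a normal with mean and SD estimated from the sample."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    cdf = stats.norm.cdf((x - np.mean(x)) / sd)
    up = np.arange(1, n + 1) / n - cdf
    lo = cdf - np.arange(0, n) / n
    return float(max(up.max(), lo.max()))


def lilliefors_null(n: int, n_mc: int = 10_000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors statistic at size n.

    Simulates Gaussian samples and re-estimates mean and SD for each, i.e.
    the same estimation step as the test itself.  The null depends only on
    n, so the returned statistics can be reused across many tests.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_mc, n))
    z.sort(axis=1)
    mu = z.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, ddof=1, keepdims=True)
    cdf = stats.norm.cdf((z - mu) / sd)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
    return d


def lilliefors_test(
    x: Sequence[float],
    n_mc: int = 10_000,
    seed: int = 0,
    null_stats: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Lilliefors normality test with a simulated null.

    Returns ``(statistic, p)``.  The p-value is the add-one Monte-Carlo
    estimate against ``n_mc`` simulated Gaussian samples of the same size
    (pass ``null_stats`` from :func:`lilliefors_null` to reuse a
    precomputed table).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    d = _lilliefors_statistic(x)
    if null_stats is None:
        null_stats = lilliefors_null(len(x), n_mc=n_mc, seed=seed)
    p = (1.0 + np.sum(null_stats >= d)) / (len(null_stats) + 1.0)
    return d, float(p)


# --------------------------------------------------------------------------
# Spearman correlation
# --------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("constant input: correlation undefined")
    return float(rx @ ry) / denom


#: Exhaustive permutation p-values are used up to this sample size
#: (9! = 362,880 orderings; 10! is impractical).
EXACT_PERMUTATION_MAX_N = 9


def spearman_with_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> CorrelationResult:
    """Spearman rank correlation with p-value and confidence interval.

    Ties get mid-ranks.  The p-value is exact (full enumeration of the
    permutation distribution, two-sided) for n <= 9 and the usual
    t-approximation otherwise.  The CI is Fisher-z based with the
    Bonett–Wright standard error ``sqrt((1 + rho^2 / 2) / (n - 3))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rank_corr(rx, ry)

    if n <= EXACT_PERMUTATION_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        rho_perm = (ry_c[perms] @ rx_c) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        p_method = "exact permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
        p_method = "t approximation"

    if n > 3 and abs(rho) < 1.0:
        z = math.atanh(rho)
        se = math.sqrt((1.0 + rho**2 / 2.0) / (n - 3))
        zc = stats.norm.ppf(1.0 - alpha / 2.0)
        ci_low, ci_high = math.tanh(z - zc * se), math.tanh(z + zc * se)
    else:
        ci_low, ci_high = rho, rho

    return CorrelationResult(
        r=rho, p=p, ci_low=ci_low, ci_high=ci_high, n=n,
        method_notes={"p_method": p_method, "ci": "Fisher z, Bonett-Wright SE",
                      "alpha": alpha},
    )


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

def correlation_table(
    cohort: pd.DataFrame,
    metrics: Iterable[str] = METRIC_COLUMNS,
    outcomes: Iterable[str] = OUTCOME_COLUMNS,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Metric-by-outcome Spearman correlation table.

    One row per HRV metric; per outcome the columns hold r, CI bounds, p
    and n, plus a mean ± SD summary of the metric.  The primary analysis
    concerns the time-to-delivery column (``primary_outcome`` attribute).
    With ``bh_correct`` a Benjamini–Hochberg adjusted p (within each
    outcome) is reported alongside, never replacing the raw p.
    """
    metrics = list(metrics)
    outcomes = list(outcomes)
    missing = [m for m in metrics if m not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table lacks metric columns {missing}")
    rows = []
    for m in metrics:
        vals = cohort[m].to_numpy(dtype=float)
        row: dict = {
            "metric": m,
            "label": _METRIC_LABELS.get(m, m),
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        }
        for o in outcomes:
            res = spearman_with_ci(vals, cohort[o].to_numpy(dtype=float), alpha=alpha)
            row[f"{o}_r"] = res.r
            row[f"{o}_ci_low"] = res.ci_low
            row[f"{o}_ci_high"] = res.ci_high
            row[f"{o}_p"] = res.p
            row[f"{o}_n"] = res.n
        rows.append(row)
    table = pd.DataFrame(rows)
    if bh_correct:
        for o in outcomes:
            table[f"{o}_p_bh"] = _benjamini_hochberg(table[f"{o}_p"].to_numpy())
    table.attrs["primary_outcome"] = PRIMARY_OUTCOME
    table.attrs["alpha"] = alpha
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def format_correlation_table(table: pd.DataFrame) -> str:
    """Human-readable rendering, one metric per row, outcomes as columns."""
    outcome_labels = {
        "ga_recording": "GA at recording",
        "ga_delivery": "GA at delivery",
        "ttd": "Time to delivery (primary)",
    }
    outcomes = [o for o in OUTCOME_COLUMNS if f"{o}_r" in table.columns]
    lines = []
    header = f"{'Feature':<12} {'Mean±SD':>14}"
    for o in outcomes:
        header += f"  {outcome_labels.get(o, o):>38}"
    lines.append(header)
    for _, row in table.iterrows():
        line = f"{row['label']:<12} {row['mean']:>7.2f}±{row['sd']:<6.2f}"
        for o in outcomes:
            cell = (f"r={row[f'{o}_r']:+.2f} "
                    f"[{row[f'{o}_ci_low']:+.2f},{row[f'{o}_ci_high']:+.2f}] "
                    f"p={row[f'{o}_p']:.4f}")
            line += f"  {cell:>38}"
        lines.append(line)
    lines.append("Primary analysis: HRV vs time to delivery (last column).")
    return "\n".join(lines)


def demographics_summary(
    cohort: pd.DataFrame, group_by: Optional[str] = None
) -> pd.DataFrame:
    """Count and mean ± SD of age, BMI and GA fields, optionally per group.

    A single-subject group reports SD 0 with ``sd_defined = False``.
    """
    fields = ["age", "bmi", "ga_recording", "ga_delivery"]
    groups = (
        [(label, g) for label, g in cohort.groupby(group_by)]
        if group_by else [("all", cohort)]
    )
    rows = []
    for label, g in groups:
        row: dict = {"group": label, "n": len(g)}
        for f in fields:
            vals = g[f].dropna().to_numpy(dtype=float) if f in g else np.array([])
            if len(vals) == 0:
                row[f"{f}_mean"] = np.nan
                row[f"{f}_sd"] = np.nan
                row[f"{f}_sd_defined"] = False
            else:
                row[f"{f}_mean"] = float(np.mean(vals))
                row[f"{f}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                row[f"{f}_sd_defined"] = len(vals) > 1
        rows.append(row)
    return pd.DataFrame(rows)
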