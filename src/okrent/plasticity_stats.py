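"""Homeostatic-plasticity statistics on per-cycle amplitude tables.

Per animal: the *immediate* response I (mean peak-to-peak amplitude over the
first five valid stimulus cycles) and the *entrained* response E (mean over
the last five valid cycles) of a 30-min training session.  Per cohort: the
ordinary least-squares regression of the amplitude change dA = E - I on I,
whose slope quantifies how strongly the plasticity depends on the starting
amplitude and whose x-axis zero-intercept x0 = -intercept/slope estimates
the homeostatic setpoint (the initial amplitude at which training induces no
net change).  Also: variability (SD) homogenization metrics, population
per-cycle averages, and the nonparametric tests used for group comparisons
(exact Wilcoxon signed-rank and Mann-Whitney U by enumeration at small n,
tie-corrected normal approximations otherwise; Kruskal-Wallis with Dunn's
Bonferroni-adjusted post hoc).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Width of the immediate/entrained measurement windows (cycles).
N_EDGE = 5

#: Largest sample size for which exact enumeration p-values are computed.
EXACT_WILCOXON_MAX_N = 12
EXACT_MWU_MAX_N = 12

#: |slope| below which the x-axis zero-intercept is reported undefined.
SLOPE_TOLERANCE = 1e-6


@dataclass(frozen=True)
class AnimalSummary:
    """Immediate/entrained response amplitudes of one animal (deg)."""

    animal_id: str
    immediate: float
    entrained: float
    group: str = ""
    profile_id: int = 0

    def __post_init__(self) -> None:
        if self.immediate < 0 or self.entrained < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def delta(self) -> float:
        """Training-induced amplitude change E - I (deg)."""
        return self.entrained - self.immediate


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of amplitude change on immediate amplitude."""

    slope: float
    intercept: float
    r_squared: float
    x_zero_intercept: float | None
    slope_se: float
    intercept_se: float
    n: int
    x_mean: float
    ss_x: float
    residual_var: float

    def confidence_band(self, x: np.ndarray, level: float = 0.95):
        """(lower, upper) of the confidence band of the fitted mean at ``x``."""
        x = np.asarray(x, dtype=float)
        fit = self.intercept + self.slope * x
        tcrit = sps.t.ppf(0.5 + level / 2.0, self.n - 2)
        se = np.sqrt(
            self.residual_var * (1.0 / self.n + (x - self.x_mean) ** 2 / self.ss_x)
        )
        return fit - tcrit * se, fit + tcrit * se


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool
    n: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# per-animal summaries
# ---------------------------------------------------------------------------

def immediate_entrained(
    table: pd.DataFrame,
    n_edge: int = N_EDGE,
    animal_id: str = "",
    group: str = "",
    profile_id: int = 0,
) -> AnimalSummary:
    """Mean peak-to-peak amplitude over the first/last ``n_edge`` valid cycles.

    Invalid cycles (edge, fast phase, missing) are skipped and the window
    extended, so I is always the mean of the first ``n_edge`` *valid* cycles
    and E of the last ``n_edge``.
    """
    valid = table[table["valid"] & np.isfinite(table["pp_deg"])]
    valid = valid.sort_values("cycle_index")
    if len(valid) < 2 * n_edge:
        raise ValueError(
            f"too few valid cycles: {len(valid)} < {2 * n_edge} required"
        )
    immediate = float(valid["pp_deg"].head(n_edge).mean())
    entrained = float(valid["pp_deg"].tail(n_edge).mean())
    return AnimalSummary(
        animal_id=animal_id,
        immediate=immediate,
        entrained=entrained,
        group=group,
        profile_id=profile_id,
    )


def summaries_frame(summaries: list[AnimalSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in summaries],
            "group": [s.group for s in summaries],
            "profile_id": [s.profile_id for s in summaries],
            "immediate_deg": [s.immediate for s in summaries],
            "entrained_deg": [s.entrained for s in summaries],
            "delta_deg": [s.delta for s in summaries],
        }
    )


# ---------------------------------------------------------------------------
# setpoint regression
# ---------------------------------------------------------------------------

def regress_change(summaries: list[AnimalSummary]) -> RegressionResult:
    """OLS of the amplitude change dA = E - I on the immediate amplitude I.

    The x-axis zero-intercept -intercept/slope is the estimated homeostatic
    setpoint; it is reported as None (undefined) when |slope| is below
    :data:`SLOPE_TOLERANCE`, where the ratio would be numerically meaningless.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 animals for the regression")
    x = np.array([s.immediate for s in summaries])
    y = np.array([s.delta for s in summaries])
    if np.ptp(x) == 0:
        raise ValueError("degenerate cohort: all immediate amplitudes identical")
    fit = sps.linregress(x, y)
    n = x.size
    resid = y - (fit.intercept + fit.slope * x)
    residual_var = float(resid @ resid) / (n - 2) if n > 2 else 0.0
    if abs(fit.slope) > SLOPE_TOLERANCE:
        x_zero = -fit.intercept / fit.slope
    else:
        x_zero = None
        logger.warning("slope ~ 0: x-axis zero-intercept undefined")
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        x_zero_intercept=x_zero,
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
        n=n,
        x_mean=float(x.mean()),
        ss_x=float(((x - x.mean()) ** 2).sum()),
        residual_var=residual_var,
    )


def variability_metrics(summaries: list[AnimalSummary]) -> pd.DataFrame:
    """SD of immediate and entrained amplitudes per (group, paradigm) + pooled.

    The homeostatic homogenization signature is SD(E) < SD(I); this function
    reports the numbers, it does not assert the comparison.
    """
    frame = summaries_frame(summaries)
    rows = []

    def _row(sub: pd.DataFrame, group: str, profile_id) -> dict:
        return {
            "group": group,
            "profile_id": profile_id,
            "n": len(sub),
            "sd_immediate_deg": float(sub["immediate_deg"].std(ddof=1))
            if len(sub) > 1
            else np.nan,
            "sd_entrained_deg": float(sub["entrained_deg"].std(ddof=1))
            if len(sub) > 1
            else np.nan,
        }

    for (group, pid), sub in frame.groupby(["group", "profile_id"]):
        rows.append(_row(sub, group, pid))
    for group, sub in frame.groupby("group"):
        rows.append(_row(sub, group, "pooled"))
    return pd.DataFrame(rows)


def population_cycle_average(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean peak-to-peak amplitude per cycle index across animals.

    Invalid cycles are excluded per index; a cycle index with zero
    contributors yields NaN (a gap, not zero).  An animal whose table has no
    valid cycles at all is excluded with a warning.
    """
    usable = []
    for i, table in enumerate(tables):
        if table["valid"].any():
            usable.append(table)
        else:
            logger.warning("animal %d has no valid cycles; excluded", i)
    if not usable:
        raise ValueError("no animals with valid cycles")
    max_index = max(int(t["cycle_index"].max()) for t in usable)
    idx = np.arange(1, max_index + 1)
    values = np.full((len(usable), idx.size), np.nan)
    for row, table in enumerate(usable):
        ok = table[table["valid"] & np.isfinite(table["pp_deg"])]
        values[row, ok["cycle_index"].to_numpy(dtype=int) - 1] = ok["pp_deg"]
    n_contrib = np.isfinite(values).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1)
    mean[n_contrib == 0] = np.nan
    return pd.DataFrame(
        {"cycle_index": idx, "mean_pp_deg": mean, "sd_pp_deg": sd, "n": n_contrib}
    )


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def _two_sided_tail(values: np.ndarray, observed: float, mean: float) -> float:
    """P(|V - mean| >= |observed - mean|) over an enumerated null distribution."""
    dev = abs(observed - mean) - 1e-12
    return float(np.mean(np.abs(values - mean) >= dev))


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (error if none remain or fewer than 5 pairs
    survive).  For n <= 12 the p-value is exact, by enumeration of all 2^n
    sign assignments of the (mid-)ranked |differences| (valid under ties);
    otherwise a normal approximation with Var(W+) = sum(r_i^2)/4, which
    equals the classical tie-corrected variance for midranks.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError("need at least 5 nonzero paired differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = ranks.sum() / 2.0
    if n <= EXACT_WILCOXON_MAX_N:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        null = bits @ ranks
        p = _two_sided_tail(null, w_plus, mean)
        exact = True
    else:
        sigma = math.sqrt(float(ranks @ ranks) / 4.0)
        z = (w_plus - mean) / sigma
        p = 2.0 * sps.norm.sf(abs(z))
        exact = False
    return TestResult(
        statistic=w_plus,
        p_value=min(p, 1.0),
        method="wilcoxon",
        exact=exact,
        n=n,
    )


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    Exact p by enumeration of all C(nx+ny, nx) group assignments when
    nx + ny <= 12 and the pooled sample is tie-free; otherwise the normal
    approximation with the classical tie correction.  The reported statistic
    is U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    mean = nx * ny / 2.0
    n_total = nx + ny
    has_ties = np.unique(pooled).size < n_total
    if n_total <= EXACT_MWU_MAX_N and not has_ties:
        rank_values = np.arange(1, n_total + 1, dtype=float)
        null = np.array(
            [
                sum(rank_values[list(c)]) - nx * (nx + 1) / 2.0
                for c in combinations(range(n_total), nx)
            ]
        )
        p = _two_sided_tail(null, u_x, mean)
        exact = True
    else:
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum()) / (n_total * (n_total - 1))
        var = nx * ny / 12.0 * ((n_total + 1) - tie_term)
        if var <= 0:
            raise ValueError("zero variance: all pooled values identical")
        z = (u_x - mean) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
        exact = False
    return TestResult(
        statistic=u_x,
        p_value=min(p, 1.0),
        method="mann_whitney",
        exact=exact,
        n=n_total,
    )


def kruskal_dunn(
    groups: list[np.ndarray], labels: list[str] | None = None
) -> tuple[TestResult, dict[tuple[str, str], TestResult]]:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post hoc.

    Dunn z-statistics use the pooled mean ranks with the standard tie
    correction; pairwise p-values are Bonferroni-adjusted over all pairs
    (the multiple-comparison correction applied with Dunn's test here).
    Requires >= 3 groups of >= 2 observations each.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    h, p_omnibus = sps.kruskal(*groups)
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(float(ranks[start : start + size].mean()))
        start += size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    pairwise: dict[tuple[str, str], TestResult] = {}
    for i, j in combinations(range(len(groups)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_adj = min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_pairs)
        pairwise[(labels[i], labels[j])] = TestResult(
            statistic=float(z),
            p_value=p_adj,
            method="kruskal_dunn",
            exact=False,
            n=sizes[i] + sizes[j],
            extra={"adjustment": "bonferroni"},
        )
    omnibus = TestResult(
        statistic=float(h),
        p_value=float(p_omnibus),
        method="kruskal_dunn",
        exact=False,
        n=n_total,
        extra={"k_groups": len(groups)},
    )
    return omnibus, pairwise
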