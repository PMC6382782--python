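"""Clinical score conversion and the longitudinal statistical battery.

Implements the analysis run over the three-timepoint cohort table:

* visual acuity conversion to logMAR (counting fingers 2.0, hand motion
  2.30 by convention), and the mean M-CHARTS score (average of the
  vertical and horizontal metamorphopsia scores);
* per-outcome Friedman tests across the three timepoints with
  Bonferroni-corrected pairwise Wilcoxon signed-rank post hocs;
* Mann-Whitney U comparisons of MV vs MH and of vertical vs horizontal
  fold counts at each timepoint (the study's stated test, kept although
  the design is paired; a paired alternative is available via
  ``paired_mv_mh=True``);
* a Spearman rank-correlation table between fold metrics at earlier
  timepoints and mean M-CHARTS at the same or later timepoints.

All tests are thin, explicitly-parameterised wrappers over
``scipy.stats``; Spearman p-values use exact permutation enumeration for
n <= 10 and the t approximation above.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "to_logmar",
    "mean_mcharts",
    "spearman",
    "longitudinal_tests",
    "correlation_table",
    "StatsReport",
]

#: outcome column -> label used in reports
OUTCOME_COLUMNS = {
    "bcva_logmar": "bcva",
    "mv": "mv",
    "mh": "mh",
    "mean_mcharts": "mean_mcharts",
    "density_pct": "density",
    "n_total": "n_total",
    "n_vertical": "n_vertical",
    "n_horizontal": "n_horizontal",
    "mean_length_px": "mean_length",
    "mean_width_px": "mean_width",
}

FOLD_METRICS = ("density_pct", "n_total")


def to_logmar(acuity) -> float:
    """Convert a decimal visual acuity (or category token) to logMAR.

    Decimal fraction v -> -log10(v); the categories "CF" (counting
    fingers) and "HM" (hand motion) map to 2.0 and 2.30 logMAR.
    """
    if isinstance(acuity, str):
        token = acuity.strip().upper()
        if token == "CF":
            return 2.0
        if token == "HM":
            return 2.30
        raise ValueError(f"unrecognized acuity token {acuity!r}")
    v = float(acuity)
    if v <= 0:
        raise ValueError(f"decimal acuity must be positive, got {v}")
    return -math.log10(v)


def mean_mcharts(mv: float, mh: float) -> float:
    """Mean M-CHARTS score: arithmetic mean of vertical and horizontal."""
    if mv < 0 or mh < 0:
        raise ValueError("M-CHARTS scores must be >= 0")
    return (mv + mh) / 2.0


@dataclass
class StatsReport:
    """Container for the full battery; tables are tidy DataFrames."""

    friedman: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    group_comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    spearman: pd.DataFrame = field(default_factory=pd.DataFrame)
    alpha: float = 0.05


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided permutation p for Spearman r, full enumeration (n <= 10)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    count = 0
    total = 0
    chunk = []
    thresh = abs(r_obs) - 1e-12

    def flush(chunk):
        nonlocal count, total
        P = np.array(chunk)
        rs = (P @ ry) / denom
        count += int((np.abs(rs) >= thresh).sum())
        total += len(P)

    for perm in itertools.permutations(rx):
        chunk.append(perm)
        if len(chunk) == 100_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and two-sided p.

    Exact permutation p for n <= 10, t approximation for larger n.
    Returns (nan, nan) when either variable is constant (the correlation
    is undefined, not zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r = float(stats.spearmanr(x, y).statistic)
    if n <= 10:
        p = _spearman_exact_p(x, y, r)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return r, min(p, 1.0)


def _wilcoxon(a: np.ndarray, b: np.ndarray, zero_method: str = "pratt"):
    """Paired Wilcoxon signed-rank: exact for n < 25 when possible."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.all(d == 0):
        return 0.0, 1.0
    n = int((d != 0).sum())
    has_ties = len(np.unique(np.abs(d[d != 0]))) < n
    has_zeros = bool(np.any(d == 0))
    if n < 25 and not has_ties and not has_zeros:
        res = stats.wilcoxon(a, b, zero_method=zero_method, method="exact")
    else:
        res = stats.wilcoxon(
            a, b, zero_method=zero_method, method="approx", correction=True
        )
    return float(res.statistic), float(res.pvalue)


def _check_complete(cohort: pd.DataFrame, timepoints) -> None:
    counts = cohort.groupby("eye_id")["timepoint"].nunique()
    bad = counts[counts < len(timepoints)]
    if len(bad):
        raise ValueError(
            "eyes missing timepoints: " + ", ".join(map(str, bad.index.tolist()))
        )


def longitudinal_tests(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    paired_mv_mh: bool = False,
) -> StatsReport:
    """Friedman + post-hoc battery over the three-timepoint cohort table.

    For every outcome present in the table, computes the Friedman test
    across timepoints; when its p < ``alpha``, pairwise Wilcoxon
    signed-rank tests with a Bonferroni factor of 3 are run.  MV vs MH and
    vertical vs horizontal counts are compared at each timepoint with
    Mann-Whitney U (or Wilcoxon signed-rank if ``paired_mv_mh``).

    The cohort table must contain one row per (eye, timepoint) for every
    timepoint; eyes with missing visits raise a ValueError naming them.
    """
    tps = list(dict.fromkeys(cohort["timepoint"]))
    if len(tps) != 3:
        raise ValueError(f"expected 3 timepoints, found {tps}")
    _check_complete(cohort, tps)
    wide = {
        tp: cohort[cohort["timepoint"] == tp].set_index("eye_id").sort_index()
        for tp in tps
    }
    n_eyes = len(wide[tps[0]])
    if n_eyes < 3:
        raise ValueError("need at least 3 eyes")

    fried_rows, pair_rows = [], []
    outcomes = [c for c in OUTCOME_COLUMNS if c in cohort.columns]
    for col in outcomes:
        label = OUTCOME_COLUMNS[col]
        samples = [wide[tp][col].to_numpy(dtype=float) for tp in tps]
        if all(np.array_equal(samples[0], s) for s in samples[1:]):
            # every eye identical across timepoints: all within-eye ranks
            # tie, the statistic is 0 and the tie correction degenerates
            statistic, p = 0.0, 1.0
        else:
            res = stats.friedmanchisquare(*samples)
            statistic, p = float(res.statistic), float(res.pvalue)
        fried_rows.append(
            {"outcome": label, "statistic": statistic, "p": p, "n": n_eyes}
        )
        if p < alpha:
            for t1, t2 in itertools.combinations(range(3), 2):
                w, praw = _wilcoxon(samples[t1], samples[t2])
                pair_rows.append(
                    {
                        "outcome": label,
                        "comparison": f"{tps[t1]} vs {tps[t2]}",
                        "statistic": w,
                        "p_raw": praw,
                        "p_bonferroni": min(1.0, praw * 3),
                    }
                )

    group_rows = []
    for tp in tps:
        pairs = [("mv", "mh", "mv vs mh")]
        if "n_vertical" in cohort.columns and "n_horizontal" in cohort.columns:
            pairs.append(("n_vertical", "n_horizontal", "vertical vs horizontal"))
        for ca, cb, label in pairs:
            if ca not in cohort.columns or cb not in cohort.columns:
                continue
            a = wide[tp][ca].to_numpy(dtype=float)
            b = wide[tp][cb].to_numpy(dtype=float)
            if paired_mv_mh:
                u, p = _wilcoxon(a, b)
                test = "wilcoxon"
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                u, p, test = float(res.statistic), float(res.pvalue), "mannwhitneyu"
            group_rows.append(
                {
                    "timepoint": tp,
                    "comparison": label,
                    "test": test,
                    "statistic": u,
                    "p": p,
                }
            )

    return StatsReport(
        friedman=pd.DataFrame(fried_rows),
        pairwise=pd.DataFrame(pair_rows),
        group_comparisons=pd.DataFrame(group_rows),
        spearman=correlation_table(cohort),
        alpha=alpha,
    )


def correlation_table(
    cohort: pd.DataFrame,
    fold_metrics: tuple[str, ...] = FOLD_METRICS,
) -> pd.DataFrame:
    """Spearman table: fold metric at t1 vs mean M-CHARTS at t2 >= t1.

    Reproduces the upper-triangular layout of the study's correlation
    table: each fold metric at an earlier or equal timepoint against the
    mean M-CHARTS score at the same or later timepoint.  Undefined
    correlations (a constant column) are reported as NaN, not zero.
    """
    tps = list(dict.fromkeys(cohort["timepoint"]))
    _check_complete(cohort, tps)
    wide = {
        tp: cohort[cohort["timepoint"] == tp].set_index("eye_id").sort_index()
        for tp in tps
    }
    rows = []
    for metric in fold_metrics:
        if metric not in cohort.columns:
            continue
        for i, t1 in enumerate(tps):
            for t2 in tps[i:]:
                x = wide[t1][metric].to_numpy(dtype=float)
                y = wide[t2]["mean_mcharts"].to_numpy(dtype=float)
                r, p = spearman(x, y)
                rows.append(
                    {
                        "metric": OUTCOME_COLUMNS.get(metric, metric),
                        "metric_timepoint": t1,
                        "mcharts_timepoint": t2,
                        "r": r,
                        "p": p,
                        "n": len(x),
                    }
                )
    return pd.DataFrame(rows)
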