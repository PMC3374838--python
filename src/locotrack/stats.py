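"""Population-level summaries and hypothesis tests.

The analysis treats each track's summary statistic as one independent
measurement.  Tracks are grouped into half-open average-speed bins
[k*w, (k+1)*w) so that populations can be compared at matched speeds;
per-bin means and SEMs give the binned curves, a two-way ANOVA
(genotype + speed bin, main effects, Type-II sums of squares on the
unbalanced design) tests for a genotype effect across the curve, and a
Student's (pooled-variance) t-test compares pairs of points or average
speeds.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "SpeedHistogram",
    "BinnedSummary",
    "AnovaResult",
    "population_average_speed",
    "speed_histogram",
    "bin_tracks_by_avg_speed",
    "two_way_anova",
    "t_test",
]


@dataclass
class SpeedHistogram:
    """Fraction of time spent at each speed, in uniform half-open bins."""

    bin_edges: np.ndarray  # mm/s, length n_bins + 1
    fraction_of_time: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "fraction": self.fraction_of_time,
            }
        )


@dataclass
class BinnedSummary:
    """Per-speed-bin mean and SEM of one per-track statistic.

    ``table`` columns: bin_lo, bin_hi, n, mean, sem (sem is NaN where
    n < 2).  Bins with no tracks are omitted entirely, never reported as
    zero.
    """

    field: str
    bin_width: float
    label: str | None
    table: pd.DataFrame


@dataclass
class AnovaResult:
    factors: list[str]
    f: dict[str, float]
    p: dict[str, float]
    df: dict[str, float]
    df_resid: float

    @property
    def genotype_p(self) -> float:
        return self.p["genotype"]


def population_average_speed(smoothed_speeds: list[np.ndarray]) -> float:
    """Mean of all pooled instantaneous (smoothed) speed samples across
    tracks — long tracks weigh more, by definition."""
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in smoothed_speeds]) if smoothed_speeds else np.empty(0)
    if pooled.size == 0:
        raise ValueError("no speed samples to average")
    return float(pooled.mean())


def speed_histogram(
    smoothed_speeds: list[np.ndarray], bin_width: float = 0.006
) -> SpeedHistogram:
    """Histogram of pooled smoothed speeds as fractions of time.

    Bins are half-open [k*w, (k+1)*w) starting at 0; fractions sum to 1.
    The 0.006 mm/s default is the conventional width for full-resolution
    speed distributions.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in smoothed_speeds]) if smoothed_speeds else np.empty(0)
    if pooled.size == 0:
        raise ValueError("no speed samples to histogram")
    n_bins = int(np.floor(pooled.max() / bin_width)) + 1
    idx = np.floor(pooled / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    return SpeedHistogram(bin_edges=edges, fraction_of_time=counts / pooled.size)


def speed_bin_of(avg_speed: float | np.ndarray, bin_width: float) -> np.ndarray:
    """Half-open bin index floor(avg_speed / width)."""
    return np.floor(np.asarray(avg_speed, dtype=float) / bin_width).astype(int)


def bin_tracks_by_avg_speed(
    stats: pd.DataFrame,
    field: str,
    bin_width: float = 0.03,
    label: str | None = None,
) -> BinnedSummary:
    """Bin per-track statistics by average speed and summarize per bin.

    ``stats`` is a per-track table with at least ``avg_speed`` and
    ``field`` columns (see ``kinematics.stats_table``).  Each track falls
    in bin floor(avg_speed / bin_width); each track is one independent
    measurement, so the per-bin SEM is sample SD / sqrt(n).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if field not in stats.columns:
        raise KeyError(f"unknown per-track field {field!r}")
    df = stats.dropna(subset=[field]).copy()
    df["_bin"] = speed_bin_of(df["avg_speed"].to_numpy(), bin_width)
    rows = []
    for b, grp in df.groupby("_bin", sort=True):
        vals = grp[field].to_numpy(dtype=float)
        n = len(vals)
        rows.append(
            {
                "bin_lo": b * bin_width,
                "bin_hi": (b + 1) * bin_width,
                "n": n,
                "mean": vals.mean(),
                "sem": vals.std(ddof=1) / math.sqrt(n) if n >= 2 else np.nan,
            }
        )
    return BinnedSummary(
        field=field, bin_width=bin_width, label=label, table=pd.DataFrame(rows)
    )


def two_way_anova(
    values: np.ndarray,
    genotype: np.ndarray,
    speed_bin: np.ndarray,
    interaction: bool = False,
    min_bin_n: int = 2,
) -> AnovaResult:
    """Two-way ANOVA of a per-track statistic on genotype and speed bin.

    Fits the main-effects linear model ``value ~ C(genotype) + C(speed_bin)``
    by least squares on the (generally unbalanced) design and reports
    Type-II F tests.  Speed bins holding fewer than ``min_bin_n`` tracks are
    excluded (no within-bin variance to estimate); an optional interaction
    term is available but off by default.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "genotype": np.asarray(genotype, dtype=object),
            "speed_bin": np.asarray(speed_bin),
        }
    ).dropna(subset=["value"])
    counts = df.groupby("speed_bin")["value"].count()
    keep = counts[counts >= min_bin_n].index
    df = df[df["speed_bin"].isin(keep)]
    if df["genotype"].nunique() < 2:
        raise ValueError("degenerate design: need >= 2 genotypes with data")
    if df["speed_bin"].nunique() < 2:
        raise ValueError("degenerate design: need >= 2 occupied speed bins")
    formula = "value ~ C(genotype) + C(speed_bin)"
    if interaction:
        formula += " + C(genotype):C(speed_bin)"
    fit = smf.ols(formula, data=df).fit()
    tab = anova_lm(fit, typ=2)
    name_map = {"C(genotype)": "genotype", "C(speed_bin)": "speed_bin",
                "C(genotype):C(speed_bin)": "genotype:speed_bin"}
    f, p, dof = {}, {}, {}
    for raw, nice in name_map.items():
        if raw in tab.index:
            f[nice] = float(tab.loc[raw, "F"])
            p[nice] = float(tab.loc[raw, "PR(>F)"])
            dof[nice] = float(tab.loc[raw, "df"])
    return AnovaResult(
        factors=list(f),
        f=f,
        p=p,
        df=dof,
        df_resid=float(tab.loc["Residual", "df"]),
    )


def t_test(a: np.ndarray, b: np.ndarray, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test (Student's pooled-variance by default;
    set ``equal_var=False`` for Welch).

    Degenerate variance is handled by convention: if both groups are
    constant, p = 1 when the means are equal and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
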