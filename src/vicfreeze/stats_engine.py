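"""Split-plot ANOVA and companion tests for the behavioral analyses.

The central tool is the classical two-way mixed (split-plot) ANOVA: one
between-subjects factor (group) and one within-subjects factor (time bin),
with the group effect tested against subjects-within-group variance and the
time and interaction effects against the within-subject residual. The sums
of squares are computed from cell means — the classical balanced
decomposition, falling back to unweighted-means analysis with the harmonic
mean group size when group sizes differ (n = 11-15 per group in the study
design). No REML machinery is involved.

Planned comparisons are ordinary pooled-variance t-tests, multiplicity is
handled by Bonferroni, and associations by Pearson correlation. The
proportion of animal pairs emitting any ultrasonic call is compared between
groups with a t-test on the binary emit indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "AnovaResult",
    "TestResult",
    "mixed_anova",
    "t_test",
    "pearson_r",
    "bonferroni",
    "pairs_emitting_usv",
]


@dataclass
class EffectRow:
    ss: float
    df: int
    ms: float
    f: float
    p: float


@dataclass
class AnovaResult:
    """Split-plot decomposition: fixed effects and their error strata."""

    effects: dict[str, EffectRow]
    error_between: EffectRow  # subjects within group
    error_within: EffectRow  # time x subjects within group
    balanced: bool
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = {**self.effects,
                "subjects_within_group": self.error_between,
                "residual_within": self.error_within}
        return pd.DataFrame(
            {k: {"SS": v.ss, "df": v.df, "MS": v.ms, "F": v.f, "p": v.p}
             for k, v in rows.items()}
        ).T


@dataclass
class TestResult:
    statistic: float
    df: float
    p_raw: float
    method: str
    p_adjusted: float | None = None
    degenerate: bool = False


@dataclass
class CohortTable:
    """Tidy per-animal, per-bin outcomes with one between-subjects group."""

    data: pd.DataFrame  # columns: animal_id, group, bin, value

    REQUIRED = ("animal_id", "group", "bin", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        dup = self.data.duplicated(subset=["animal_id", "bin"])
        if dup.any():
            raise ValueError("more than one value per (animal, bin)")
        groups_per_animal = self.data.groupby("animal_id")["group"].nunique()
        if (groups_per_animal > 1).any():
            raise ValueError("each animal must belong to exactly one group")

    @property
    def is_balanced(self) -> bool:
        sizes = self.data.groupby("group")["animal_id"].nunique()
        return bool(sizes.nunique() == 1)


def mixed_anova(table: CohortTable, allow_listwise: bool = False) -> AnovaResult:
    """Classical split-plot ANOVA on a complete (animal x bin) table.

    Between stratum: SS_group vs subjects-within-group. Within stratum:
    SS_time and SS_group:time vs the time-by-subject residual. Animals
    missing any bin raise unless ``allow_listwise`` drops them.
    """
    df = table.data.copy()
    bins = sorted(df["bin"].unique(), key=str)
    counts = df.groupby("animal_id")["bin"].nunique()
    incomplete = counts[counts < len(bins)].index
    if len(incomplete):
        if not allow_listwise:
            raise ValueError(
                f"animals missing time bins: {list(incomplete)[:5]} "
                "(pass allow_listwise=True to drop them)"
            )
        df = df[~df["animal_id"].isin(incomplete)]

    wide = df.pivot(index="animal_id", columns="bin", values="value")[bins]
    group_of = df.groupby("animal_id")["group"].first().loc[wide.index]
    groups = sorted(group_of.unique(), key=str)
    g, b = len(groups), len(bins)
    n_subj = len(wide)
    if g < 2 or b < 2:
        raise ValueError("need at least 2 groups and 2 time bins")

    y = wide.to_numpy(dtype=float)
    subj_mean = y.mean(axis=1)
    n_g = np.array([int((group_of == grp).sum()) for grp in groups])
    balanced = len(set(n_g)) == 1
    n_h = len(n_g) / np.sum(1.0 / n_g)  # harmonic mean; == n when balanced

    # cell means (unweighted analysis basis)
    cell = np.vstack([y[(group_of == grp).to_numpy()].mean(axis=0) for grp in groups])
    row_m = cell.mean(axis=1)
    col_m = cell.mean(axis=0)
    grand = cell.mean()

    ss_group = b * n_h * float(np.sum((row_m - grand) ** 2))
    ss_time = g * n_h * float(np.sum((col_m - grand) ** 2))
    ss_int = n_h * float(np.sum((cell - row_m[:, None] - col_m[None, :] + grand) ** 2))

    # error strata from the raw data (exact in all cases)
    ss_subj = 0.0
    ss_resid = 0.0
    for gi, grp in enumerate(groups):
        mask = (group_of == grp).to_numpy()
        sm = subj_mean[mask]
        ss_subj += b * float(np.sum((sm - sm.mean()) ** 2))
        dev = y[mask] - sm[:, None] - cell[gi][None, :] + sm.mean()
        ss_resid += float(np.sum(dev**2))

    df_group, df_subj = g - 1, n_subj - g
    df_time, df_int = b - 1, (g - 1) * (b - 1)
    df_resid = (n_subj - g) * (b - 1)

    ms_subj = ss_subj / df_subj if df_subj else np.nan
    ms_resid = ss_resid / df_resid if df_resid else np.nan
    degenerate = not (ms_subj > 0 and ms_resid > 0)

    def effect(ss: float, dfe: int, ms_err: float, df_err: int) -> EffectRow:
        ms = ss / dfe
        if degenerate or not ms_err > 0:
            return EffectRow(ss, dfe, ms, float("nan"), float("nan"))
        f = ms / ms_err
        return EffectRow(ss, dfe, ms, f, float(stats.f.sf(f, dfe, df_err)))

    return AnovaResult(
        effects={
            "group": effect(ss_group, df_group, ms_subj, df_subj),
            "time": effect(ss_time, df_time, ms_resid, df_resid),
            "group:time": effect(ss_int, df_int, ms_resid, df_resid),
        },
        error_between=EffectRow(ss_subj, df_subj, ms_subj, float("nan"), float("nan")),
        error_within=EffectRow(ss_resid, df_resid, ms_resid, float("nan"), float("nan")),
        balanced=balanced,
        degenerate=degenerate,
    )


def t_test(
    sample_a: Sequence[float], sample_b: Sequence[float], paired: bool = False
) -> TestResult:
    """Planned-comparison t-test: pooled-variance unpaired or paired Student t."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal sample sizes")
        d = a - b
        if np.var(d, ddof=1) == 0:
            return TestResult(float("nan"), len(a) - 1, float("nan"),
                              "paired t-test", degenerate=True)
        res = stats.ttest_rel(a, b)
        return TestResult(float(res.statistic), len(a) - 1, float(res.pvalue),
                          "paired t-test")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return TestResult(float("nan"), len(a) + len(b) - 2, float("nan"),
                          "unpaired t-test (pooled variance)", degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(float(res.statistic), len(a) + len(b) - 2, float(res.pvalue),
                      "unpaired t-test (pooled variance)")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with the usual t-based two-sided p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return TestResult(float(res.statistic), len(x) - 2, float(res.pvalue),
                      "Pearson correlation")


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p*m), m the family size."""
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    if m < len(p):
        raise ValueError("family size m must cover all supplied p-values")
    return np.minimum(1.0, p * m)


def pairs_emitting_usv(
    counts_by_group: Mapping[str, Sequence[int]],
) -> tuple[dict[str, float], TestResult]:
    """Per-group % of pairs with any call, compared by t-test on emit flags."""
    percents: dict[str, float] = {}
    indicators: list[np.ndarray] = []
    for name, counts in counts_by_group.items():
        c = np.asarray(counts)
        if c.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 pairs")
        emit = (c > 0).astype(float)
        percents[name] = 100.0 * float(emit.mean())
        indicators.append(emit)
    if len(indicators) != 2:
        raise ValueError("exactly two groups are compared")
    return percents, t_test(indicators[0], indicators[1], paired=False)
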