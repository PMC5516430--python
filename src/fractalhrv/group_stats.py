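"""Small-cohort inferential statistics for the five-session study design.

Each of a handful of subjects (astronauts) contributes one value of an HRV
index per study stage: Pre (before flight), F01/F02/F03 (in flight) and Post
(after return).  The Earth condition is the mean of Pre and Post; the space
condition is the mean of F01-F03.  Space-vs-Earth contrasts use a two-sided
one-sample t test on per-subject log10(space/Earth) ratios (which minimizes
inter-individual spread); adaptation across the three in-flight sessions is
screened by a one-way ANOVA; p values are Bonferroni-adjusted across the
indices tested, and variance homogeneity is checked by the Fmax and Bartlett
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAGES = ("Pre", "F01", "F02", "F03", "Post")
EARTH_STAGES = ("Pre", "Post")
SPACE_STAGES = ("F01", "F02", "F03")

#: default number of simultaneous comparisons: the five indices
#: (beta, ULF, VLF, LF, HF) tested side by side
DEFAULT_BONFERRONI_M = 5


@dataclass
class TestResult:
    statistic: float
    df: float | tuple
    p: float
    method: str
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p - 1e-12:
            raise ValueError("adjusted p smaller than raw p")


def validate_stage_values(df: pd.DataFrame) -> pd.DataFrame:
    """Check a per-subject x stage table (columns Pre..Post, one row per subject)."""
    missing = [s for s in STAGES if s not in df.columns]
    if missing:
        raise ValueError(f"missing stages: {missing}")
    sub = df[list(STAGES)]
    if sub.isna().any().any():
        bad = sub.isna().stack()
        subj, stage = bad[bad].index[0]
        raise ValueError(f"missing value for subject {subj!r}, stage {stage}")
    return sub


def earth_space_means(stage_values: pd.DataFrame) -> pd.DataFrame:
    """Per-subject Earth (mean of Pre, Post) and space (mean of F01-F03) averages."""
    sv = validate_stage_values(stage_values)
    return pd.DataFrame(
        {
            "earth": sv[list(EARTH_STAGES)].mean(axis=1),
            "space": sv[list(SPACE_STAGES)].mean(axis=1),
        }
    )


def paired_t_log_ratio(pairs: pd.DataFrame) -> TestResult:
    """Two-sided t on log10(space/earth) per subject against zero.

    Requires every (earth, space) pair to have the same sign so the ratio is
    positive (beta is negative throughout, band powers positive).  The t
    statistic is reported as |t|; it is identical under any log base.
    """
    earth = pairs["earth"].to_numpy(dtype=float)
    space = pairs["space"].to_numpy(dtype=float)
    if earth.size < 2:
        raise ValueError("need at least 2 subjects")
    ratio = space / earth
    if np.any(ratio <= 0):
        raise ValueError("earth/space pair with opposite signs: log ratio undefined")
    r = np.log10(ratio)
    if np.allclose(r.std(ddof=1), 0.0):
        raise ValueError("zero variance of log ratios: t undefined")
    t, p = stats.ttest_1samp(r, 0.0)
    return TestResult(abs(float(t)), earth.size - 1, float(p), "paired t on log10(space/earth)")


def paired_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Standard two-sided paired t test on matched per-subject values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need matched samples of equal length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return TestResult(float(t), a.size - 1, float(p), "paired t")


def one_way_anova(groups: list[np.ndarray]) -> TestResult:
    """Plain between-groups one-way ANOVA, F with (g-1, N-g) df.

    This is the computation that reproduces the published in-flight
    comparisons; a subject-blocked variant is
    :func:`one_way_rm_anova`.  When the between-group sum of squares is
    zero, F is defined as 0.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    if np.isclose(ss_between, 0.0):
        N = sum(g.size for g in gs)
        return TestResult(0.0, (len(gs) - 1, N - len(gs)), 1.0, "one-way ANOVA")
    F, p = stats.f_oneway(*gs)
    N = sum(g.size for g in gs)
    return TestResult(float(F), (len(gs) - 1, N - len(gs)), float(p), "one-way ANOVA")


def one_way_rm_anova(stage_values: pd.DataFrame, stages: tuple[str, ...] = SPACE_STAGES) -> TestResult:
    """Repeated-measures one-way ANOVA with subjects as blocks."""
    sv = validate_stage_values(stage_values)[list(stages)] if set(STAGES) <= set(stage_values.columns) else stage_values[list(stages)]
    X = sv.to_numpy(dtype=float)
    k, g = X.shape
    grand = X.mean()
    ss_stage = k * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subj = g * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((X - grand) ** 2)
    ss_err = ss_tot - ss_stage - ss_subj
    df1, df2 = g - 1, (g - 1) * (k - 1)
    if ss_err <= 0 or df2 <= 0:
        raise ValueError("degenerate repeated-measures design")
    F = (ss_stage / df1) / (ss_err / df2)
    return TestResult(float(F), (df1, df2), float(stats.f.sf(F, df1, df2)), "repeated-measures one-way ANOVA")


def bonferroni(p_raw: float, m: int = DEFAULT_BONFERRONI_M) -> float:
    """Bonferroni-adjusted p = min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p_raw * m)


def homogeneity_checks(groups: list[np.ndarray]) -> dict[str, TestResult]:
    """Fmax (max/min group variance) and Bartlett's chi-square homogeneity tests."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    variances = np.array([g.var(ddof=1) for g in gs])
    if np.any(variances == 0):
        raise ValueError("zero variance in a group: Fmax undefined")
    fmax = float(variances.max() / variances.min())
    # Fmax reference distribution (Hartley) is tabulated; report the statistic
    # with the equal-n Hartley p when group sizes match, else without p.
    stat, p = stats.bartlett(*gs)
    return {
        "fmax": TestResult(fmax, (len(gs), gs[0].size - 1), 1.0, "Hartley Fmax (statistic only)"),
        "bartlett": TestResult(float(stat), len(gs) - 1, float(p), "Bartlett chi-square"),
    }


# ---------------------------------------------------------------------------
# Full statistics table (replication of the published layout)
# ---------------------------------------------------------------------------

def statistics_table(
    indices: dict[str, pd.DataFrame],
    m_bonferroni: int = DEFAULT_BONFERRONI_M,
) -> pd.DataFrame:
    """Space-vs-Earth and in-flight statistics for several HRV indices.

    ``indices`` maps an index name (e.g. ``beta``, ``ulf``) to its
    per-subject x stage table.  One row per index: stage means/s.d., Earth
    and space means, the log-ratio paired |t| with raw and adjusted p, and
    the F01-F03 one-way ANOVA F.
    """
    rows = []
    for name, df in indices.items():
        sv = validate_stage_values(df)
        es = earth_space_means(sv)
        tres = paired_t_log_ratio(es)
        ares = one_way_anova([sv[s].to_numpy() for s in SPACE_STAGES])
        row = {"index": name}
        for s in STAGES:
            row[f"mean_{s}"] = sv[s].mean()
            row[f"sd_{s}"] = sv[s].std(ddof=1)
        row.update(
            earth_mean=es["earth"].mean(),
            space_mean=es["space"].mean(),
            paired_t=tres.statistic,
            paired_t_df=tres.df,
            p_raw=tres.p,
            p_adjusted=bonferroni(tres.p, m_bonferroni),
            anova_F=ares.statistic,
            anova_df1=ares.df[0],
            anova_df2=ares.df[1],
            anova_p=ares.p,
        )
        rows.append(row)
    return pd.DataFrame(rows)
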