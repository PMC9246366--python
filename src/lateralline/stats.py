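"""Per-fish aggregation and the population-level statistical battery.

The key inference is the weighted regression of per-fish swim rate on
per-fish pre-swim rate against the line of unity: a slope confidence
interval excluding 1 indicates swim-locked suppression of afferent
activity (an active corollary discharge), while an interval containing 1
means swimming leaves the afferent rate statistically unchanged.  Fish are
weighted by the square root of their number of retained swims, since the
precision of a fish's mean rates grows with the number of bouts observed.

Group comparisons use analysis of variance over the population x treatment
x period cells followed by Tukey's HSD, summarized as a compact letter
display.  Standard fits and tests are delegated to statsmodels and scipy.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .containers import BoutRates, FishMetadata, FishSummary, RegressionResult


def summarize_fish(
    bout_rates: list[BoutRates],
    spontaneous_rate: float,
    metadata: FishMetadata,
) -> FishSummary:
    """Average per-bout variables over one fish's retained bouts."""
    retained = [b for b in bout_rates if b.retained]
    if not retained:
        raise ValueError(
            f"fish {metadata.fish_id!r} has no retained bouts and is excluded"
        )
    return FishSummary(
        fish_id=metadata.fish_id,
        population=metadata.population,
        treatment=metadata.treatment,
        n_swims=len(retained),
        mean_pre_rate=float(np.mean([b.pre_rate for b in retained])),
        mean_swim_rate=float(np.mean([b.swim_rate for b in retained])),
        mean_post_rate=float(np.mean([b.post_rate for b in retained])),
        mean_spontaneous_rate=float(spontaneous_rate),
        mean_inhibition=float(np.mean([b.inhibition for b in retained])),
    )


def fish_summary_frame(summaries: list[FishSummary]) -> pd.DataFrame:
    """Tabulate fish summaries (one row per fish) for downstream statistics."""
    return pd.DataFrame(
        [
            dict(
                fish_id=s.fish_id, population=s.population, treatment=s.treatment,
                n_swims=s.n_swims, mean_pre_rate=s.mean_pre_rate,
                mean_swim_rate=s.mean_swim_rate, mean_post_rate=s.mean_post_rate,
                mean_spontaneous_rate=s.mean_spontaneous_rate,
                mean_inhibition=s.mean_inhibition, weight=s.weight,
            )
            for s in summaries
        ]
    )


def maybe_log_transform(
    df: pd.DataFrame,
    group_col: str,
    value_cols: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Log-transform variables whose group means and variances are correlated.

    For each variable the per-group means and variances are rank-correlated
    (Spearman); a significantly positive correlation at level ``alpha``
    triggers a natural-log transform (variance growing with the mean is the
    classic signature of a multiplicative scale, e.g. count-like rates).
    Zeros are handled with an offset of half the smallest positive value.
    Requires at least 4 groups to assess the mean-variance relation.
    """
    if value_cols is None:
        value_cols = [
            c for c in df.columns
            if c != group_col and pd.api.types.is_numeric_dtype(df[c])
        ]
    groups = df.groupby(group_col, observed=True)
    if groups.ngroups < 4:
        raise ValueError("need at least 4 groups to assess the mean-variance relation")
    out = df.copy()
    flags: dict[str, bool] = {}
    for col in value_cols:
        means = groups[col].mean().to_numpy()
        variances = groups[col].var(ddof=1).to_numpy()
        if np.ptp(means) == 0 or np.ptp(variances) == 0:
            flags[col] = False
            continue
        rho, p = sps.spearmanr(means, variances)
        flag = bool(rho > 0 and p < alpha)
        flags[col] = flag
        if flag:
            x = out[col].to_numpy(dtype=float)
            offset = 0.0
            if np.any(x <= 0):
                positive = x[x > 0]
                # half the smallest positive value, shifted further if
                # negative values are present so the argument stays positive
                offset = (0.5 * positive.min() if positive.size else 1.0)
                offset += max(0.0, -x.min())
            out[col] = np.log(x + offset)
    return out, flags


def weighted_unity_test(
    x, y, weights=None, alpha: float = 0.05
) -> RegressionResult:
    """Weighted least squares of swim rate on pre-swim rate vs the unity line.

    The 95% (``1 - alpha``) slope confidence interval comes from the t
    distribution with n - 2 degrees of freedom; with unit weights the fit
    reduces exactly to ordinary least squares.  Wide intervals are reported
    as-is (never clamped).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 fish for the unity test")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = res.params
    lo, hi = res.conf_int(alpha=alpha)[1]
    se = res.bse[1]
    t_unity = (slope - 1.0) / se
    p_unity = 2.0 * sps.t.sf(abs(t_unity), df=x.size - 2)
    return RegressionResult(
        slope=float(slope), intercept=float(intercept),
        slope_ci_low=float(lo), slope_ci_high=float(hi),
        excludes_unity=bool(hi < 1.0 or lo > 1.0),
        n=int(x.size), slope_se=float(se), p_unity=float(p_unity),
    )


def paired_swim_test(swim_rates, nonswim_rates) -> tuple[float, float]:
    """Paired two-tailed Student's t-test of swim vs nonswim rates per fish."""
    a = np.asarray(swim_rates, dtype=float).ravel()
    b = np.asarray(nonswim_rates, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.all(d == d[0]) and d[0] == 0:
        return 0.0, 1.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def unpaired_test(a, b) -> tuple[float, float]:
    """Two-tailed two-sample t-test with pooled variance."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# --------------------------------------------------------------------------
# ANOVA with Tukey letters
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """ANOVA table, Tukey pairwise results, and compact letter groupings."""

    anova_table: pd.DataFrame
    tukey_table: pd.DataFrame
    letters: dict[str, str]
    alpha: float


def compact_letter_display(
    groups: list[str], significant_pairs: set[frozenset]
) -> dict[str, str]:
    """Compact letter display from the set of significantly different pairs.

    Insert-and-absorb construction: start with one letter column holding
    every group; for each significant pair split every column containing
    both members, then absorb columns that are subsets of others.  Two
    groups share a letter if and only if they were not declared different.
    """
    columns: list[set[str]] = [set(groups)]
    for pair in sorted(significant_pairs, key=sorted):
        a, b = sorted(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for reduced in (col - {a}, col - {b}):
                if reduced and not any(reduced <= other for other in columns):
                    columns.append(reduced)
        columns = [
            c for c in columns
            if not any(c < other for other in columns)
        ]
    # order columns by the first group (in input order) they contain
    rank = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, col in zip(itertools.cycle(alphabet), columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in groups}


def group_comparison(
    df: pd.DataFrame,
    value_col: str,
    factor_cols: list[str],
    alpha: float = 0.05,
    factorial: bool = False,
) -> GroupComparison:
    """ANOVA across factor cells with Tukey HSD post-hoc letter groupings.

    By default the factors are combined into a single cell factor and a
    one-way ANOVA is run across cells (a design with k cells has k - 1
    numerator degrees of freedom); ``factorial=True`` instead fits the full
    factorial decomposition with interactions (type-II sums of squares).
    Tukey's HSD compares all cell pairs in both modes.
    """
    data = df.copy()
    data["_cell"] = data[factor_cols].astype(str).agg(":".join, axis=1)
    counts = data["_cell"].value_counts()
    if counts.size < 2:
        raise ValueError("need at least 2 groups")
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(
            f"groups with fewer than 2 observations: {', '.join(singletons.index)}"
        )
    data = data.rename(columns={value_col: "_value"})
    if factorial:
        terms = " * ".join(f"C({c})" for c in factor_cols)
        model = ols(f"_value ~ {terms}", data=data).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    else:
        model = ols("_value ~ C(_cell)", data=data).fit()
        anova = sm.stats.anova_lm(model, typ=1)

    tukey = pairwise_tukeyhsd(
        data["_value"].to_numpy(), data["_cell"].to_numpy(), alpha=alpha
    )
    tukey_frame = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    sig = {
        frozenset((row["group1"], row["group2"]))
        for _, row in tukey_frame.iterrows()
        if row["reject"]
    }
    cells = list(dict.fromkeys(data["_cell"]))
    letters = compact_letter_display(cells, sig)
    return GroupComparison(anova, tukey_frame, letters, alpha)
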