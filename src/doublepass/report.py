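"""Cohort-level statistics, tables and figures.

Conventions: two-sided p-values throughout; no multiple-testing correction;
Cohen's d for paired comparisons uses the SD of the paired differences;
error bars are +/- 1 SEM across participants (n - 1 denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "BinnedHitRates",
    "one_sample_t",
    "paired_t",
    "miss_rate_diff",
    "bin_hit_rates",
    "scatter_p12",
    "rt_descriptives",
]


@dataclass(frozen=True)
class TestResult:
    """A t-test with its effect size."""

    kind: str  # one_sample_t | paired_t
    statistic: float
    df: int
    p_value: float
    cohens_d: float
    n: int
    mean: float

    def __str__(self) -> str:
        return (
            f"{self.kind}: t({self.df}) = {self.statistic:.3f}, "
            f"p = {self.p_value:.4g}, Cohen's d = {self.cohens_d:.2f}, n = {self.n}"
        )


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Two-sided one-sample t-test with Cohen's d = (mean - mu0) / SD."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError(f"need at least 2 values, got {len(x)}")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero standard deviation: t statistic undefined")
    res = stats.ttest_1samp(x, mu0)
    return TestResult(
        kind="one_sample_t",
        statistic=float(res.statistic),
        df=len(x) - 1,
        p_value=float(res.pvalue),
        cohens_d=float((x.mean() - mu0) / sd),
        n=len(x),
        mean=float(x.mean()),
    )


def paired_t(x, y) -> TestResult:
    """Two-sided paired t-test: a one-sample test on the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if np.all(x == y):
        # identical samples: a well-defined no-effect case, not an error
        return TestResult(
            kind="paired_t", statistic=0.0, df=len(x) - 1, p_value=1.0,
            cohens_d=0.0, n=len(x), mean=0.0,
        )
    res = one_sample_t(x - y, 0.0)
    return TestResult(
        kind="paired_t",
        statistic=res.statistic,
        df=res.df,
        p_value=res.p_value,
        cohens_d=res.cohens_d,
        n=res.n,
        mean=res.mean,
    )


def miss_rate_diff(
    estimates: pd.DataFrame,
    condition_a: str = "nocue_nocue",
    condition_b: str = "nocue_cue",
) -> tuple[pd.DataFrame, TestResult]:
    """Per-participant miss-rate change (P2 - P1) by cue condition, plus the paired test.

    ``estimates`` is the per-participant, per-condition rates table (columns
    participant_id, condition, P1, P2).  Participants missing either condition
    are dropped with a warning.  The paired comparison asks whether the cue
    produced a larger round-2 drop in misses than repetition alone.
    """
    wide = estimates.pivot_table(
        index="participant_id", columns="condition", values=["P1", "P2"]
    )
    diffs = {}
    for cond in (condition_a, condition_b):
        if ("P1", cond) not in wide.columns:
            raise ValueError(f"condition {cond!r} absent from estimates")
        diffs[cond] = wide[("P2", cond)] - wide[("P1", cond)]
    table = pd.DataFrame(diffs)
    complete = table.dropna()
    if len(complete) < len(table):
        dropped = sorted(set(table.index) - set(complete.index))
        warnings.warn(f"participants missing a condition dropped: {dropped}")
    test = paired_t(complete[condition_a], complete[condition_b])
    table = complete.rename(
        columns={condition_a: f"p2_minus_p1_{condition_a}",
                 condition_b: f"p2_minus_p1_{condition_b}"}
    )
    return table, test


@dataclass
class BinnedHitRates:
    """Hit rate as a function of target-background contrast."""

    table: pd.DataFrame  # columns: bin, hit_rate, sem, n_participants

    def __post_init__(self) -> None:
        rates = self.table["hit_rate"]
        if ((rates < 0) | (rates > 1)).any():
            raise ValueError("hit rates outside [0, 1]")


def bin_hit_rates(trials: pd.DataFrame, bin_width: float | None = 50.0) -> BinnedHitRates:
    """Hit rate per T-B contrast bin, with SEM across participants.

    With ``bin_width`` set, signed T-B values are grouped into bins of that
    width centered on 0; with ``bin_width=None`` the discrete observed levels
    are used directly (the controlled-contrast dialect).
    """
    present = trials[trials["target_present"]].copy()
    if len(present) == 0:
        raise ValueError("no present trials to bin")
    tb = present["tb_contrast"].astype(float)
    if tb.isna().all():
        raise ValueError("present trials carry no tb_contrast values")
    if bin_width is None:
        present["bin"] = tb
    else:
        present["bin"] = (np.floor(tb / bin_width) + 0.5) * bin_width
    present["hit"] = (present["response"] == "present").astype(float)
    per_pp = (
        present.groupby(["bin", "participant_id"], observed=True)["hit"].mean()
    )
    grouped = per_pp.groupby("bin", observed=True)
    table = pd.DataFrame(
        {
            "bin": grouped.mean().index,
            "hit_rate": grouped.mean().values,
            "sem": grouped.apply(
                lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
            ).values,
            "n_participants": grouped.size().values,
        }
    ).reset_index(drop=True)
    return BinnedHitRates(table=table)


def scatter_p12(estimates: pd.DataFrame, ax=None):
    """Observed P12 against P1 with the stochastic and deterministic predictions.

    ``estimates`` needs columns participant_id, P1, P2, P12.  Returns
    (table, matplotlib Axes); the table carries, per participant, the
    observed point and both predictions.
    """
    table = estimates[["participant_id", "P1", "P2", "P12"]].copy()
    table["stochastic_pred"] = table["P1"] * table["P2"]
    table["deterministic_pred"] = table[["P1", "P2"]].min(axis=1)
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(table["P1"], table["P12"], color="tab:blue", label="observed", zorder=3)
    ax.scatter(
        table["P1"], table["stochastic_pred"], facecolors="none",
        edgecolors="tab:red", label="stochastic pred. (P1*P2)",
    )
    ax.scatter(
        table["P1"], table["deterministic_pred"], facecolors="none",
        edgecolors="black", label="deterministic pred. (min(P1, P2))",
    )
    ax.set_xlabel("P1 (round-1 miss rate)")
    ax.set_ylabel("P12 (missed both rounds)")
    ax.legend(frameon=False, fontsize=8)
    return table, ax


def rt_descriptives(trials: pd.DataFrame, cell_keys=None) -> pd.DataFrame:
    """Per-cell correct-trial RT means with SEM across participants."""
    if cell_keys is None:
        cell_keys = ["target_present", "set_size", "copy"]
    correct = trials[
        (trials["target_present"] & (trials["response"] == "present"))
        | (~trials["target_present"] & (trials["response"] == "absent"))
    ]
    per_pp = correct.groupby(cell_keys + ["participant_id"], observed=True)[
        "rt_ms"
    ].mean()
    grouped = per_pp.groupby(cell_keys, observed=True)
    return pd.DataFrame(
        {
            "mean_rt_ms": grouped.mean(),
            "sem_rt_ms": grouped.apply(
                lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
            ),
            "n_participants": grouped.size(),
        }
    ).reset_index()
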