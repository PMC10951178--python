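"""Model/Results interface over the full double-pass analysis pipeline.

:class:`DoublePassModel` wraps a cohort trial log (one row per trial); its
:meth:`~DoublePassModel.fit` runs the exclusion pipeline, computes the
observed (P1, P2, P12) per participant and condition, solves the closed-form
decomposition, and returns a :class:`DoublePassResults` carrying the
estimates table, the exclusion bookkeeping and the cohort-level tests.

Typical use::

    design = build_design("exp2b", rng_seed=1)
    sessions = simulate_cohort(20, design, LatentParams(d1=0.05, s1=0.12, s2=0.08))
    res = DoublePassModel.from_sessions(sessions, dialect="exp2b").fit()
    print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import decompose, preprocess, report
from .preprocess import ExclusionReport
from .synthetic_behavior import ParticipantSession, load_trials

__all__ = ["DoublePassModel", "DoublePassResults"]

_CUED_DIALECTS = ("exp3", "exp3a", "exp3b", "exp3c")

ESTIMATE_COLUMNS = [
    "participant_id",
    "condition",
    "n_pairs",
    "P1",
    "P2",
    "P12",
    "stoch_pred",
    "det_pred",
    "d1",
    "d2",
    "s1",
    "s2",
    "d_raw",
    "rounded_d",
    "excluded",
    "exclusion_reason",
]


class DoublePassModel:
    """Stochastic/deterministic decomposition of repeated-display miss errors.

    Parameters
    ----------
    trials
        Cohort trial log with the standard columns (participant_id,
        display_id, copy, set_size, target_present, response, rt_ms,
        corrected, and cue_group for the cued dialect).
    dialect
        Which design the log comes from: ``exp1``, ``exp2a``, ``exp2b`` (one
        uncued condition) or ``exp3``/``exp3a``/``exp3b``/``exp3c`` (a
        noCue-noCue and a noCue-Cue condition per participant).
    run_preprocess
        Apply the RT/motor-correction exclusion pipeline and d' screening
        before computing rates (default).  Disable for already-clean data.
    cue_d1_source
        Where the cued solver borrows its d1: the same participant's uncued
        estimate (``"participant"``, default) or the cohort-mean uncued d
        (``"group"``).
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        dialect: str = "exp1",
        run_preprocess: bool = True,
        k_sd: float = preprocess.DEFAULT_K_SD,
        cue_d1_source: str = "participant",
    ) -> None:
        if cue_d1_source not in ("participant", "group"):
            raise ValueError(f"unknown cue_d1_source {cue_d1_source!r}")
        self.trials = trials
        self.dialect = dialect
        self.run_preprocess = run_preprocess
        self.k_sd = k_sd
        self.cue_d1_source = cue_d1_source
        self.is_cued = dialect in _CUED_DIALECTS

    @classmethod
    def from_sessions(
        cls, sessions: list[ParticipantSession], dialect: str | None = None, **kwargs
    ) -> "DoublePassModel":
        if dialect is None:
            dialect = sessions[0].experiment or "exp1"
        trials = pd.concat([s.trials for s in sessions], ignore_index=True)
        return cls(trials, dialect=dialect, **kwargs)

    @classmethod
    def from_csv(cls, path, dialect: str = "exp1", **kwargs) -> "DoublePassModel":
        return cls(load_trials(path), dialect=dialect, **kwargs)

    # ------------------------------------------------------------------
    def fit(self) -> "DoublePassResults":
        if self.run_preprocess:
            clean, excl = preprocess.preprocess_cohort(
                self.trials, self.dialect, self.k_sd
            )
        else:
            clean = self.trials
            excl = ExclusionReport(n_total=len(clean), n_remaining=len(clean))

        if self.is_cued:
            estimates = self._fit_cued(clean)
        else:
            estimates = self._fit_uncued(clean)
        return DoublePassResults(self, clean, estimates, excl)

    def _row(self, pid, r, est) -> dict:
        b = decompose.predictions(r)
        return {
            "participant_id": pid,
            "condition": r.condition,
            "n_pairs": r.n_pairs,
            "P1": r.P1,
            "P2": r.P2,
            "P12": r.P12,
            "stoch_pred": b.stochastic_pred,
            "det_pred": b.deterministic_pred,
            "d1": est.d1,
            "d2": est.d2,
            "s1": est.s1,
            "s2": est.s2,
            "d_raw": est.d_raw,
            "rounded_d": est.rounded_d,
            "excluded": est.excluded,
            "exclusion_reason": est.exclusion_reason,
        }

    def _fit_uncued(self, clean: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for pid, df in clean.groupby("participant_id"):
            r = decompose.compute_rates(df, condition="all")
            rows.append(self._row(pid, r, decompose.solve_nocue(r)))
        return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)

    def _fit_cued(self, clean: pd.DataFrame) -> pd.DataFrame:
        if "cue_group" not in clean.columns:
            raise ValueError("cued dialect requires a cue_group column")
        nocue_rows, cue_cells = [], []
        for pid, df in clean.groupby("participant_id"):
            r_nn = decompose.compute_rates(
                df[df["cue_group"] == "nocue_nocue"], condition="nocue_nocue"
            )
            est_nn = decompose.solve_nocue(r_nn)
            nocue_rows.append(self._row(pid, r_nn, est_nn))
            r_nc = decompose.compute_rates(
                df[df["cue_group"] == "nocue_cue"], condition="nocue_cue"
            )
            cue_cells.append((pid, r_nc, est_nn))

        if self.cue_d1_source == "group":
            ds = [row["d1"] for row in nocue_rows if not row["excluded"]]
            group_d = float(np.mean(ds)) if ds else np.nan

        rows = list(nocue_rows)
        for pid, r_nc, est_nn in cue_cells:
            if self.cue_d1_source == "participant":
                d1_ref = est_nn.d1 if not est_nn.excluded else None
            else:
                d1_ref = group_d
            if d1_ref is None or not np.isfinite(d1_ref):
                est = decompose.DecompositionEstimate(
                    mode="cue",
                    condition="nocue_cue",
                    n_pairs=r_nc.n_pairs,
                    excluded=True,
                    exclusion_reason="degenerate_denominator",
                )
            else:
                est = decompose.solve_cue(r_nc, d1_ref)
            rows.append(self._row(pid, r_nc, est))
        return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


class DoublePassResults:
    """Fitted decomposition: estimates, exclusions, tests, summary and plots."""

    def __init__(
        self,
        model: DoublePassModel,
        clean_trials: pd.DataFrame,
        estimates: pd.DataFrame,
        exclusion_report: ExclusionReport,
    ) -> None:
        self.model = model
        self.clean_trials = clean_trials
        self.estimates = estimates
        self.exclusion_report = exclusion_report

    # -- selections -----------------------------------------------------
    def _usable(self, condition: str) -> pd.DataFrame:
        sub = self.estimates[self.estimates["condition"] == condition]
        return sub[~sub["excluded"]]

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.estimates["condition"]))

    # -- tests ----------------------------------------------------------
    def test_d_zero(self, condition: str | None = None) -> report.TestResult:
        """Is the deterministic error proportion different from zero?"""
        condition = condition or self.conditions[0]
        return report.one_sample_t(self._usable(condition)["d1"], 0.0)

    def test_learning(self, condition: str | None = None) -> report.TestResult:
        """Paired s1 vs s2: did stochastic errors drop on the second pass?"""
        condition = condition or self.conditions[0]
        sub = self._usable(condition)
        return report.paired_t(sub["s1"], sub["s2"])

    def test_cue_deterministic(self) -> report.TestResult:
        """Paired d1 vs d2 in the cued condition: did the cue convert
        unfindable displays to findable?"""
        sub = self._usable("nocue_cue")
        return report.paired_t(sub["d1"], sub["d2"])

    def test_cue_stochastic(self) -> report.TestResult:
        """Paired s1 vs s2 in the cued condition."""
        sub = self._usable("nocue_cue")
        return report.paired_t(sub["s1"], sub["s2"])

    def test_miss_rate_diff(self) -> tuple[pd.DataFrame, report.TestResult]:
        """P2 - P1 by cue condition and its paired comparison."""
        return report.miss_rate_diff(self.estimates)

    # -- derived outputs ------------------------------------------------
    def contrast_split(self, threshold: float = 30.0) -> pd.DataFrame:
        """Per-participant decomposition within low/high |T-B| strata."""
        rows = []
        for pid, df in self.clean_trials.groupby("participant_id"):
            for r in decompose.split_by_contrast(df, threshold=threshold):
                est = decompose.solve_nocue(r)
                rows.append(self.model._row(pid, r, est))
        return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)

    def binned_hit_rates(self, bin_width: float | None = 50.0) -> report.BinnedHitRates:
        return report.bin_hit_rates(self.clean_trials, bin_width)

    def prediction_table(self) -> pd.DataFrame:
        table, _ = report.scatter_p12(self.estimates)
        return table

    def plot_predictions(self, ax=None):
        _, ax = report.scatter_p12(self.estimates, ax=ax)
        return ax

    def rt_descriptives(self) -> pd.DataFrame:
        return report.rt_descriptives(self.clean_trials)

    # -- summary --------------------------------------------------------
    def summary(self) -> str:
        e = self.exclusion_report
        lines = [
            "Double-Pass Miss-Error Decomposition",
            "=" * 68,
            f"Dialect: {self.model.dialect}    "
            f"Participants: {self.estimates['participant_id'].nunique()}"
            f" ({len(e.excluded_participants)} screened out by d')",
            f"Trials: {e.n_total} -> {e.n_remaining} after cleaning "
            f"({e.pct_remaining_after_pairing:.1f}% remain; "
            f"{e.pct_outlier_rt:.2f}% RT outliers, "
            f"{e.pct_corrected:.2f}% motor-corrected)",
            "",
            f"{'condition':<14}{'n':>4}{'P1':>8}{'P2':>8}{'P12':>8}"
            f"{'d1':>8}{'d2':>8}{'s1':>8}{'s2':>8}",
            "-" * 68,
        ]
        for cond in self.conditions:
            sub = self._usable(cond)
            if len(sub) == 0:
                continue
            m = sub[["P1", "P2", "P12", "d1", "d2", "s1", "s2"]].mean()
            lines.append(
                f"{cond:<14}{len(sub):>4}"
                f"{m['P1']:>8.3f}{m['P2']:>8.3f}{m['P12']:>8.3f}"
                f"{m['d1']:>8.3f}{m['d2']:>8.3f}{m['s1']:>8.3f}{m['s2']:>8.3f}"
            )
        lines.append("-" * 68)
        for cond in self.conditions:
            if len(self._usable(cond)) >= 2:
                try:
                    lines.append(f"d = 0 ({cond}): {self.test_d_zero(cond)}")
                    lines.append(f"s1 vs s2 ({cond}): {self.test_learning(cond)}")
                except ValueError:
                    pass
        if self.model.is_cued and len(self._usable("nocue_cue")) >= 2:
            lines.append(f"d1 vs d2 (cue): {self.test_cue_deterministic()}")
        n_excl = int(self.estimates["excluded"].sum())
        if n_excl:
            lines.append(f"Excluded estimate cells: {n_excl}")
        return "\n".join(lines)
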