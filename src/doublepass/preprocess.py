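"""Data-exclusion pipeline and d-prime participant screening.

The cleaning order is: (1) an extreme screen removing reaction times longer
than 100 s, which would otherwise distort the trimming statistics; (2) a
per-cell trim removing trials strictly outside mean +/- k SD of the remaining
RTs, computed separately for each participant within each design cell;
(3) removal of motor-corrected trials; (4) pair removal — whenever one copy
of a display is gone, the surviving copy is removed too, so every display
contributes either a complete pair or nothing.  Finally each participant's
detection sensitivity d' = z(hit rate) - z(false-alarm rate) is computed on
the surviving trials and participants beyond k SD from the group-mean d' are
flagged for exclusion.

Trimming cells are {target presence x set size} for the uncued dialects and
{target presence x set size x repetition x cue} for the cued dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DPrime",
    "ExclusionReport",
    "cell_keys_for_dialect",
    "trim_rts",
    "pair_removal",
    "dprime",
    "screen_participants",
    "preprocess_session",
    "preprocess_cohort",
]

EXTREME_CUTOFF_MS = 100_000.0
DEFAULT_K_SD = 2.5

#: Trimming cells per experiment dialect.
_CELLS_UNCUED = ["target_present", "set_size"]
_CELLS_CUED = ["target_present", "set_size", "copy", "cue_condition"]


def cell_keys_for_dialect(dialect: str) -> list[str]:
    if dialect in ("exp1", "exp2a", "exp2b"):
        return list(_CELLS_UNCUED)
    if dialect in ("exp3", "exp3a", "exp3b", "exp3c"):
        return list(_CELLS_CUED)
    raise ValueError(f"unknown dialect {dialect!r}")


@dataclass
class DPrime:
    """Detection sensitivity of one participant."""

    hit_rate: float
    fa_rate: float
    dprime: float
    n_present: int
    n_absent: int


@dataclass
class ExclusionReport:
    """Bookkeeping of the cleaning pipeline over a cohort.

    Counts partition the input: ``n_extreme_rt_removed + n_outlier_rt_removed
    + n_corrected_removed + n_pair_removed + n_remaining == n_total``.
    """

    n_total: int = 0
    n_extreme_rt_removed: int = 0
    n_outlier_rt_removed: int = 0
    n_corrected_removed: int = 0
    n_pair_removed: int = 0
    n_remaining: int = 0
    pct_outlier_rt: float = 0.0
    pct_corrected: float = 0.0
    pct_remaining_after_pairing: float = 0.0
    excluded_participants: list[dict] = field(default_factory=list)
    dprime_per_participant: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def trim_rts(
    trials: pd.DataFrame,
    cell_keys: list[str] | None = None,
    k_sd: float = DEFAULT_K_SD,
    extreme_cutoff_ms: float = EXTREME_CUTOFF_MS,
) -> tuple[pd.DataFrame, dict]:
    """Remove extreme and per-cell outlier RTs (not yet pair-removed).

    The extreme screen runs first so that trials longer than the cutoff do
    not inflate the per-cell mean/SD.  Within each (participant x cell) the
    trim removes trials *strictly* outside mean +/- k_sd x SD (sample SD,
    n-1 denominator); when the SD is zero the bounds collapse to the mean and
    equality is retained, so nothing is removed.  Cells with no surviving
    trials are skipped with a warning.
    """
    if cell_keys is None:
        cell_keys = list(_CELLS_UNCUED)
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("reaction times must be positive")
    extreme = trials["rt_ms"] > extreme_cutoff_ms
    kept = trials[~extreme]

    outlier = pd.Series(False, index=kept.index)
    group_cols = ["participant_id"] + cell_keys
    for key, cell in kept.groupby(group_cols, observed=True):
        if len(cell) == 0:  # pragma: no cover - groupby never yields empty
            warnings.warn(f"empty trimming cell {key}; skipped")
            continue
        m = cell["rt_ms"].mean()
        sd = cell["rt_ms"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            continue
        outside = (cell["rt_ms"] < m - k_sd * sd) | (cell["rt_ms"] > m + k_sd * sd)
        outlier.loc[cell.index[outside]] = True

    info = {
        "n_extreme_rt_removed": int(extreme.sum()),
        "n_outlier_rt_removed": int(outlier.sum()),
    }
    return kept[~outlier], info


def pair_removal(
    trials: pd.DataFrame, original: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict]:
    """Keep only trials whose paired copy also survived.

    If ``original`` (the session before any removal) is supplied, display_ids
    that never had two copies raise a validation error; otherwise the input
    is taken at face value and any singleton is removed as a broken pair.
    """
    if original is not None:
        counts = original.groupby("participant_id")["display_id"].value_counts()
        orphans = counts[counts != 2]
        if len(orphans):
            raise ValueError(
                f"display_ids without exactly two copies in the input session: "
                f"{orphans.index.tolist()[:5]}"
            )
    counts = trials.groupby(["participant_id", "display_id"]).size()
    complete = counts[counts == 2].index
    keep = trials.set_index(["participant_id", "display_id"]).index.isin(complete)
    out = trials[keep]
    return out, {"n_pair_removed": int(len(trials) - len(out))}


def dprime(trials: pd.DataFrame, correction: str = "replacement") -> DPrime:
    """d' = z(hit rate) - z(false-alarm rate) with perfect-rate correction.

    Rates of 1 are replaced by (n - 0.5)/n and rates of 0 by 0.5/n before the
    z-transform (``correction="replacement"``); ``correction="none"`` leaves
    the rates untouched (and yields infinite d' at 0 or 1).
    """
    present = trials[trials["target_present"]]
    absent = trials[~trials["target_present"]]
    if len(present) == 0 or len(absent) == 0:
        raise ValueError("d' requires at least one present and one absent trial")

    def rate(df: pd.DataFrame) -> float:
        r = (df["response"] == "present").mean()
        n = len(df)
        if correction == "replacement":
            if r == 1.0:
                r = (n - 0.5) / n
            elif r == 0.0:
                r = 0.5 / n
        elif correction != "none":
            raise ValueError(f"unknown correction {correction!r}")
        return float(r)

    hr = rate(present)
    far = rate(absent)
    return DPrime(
        hit_rate=hr,
        fa_rate=far,
        dprime=float(norm.ppf(hr) - norm.ppf(far)),
        n_present=len(present),
        n_absent=len(absent),
    )


def screen_participants(
    trials: pd.DataFrame, k_sd: float = DEFAULT_K_SD
) -> tuple[dict[str, float], list[dict]]:
    """Flag participants whose d' lies beyond k_sd SDs from the group mean.

    Returns (d' per participant, list of exclusions with reasons).  With
    fewer than 3 participants there is no meaningful group distribution, so
    screening is skipped with a warning.
    """
    dprimes = {
        pid: dprime(df).dprime for pid, df in trials.groupby("participant_id")
    }
    excluded: list[dict] = []
    if len(dprimes) < 3:
        warnings.warn(
            f"only {len(dprimes)} participants: d' screening skipped "
            "(needs a group distribution)"
        )
        return dprimes, excluded
    values = np.array(list(dprimes.values()))
    m, sd = values.mean(), values.std(ddof=1)
    for pid, dp in dprimes.items():
        if sd > 0 and abs(dp - m) > k_sd * sd:
            excluded.append({"participant_id": pid, "reason": "low_dprime", "dprime": dp})
    return dprimes, excluded


def preprocess_session(
    trials: pd.DataFrame,
    dialect: str = "exp1",
    k_sd: float = DEFAULT_K_SD,
    extreme_cutoff_ms: float = EXTREME_CUTOFF_MS,
) -> tuple[pd.DataFrame, dict]:
    """Run extreme screen, SD trim, correction removal and pair removal."""
    cells = cell_keys_for_dialect(dialect)
    trimmed, info = trim_rts(trials, cells, k_sd, extreme_cutoff_ms)
    corrected = trimmed["corrected"].astype(bool)
    info["n_corrected_removed"] = int(corrected.sum())
    trimmed = trimmed[~corrected]
    clean, pair_info = pair_removal(trimmed, original=trials)
    info.update(pair_info)
    info["n_total"] = len(trials)
    info["n_remaining"] = len(clean)
    return clean, info


def preprocess_cohort(
    trials: pd.DataFrame,
    dialect: str = "exp1",
    k_sd: float = DEFAULT_K_SD,
    extreme_cutoff_ms: float = EXTREME_CUTOFF_MS,
    screen: bool = True,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Clean a cohort trial log and screen participants by d'.

    Returns the cleaned trials (excluded participants' trials dropped) and
    the full bookkeeping report.
    """
    clean, info = preprocess_session(trials, dialect, k_sd, extreme_cutoff_ms)
    report = ExclusionReport(
        n_total=info["n_total"],
        n_extreme_rt_removed=info["n_extreme_rt_removed"],
        n_outlier_rt_removed=info["n_outlier_rt_removed"],
        n_corrected_removed=info["n_corrected_removed"],
        n_pair_removed=info["n_pair_removed"],
        n_remaining=info["n_remaining"],
        pct_outlier_rt=100.0 * info["n_outlier_rt_removed"] / info["n_total"],
        pct_corrected=100.0 * info["n_corrected_removed"] / info["n_total"],
        pct_remaining_after_pairing=100.0 * info["n_remaining"] / info["n_total"],
    )
    if screen:
        dprimes, excluded = screen_participants(clean, k_sd)
        report.dprime_per_participant = dprimes
        report.excluded_participants = excluded
        bad = {e["participant_id"] for e in excluded}
        if bad:
            clean = clean[~clean["participant_id"].isin(bad)]
    return clean, report
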