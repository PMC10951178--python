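"""Closed-form decomposition of double-pass miss rates.

For a participant who saw every target-present display twice, three rates are
observable: the round-1 miss rate P1, the round-2 miss rate P2, and the
proportion of display pairs missed on both rounds, P12.  Purely stochastic
errors (independent across rounds) predict P12 = P1*P2; purely deterministic
errors (display-bound, recurring) predict P12 = min(P1, P2); a mixture lies
between the two bounds.

With a fixed deterministic proportion across rounds (d = d1 = d2) the mixture
inverts in closed form:

    d  = (P12 - P1*P2) / (1 - P1 - P2 + P12)
    s1 = (P1 - P12) / (1 - P2)
    s2 = (P2 - P12) / (1 - P1)

When the second copy carries an intervention that may convert unfindable
displays to findable, d2 <= d1 and the system is under-determined; d2 and s2
remain uniquely solvable,

    d2 = (P12 - P1*P2) / (1 - P1 - P2 + P12)
    s2 = (P2 - P12) / (1 - P1)

and s1 is recovered by borrowing the participant's uncued estimate of the
deterministic proportion as d1:  s1 = (P1 - d1) / (1 - d1).

Estimator conventions: a solved d in [-0.002, 0) is rounded to 0 (sampling
noise around a true zero); a d below -0.002 excludes the estimate, as does a
negative borrowed-d1 s1 in the cued solver and any degenerate denominator.
Out-of-range estimates are reported with flags rather than silently clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "RatesTriple",
    "PredictionBounds",
    "DecompositionEstimate",
    "compute_rates",
    "solve_nocue",
    "solve_cue",
    "predictions",
    "split_by_contrast",
    "D_ROUNDING_THRESHOLD",
]

#: A solved d in [-D_ROUNDING_THRESHOLD, 0) is rounded to 0; below it, excluded.
D_ROUNDING_THRESHOLD = 0.002

#: Denominators smaller than this are treated as degenerate.
DENOM_TOL = 1e-9


@dataclass(frozen=True)
class RatesTriple:
    """Observed (P1, P2, P12) over the surviving present-display pairs of one cell."""

    P1: float
    P2: float
    P12: float
    n_pairs: int
    condition: str = ""

    def __post_init__(self) -> None:
        for name in ("P1", "P2", "P12"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class PredictionBounds:
    """The two pure-model predictions of P12 given observed P1, P2."""

    stochastic_pred: float  # P1 * P2
    deterministic_pred: float  # min(P1, P2)


@dataclass
class DecompositionEstimate:
    """Solved (d1, d2, s1, s2) for one participant x condition cell.

    In the uncued mode d1 == d2 == d.  ``rounded_d`` marks a small negative d
    rounded to zero; ``excluded`` carries the reason when the estimate is
    unusable (d_below_threshold, negative_s1, degenerate_denominator).
    """

    d1: float | None = None
    d2: float | None = None
    s1: float | None = None
    s2: float | None = None
    d_raw: float | None = None  # solved d before rounding/exclusion
    mode: str = "nocue"
    condition: str = ""
    n_pairs: int = 0
    rounded_d: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def d(self) -> float | None:
        """The common deterministic proportion (uncued mode)."""
        return self.d1


def compute_rates(
    trials: pd.DataFrame, condition: str = "", condition_filter=None
) -> RatesTriple:
    """Observed (P1, P2, P12) from paired present trials.

    ``trials`` must already be cleaned and pair-complete; only target-present
    trials whose display contributes both copies are counted.
    ``condition_filter`` optionally subsets the trials first (callable on the
    DataFrame or a boolean mask).
    """
    df = trials
    if condition_filter is not None:
        mask = (
            condition_filter(df) if callable(condition_filter) else condition_filter
        )
        df = df[mask]
    present = df[df["target_present"]]
    counts = present.groupby("display_id").size()
    paired_ids = counts[counts == 2].index
    present = present[present["display_id"].isin(paired_ids)]
    n_pairs = len(paired_ids)
    if n_pairs == 0:
        raise ValueError(f"no surviving present-display pairs (condition {condition!r})")
    miss = present["response"] == "absent"
    p1 = miss[present["copy"] == 1].mean()
    p2 = miss[present["copy"] == 2].mean()
    both = (
        present.assign(miss=miss).groupby("display_id")["miss"].all()
    )
    p12 = both.mean()
    return RatesTriple(
        P1=float(p1), P2=float(p2), P12=float(p12), n_pairs=n_pairs, condition=condition
    )


def predictions(r: RatesTriple) -> PredictionBounds:
    """Pure-stochastic and pure-deterministic predictions of P12."""
    return PredictionBounds(
        stochastic_pred=r.P1 * r.P2, deterministic_pred=min(r.P1, r.P2)
    )


def _apply_d_rules(est: DecompositionEstimate) -> DecompositionEstimate:
    """Rounding/exclusion on the common d of the uncued solver.

    The cued solver is deliberately left out: its d2 may fall below d1 (or
    below zero by sampling noise) and that difference is the hypothesis under
    test, so it is reported raw.
    """
    d = est.d1
    if d is not None and -D_ROUNDING_THRESHOLD <= d < 0.0:
        est.rounded_d = True
        est.d1 = est.d2 = 0.0
    elif d is not None and d < -D_ROUNDING_THRESHOLD:
        est.excluded = True
        est.exclusion_reason = "d_below_threshold"
    return est


def solve_nocue(r: RatesTriple) -> DecompositionEstimate:
    """Closed-form (d, s1, s2) under the fixed-d assumption d1 = d2."""
    est = DecompositionEstimate(mode="nocue", condition=r.condition, n_pairs=r.n_pairs)
    denom_d = 1.0 - r.P1 - r.P2 + r.P12
    denom_s1 = 1.0 - r.P2
    denom_s2 = 1.0 - r.P1
    if min(denom_d, denom_s1, denom_s2) < DENOM_TOL:
        est.excluded = True
        est.exclusion_reason = "degenerate_denominator"
        return est
    d = (r.P12 - r.P1 * r.P2) / denom_d
    est.d1 = est.d2 = est.d_raw = d
    est.s1 = (r.P1 - r.P12) / denom_s1
    est.s2 = (r.P2 - r.P12) / denom_s2
    return _apply_d_rules(est)


def solve_cue(r: RatesTriple, d1_ref: float) -> DecompositionEstimate:
    """Cued-round solver: unique (d2, s2), with s1 from the borrowed d1.

    ``d1_ref`` is the same participant's deterministic proportion from the
    uncued condition (unfindability persists when nothing intervenes, so the
    round-1 proportions should agree on average).  A negative resulting s1
    indicates the borrowed d1 overestimates the cued half's true d1 — the
    estimate is excluded.
    """
    est = DecompositionEstimate(mode="cue", condition=r.condition, n_pairs=r.n_pairs)
    est.d1 = d1_ref
    denom_d = 1.0 - r.P1 - r.P2 + r.P12
    denom_s2 = 1.0 - r.P1
    denom_s1 = 1.0 - d1_ref
    if d1_ref >= 1.0 or min(denom_d, denom_s2, denom_s1) < DENOM_TOL:
        est.excluded = True
        est.exclusion_reason = "degenerate_denominator"
        return est
    est.s2 = (r.P2 - r.P12) / denom_s2
    est.d2 = est.d_raw = (r.P12 - r.P1 * r.P2) / denom_d
    est.s1 = (r.P1 - d1_ref) / denom_s1
    if est.s1 < 0.0:
        est.excluded = True
        est.exclusion_reason = "negative_s1"
    return est


def split_by_contrast(
    trials: pd.DataFrame,
    threshold: float | None = 30.0,
    bins: list[float] | None = None,
) -> list[RatesTriple]:
    """Partition present-display pairs by |T-B| contrast and compute rates.

    With a ``threshold``, two strata are formed: |T-B| < threshold ("low")
    and the rest ("high").  With explicit ``bins`` (edges), one stratum per
    bin.  Empty strata are omitted with a warning.
    """
    if "tb_contrast" not in trials.columns:
        raise ValueError("trials carry no tb_contrast values")
    present = trials[trials["target_present"]].copy()
    abs_tb = present["tb_contrast"].abs()
    if bins is not None:
        labels = pd.cut(abs_tb, bins=bins)
        strata = [(str(lab), labels == lab) for lab in labels.cat.categories]
    else:
        strata = [
            (f"low(|T-B|<{threshold:g})", abs_tb < threshold),
            (f"high(|T-B|>={threshold:g})", abs_tb >= threshold),
        ]
    out = []
    for name, mask in strata:
        sub = present[mask]
        if len(sub) == 0:
            warnings.warn(f"contrast stratum {name} is empty; omitted")
            continue
        try:
            out.append(compute_rates(sub, condition=name))
        except ValueError:
            warnings.warn(f"contrast stratum {name} has no complete pairs; omitted")
    return out
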