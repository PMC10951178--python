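"""Trial-level behavior simulation under the four-state miss model.

Every target-present display is either fundamentally *unfindable* (its target
will be missed for a deterministic, display-bound reason) or *findable*.
Unfindability is drawn once per display and persists across the two copies —
a findable display never becomes unfindable.  On top of that, every trial can
produce a *stochastic* miss with a per-round probability, regardless of
findability.  The observed miss rates therefore compose as

    P1  = d1 (1 - s1) + s1
    P2  = d2 + s2 (d1 - d2) + (1 - d1) s2
    P12 = d2 + s2 (d1 - d2) + s1 (1 - d1) s2

where d1, d2 are the round-1/round-2 unfindable proportions (d2 <= d1: an
intervention can convert unfindable displays to findable on the second copy,
never the reverse) and s1, s2 are the per-round stochastic miss rates.

The simulator draws the stochastic process on every trial and records which
cause applied (``latent_state``), so the four states of the model — hit,
stochastic miss, deterministic miss, and unfindable-but-stochastically-missed
— are all observable in the trial log, while the totals collapse to the
equations above.

Reaction times, motor-correction flags, RT outliers and false alarms are
plumbing so the exclusion pipeline has something to act on; they are
lognormal-with-knobs and claim no quantitative fidelity to human data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .stimulus_gen import Design, ScheduledTrial

__all__ = [
    "LatentParams",
    "RTModel",
    "ParticipantSession",
    "TRIAL_COLUMNS",
    "compose_rates",
    "simulate_participant",
    "simulate_cohort",
    "write_cohort",
    "load_trials",
    "load_latents",
]

#: Column schema of the trial log.
TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "display_id",
    "copy",
    "set_size",
    "target_present",
    "cue_condition",
    "cue_group",
    "tb_contrast",
    "response",
    "rt_ms",
    "corrected",
    "latent_state",
]


@dataclass(frozen=True)
class LatentParams:
    """Ground-truth error-generating parameters of one simulated participant.

    ``d1``/``d2``: proportion of target-present displays that are unfindable
    in round 1 / round 2 (``d2 <= d1``).  In a cued design the d1 -> d2
    reduction applies only to second copies that carry a cue; in an uncued
    design it applies to all second copies.  ``s1``/``s2``: per-round
    stochastic miss probabilities.  ``fa_rate``: false-alarm probability on
    target-absent trials.  ``contrast_link``: optional (threshold, slope)
    making a display's unfindability probability a decreasing logistic
    function of its |T-B| contrast, with ceiling ``d1``.  ``s2_cued``:
    optional distinct stochastic rate for cued second copies (default: the
    cue affects only findability, not the stochastic channel).
    """

    d1: float = 0.0
    d2: float | None = None
    s1: float = 0.0
    s2: float = 0.0
    fa_rate: float = 0.0
    contrast_link: tuple[float, float] | None = None
    s2_cued: float | None = None

    def __post_init__(self) -> None:
        d2 = self.d1 if self.d2 is None else self.d2
        object.__setattr__(self, "d2", d2)
        for name in ("d1", "d2", "s1", "s2", "fa_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.d2 > self.d1:
            raise ValueError(
                f"d2={self.d2} > d1={self.d1}: findable displays cannot become unfindable"
            )
        if self.s2_cued is not None and not 0.0 <= self.s2_cued <= 1.0:
            raise ValueError(f"s2_cued={self.s2_cued} outside [0, 1]")

    def unfindable_prob(self, tb_contrast: float | None) -> float:
        """Per-display round-1 unfindability, optionally contrast-linked."""
        if self.contrast_link is None or tb_contrast is None or np.isnan(tb_contrast):
            return self.d1
        threshold, slope = self.contrast_link
        return float(self.d1 * expit((threshold - abs(tb_contrast)) / slope))


def compose_rates(
    d1: float, d2: float, s1: float, s2: float
) -> tuple[float, float, float]:
    """Forward model: expected (P1, P2, P12) from the latent parameters."""
    p1 = d1 * (1 - s1) + s1
    p2 = d2 + s2 * (d1 - d2) + (1 - d1) * s2
    p12 = d2 + s2 * (d1 - d2) + s1 * (1 - d1) * s2
    return p1, p2, p12


@dataclass(frozen=True)
class RTModel:
    """Lognormal reaction-time generator with injection knobs for the cleaner.

    Median RT (ms) is ``base + slope * set_size * (1 if present else 2)``,
    plus ``absent_extra`` on absent trials, minus ``round2_absent_speedup`` on
    second-copy absent trials (a coarse qualitative match to double-pass RT
    patterns: absent slower, steeper slopes, round-2 speed-up).  ``sigma`` is
    the lognormal shape.  ``outlier_rate`` trials are multiplied by 10;
    ``correction_rate`` trials are flagged as motor-corrected; ``truncate_ms``
    optionally caps RTs (e.g. a 20 s response deadline).
    """

    base_ms: float = 600.0
    slope_ms_per_item: float = 25.0
    absent_extra_ms: float = 400.0
    round2_absent_speedup_ms: float = 300.0
    sigma: float = 0.35
    outlier_rate: float = 0.0
    correction_rate: float = 0.0
    truncate_ms: float | None = None

    def __post_init__(self) -> None:
        for name in ("outlier_rate", "correction_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.base_ms <= 0 or self.sigma <= 0:
            raise ValueError("base_ms and sigma must be positive")


@dataclass
class ParticipantSession:
    """All trials of one participant plus, for simulated data, the latent truth."""

    participant_id: str
    trials: pd.DataFrame
    latent: LatentParams | None = None
    experiment: str = ""
    block_size: int = 0

    def validate(self) -> None:
        counts = self.trials["display_id"].value_counts()
        if not (counts == 2).all():
            bad = counts[counts != 2]
            raise ValueError(
                f"{self.participant_id}: display_ids not presented exactly twice: "
                f"{bad.index.tolist()[:5]}"
            )
        if not self.trials["copy"].isin([1, 2]).all():
            raise ValueError(f"{self.participant_id}: copy indices outside {{1, 2}}")


def simulate_participant(
    design: Design,
    latent: LatentParams,
    rt: RTModel | None = None,
    seed: int = 0,
    participant_id: str = "sim-001",
) -> ParticipantSession:
    """Simulate one participant's responses to a two-copy design.

    Unfindability is drawn once per target-present display; on second copies
    eligible for the cue-driven reduction (cued copies, or all copies in an
    uncued design) an unfindable display converts to findable with probability
    ``1 - d2/d1``.  Misses are certain on unfindable copies and occur with the
    round's stochastic probability otherwise.
    """
    rt = rt or RTModel()
    rng = np.random.default_rng(seed)
    schedule = design.schedule
    n = len(schedule)

    ids = list(design.displays)
    idx_of = {did: i for i, did in enumerate(ids)}
    present = np.array([design.displays[d].target_present for d in ids])
    tb = np.array(
        [
            np.nan
            if design.displays[d].tb_contrast is None
            else design.displays[d].tb_contrast
            for d in ids
        ],
        dtype=float,
    )

    # one unfindability draw per display, persisting across copies
    p_u = np.array(
        [latent.unfindable_prob(tb[i]) if present[i] else 0.0 for i in range(len(ids))]
    )
    unfindable1 = rng.random(len(ids)) < p_u
    # conversion applies to cued second copies, or to all second copies when
    # the design has no cue conditions
    keep_prob = latent.d2 / latent.d1 if latent.d1 > 0 else 0.0
    stays = rng.random(len(ids)) < keep_prob
    if design.cue_assignment:
        eligible = np.array(
            [design.cue_assignment.get(d) == "nocue_cue" for d in ids]
        )
    else:
        eligible = np.ones(len(ids), dtype=bool)
    unfindable2 = unfindable1 & np.where(eligible, stays, True)

    t_disp = np.array([idx_of[t.display_id] for t in schedule])
    t_copy = np.array([t.copy for t in schedule])
    t_cued = np.array([t.cued for t in schedule])
    t_present = present[t_disp]
    t_set = np.array([design.displays[t.display_id].set_size for t in schedule])

    s_round = np.where(t_copy == 1, latent.s1, latent.s2)
    if latent.s2_cued is not None:
        s_round = np.where((t_copy == 2) & t_cued, latent.s2_cued, s_round)
    stoch = rng.random(n) < s_round
    unfind = np.where(t_copy == 1, unfindable1[t_disp], unfindable2[t_disp])

    miss = t_present & (unfind | stoch)
    fa = ~t_present & (rng.random(n) < latent.fa_rate)
    response = np.where(t_present, np.where(miss, "absent", "present"),
                        np.where(fa, "present", "absent"))

    state = np.empty(n, dtype=object)
    state[t_present & unfind & stoch] = "unfindable_stoch_miss"
    state[t_present & unfind & ~stoch] = "det_miss"
    state[t_present & ~unfind & stoch] = "stoch_miss"
    state[t_present & ~unfind & ~stoch] = "hit"
    state[~t_present & fa] = "false_alarm"
    state[~t_present & ~fa] = "correct_reject"

    median = (
        rt.base_ms
        + rt.slope_ms_per_item * t_set * np.where(t_present, 1.0, 2.0)
        + np.where(t_present, 0.0, rt.absent_extra_ms)
        - np.where(~t_present & (t_copy == 2), rt.round2_absent_speedup_ms, 0.0)
    )
    rts = median * np.exp(rt.sigma * rng.standard_normal(n))
    rts = np.where(rng.random(n) < rt.outlier_rate, rts * 10.0, rts)
    if rt.truncate_ms is not None:
        rts = np.minimum(rts, rt.truncate_ms)
    corrected = rng.random(n) < rt.correction_rate

    cue_group = np.array(
        [design.cue_assignment.get(t.display_id, "") for t in schedule]
    )
    cue_condition = np.where(t_cued, "cued", "none")

    trials = pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_index": np.arange(n),
            "display_id": [t.display_id for t in schedule],
            "copy": t_copy,
            "set_size": t_set,
            "target_present": t_present,
            "cue_condition": cue_condition,
            "cue_group": cue_group,
            "tb_contrast": tb[t_disp],
            "response": response,
            "rt_ms": rts,
            "corrected": corrected,
            "latent_state": state,
        }
    )
    return ParticipantSession(
        participant_id=participant_id,
        trials=trials,
        latent=latent,
        experiment=design.experiment,
        block_size=design.block_size,
    )


def _reassign_cues(design: Design, rng: np.random.Generator) -> Design:
    """Fresh per-participant random noCue-Cue / noCue-noCue split of an exp3 design."""
    ids = list(design.displays)
    cued_half = set(rng.permutation(len(ids))[: len(ids) // 2])
    assignment = {
        did: ("nocue_cue" if i in cued_half else "nocue_nocue")
        for i, did in enumerate(ids)
    }
    schedule = [
        ScheduledTrial(
            trial_index=t.trial_index,
            display_id=t.display_id,
            copy=t.copy,
            cued=(t.copy == 2 and assignment[t.display_id] == "nocue_cue"),
        )
        for t in design.schedule
    ]
    return replace(design, schedule=schedule, cue_assignment=assignment)


def simulate_cohort(
    n_participants: int,
    design: Design,
    latent_dist: LatentParams | Callable[[np.random.Generator], LatentParams],
    rt: RTModel | None = None,
    seed: int = 0,
    reassign_cues: bool = True,
) -> list[ParticipantSession]:
    """Simulate independent participants on one design.

    ``latent_dist`` is either a fixed :class:`LatentParams` shared by all
    participants or a callable drawing one per participant.  In the cued
    dialect each participant receives a fresh random cue split of the display
    set (disable with ``reassign_cues=False``).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_participants)
    sessions = []
    for i in range(n_participants):
        latent = (
            latent_dist if isinstance(latent_dist, LatentParams) else latent_dist(rng)
        )
        d = design
        if design.cue_assignment and reassign_cues:
            d = _reassign_cues(design, rng)
        sessions.append(
            simulate_participant(
                d, latent, rt, seed=int(seeds[i]), participant_id=f"sim-{i + 1:03d}"
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# Trial-log I/O


def write_cohort(sessions: Sequence[ParticipantSession], trials_path, latent_path=None):
    """Write a cohort trial log as CSV, with latent truth in a sidecar JSON."""
    pd.concat([s.trials for s in sessions], ignore_index=True).to_csv(
        trials_path, index=False
    )
    if latent_path is not None:
        doc = {
            s.participant_id: asdict(s.latent)
            for s in sessions
            if s.latent is not None
        }
        with open(latent_path, "w") as fh:
            json.dump(doc, fh, indent=1)


def load_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = (
        set(TRIAL_COLUMNS)
        - {"latent_state", "tb_contrast", "cue_group"}
        - set(df.columns)
    )
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    return df


def load_latents(path) -> dict[str, LatentParams]:
    with open(path) as fh:
        doc = json.load(fh)
    out = {}
    for pid, params in doc.items():
        link = params.get("contrast_link")
        if link is not None:
            params["contrast_link"] = tuple(link)
        out[pid] = LatentParams(**params)
    return out
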