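"""Shared fixtures: full designs are expensive to place, so build them once."""

import numpy as np
import pytest

from doublepass.stimulus_gen import (
    Design,
    DisplaySpec,
    LetterSpec,
    ScheduledTrial,
    build_design,
)


@pytest.fixture(scope="session")
def design_exp1():
    return build_design("exp1", rng_seed=1)


@pytest.fixture(scope="session")
def design_exp2b():
    return build_design("exp2b", rng_seed=3)


@pytest.fixture(scope="session")
def design_exp3():
    return build_design("exp3", rng_seed=5)


def make_present_design(
    n_displays: int,
    cue_half: bool = False,
    experiment: str = "synthetic",
    tb_levels=None,
    seed: int = 0,
) -> Design:
    """A minimal target-present-only two-copy design for simulator tests.

    Single-letter displays (the miss model only cares about target presence),
    uniform background.  With ``cue_half`` the displays are split into
    noCue-noCue / noCue-Cue halves; with ``tb_levels`` each display carries a
    nominal contrast cycled through the given levels.
    """
    rng = np.random.default_rng(seed)
    displays = {}
    cue_assignment = {}
    for i in range(n_displays):
        did = f"pd-{i:06d}"
        tb = None if tb_levels is None else int(tb_levels[i % len(tb_levels)])
        spec = DisplaySpec(
            display_id=did,
            letters=[LetterSpec(kind="T", x=0.5, y=0.5, orientation=360, gray=255)],
            target_present=True,
            set_size=1,
            background={"kind": "uniform", "gray": 128},
        )
        spec.tb_contrast = tb
        displays[did] = spec
        if cue_half:
            cue_assignment[did] = "nocue_cue" if i % 2 else "nocue_nocue"
    order = rng.permutation(2 * n_displays)
    slots = [(did, k) for did in displays for k in (1, 2)]
    schedule = []
    seen = set()
    for idx, slot in enumerate(order):
        did, _ = slots[slot]
        copy = 2 if did in seen else 1
        seen.add(did)
        cued = cue_half and copy == 2 and cue_assignment.get(did) == "nocue_cue"
        schedule.append(ScheduledTrial(idx, did, copy, cued))
    return Design(
        experiment=experiment,
        displays=displays,
        schedule=schedule,
        block_size=2 * n_displays,
        cue_assignment=cue_assignment,
    )
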