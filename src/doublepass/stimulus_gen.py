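"""Search-display generation: T-among-L arrays on uniform or 1/f noise backgrounds.

Coordinates are expressed in screen-height fractional units with the origin at
the top-left corner and y increasing downward.  All letter sizes are relative
to screen height, so a display rendered at any resolution keeps its geometry.

Four experiment dialects are supported:

``exp1``
    White letters on a uniform mid-gray background; 75 displays per
    (set size x target presence) cell, 300 unique displays, each shown twice
    across six 100-trial blocks (600 trials).
``exp2a``
    Letters of uniform-random grayscale on a 1/f^1.3 noise background,
    positions in [0.15, 0.85]; 300 displays / 600 trials as in exp1.
``exp2b``
    Pre-generated factorial design: target presence (2) x set size (2) x
    target-background contrast (8 levels) x target quadrant (4) = 128
    combinations, two arrays each -> 256 displays / 512 trials.
``exp3``
    The exp2b display set with a per-participant random split of the displays
    into a noCue-noCue half and a noCue-Cue half (cue shown on the second
    copy only).  Cues are emitted as schedule metadata, not rasterized.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ORIENTATIONS",
    "TB_LEVELS",
    "QUADRANTS",
    "LetterSpec",
    "DisplaySpec",
    "NoiseImage",
    "Design",
    "ScheduledTrial",
    "PlacementError",
    "generate_noise",
    "fit_spectral_exponent",
    "place_letters",
    "build_design",
    "render_display",
    "letter_mask",
    "tb_contrast",
]

#: The 12 permitted letter rotations, in degrees.
ORIENTATIONS = tuple(range(30, 361, 30))

#: Controlled target-minus-background grayscale levels of the exp2b dialect.
TB_LEVELS = (-105, -75, -45, -15, 15, 45, 75, 105)

#: Quadrant name -> (x-range, y-range) for the target center, exp2b dialect.
QUADRANTS = {
    "UL": ((0.15, 0.45), (0.15, 0.45)),
    "UR": ((0.55, 0.85), (0.15, 0.45)),
    "BL": ((0.15, 0.45), (0.55, 0.85)),
    "BR": ((0.55, 0.85), (0.55, 0.85)),
}

#: Nominal background gray used when computing the controlled T-B levels.
NOMINAL_BACKGROUND_GRAY = 128

#: Minimum center-to-center distance between letters, screen-height units.
MIN_LETTER_DISTANCE = 0.1

#: Stroke length of the two line segments composing a T or an L.
STROKE_LEN = 0.03


class PlacementError(RuntimeError):
    """Raised when letter positions cannot be placed within the attempt budget."""


@dataclass(frozen=True)
class LetterSpec:
    """One letter in a display.

    ``x``/``y`` locate the letter's bounding-box center; ``orientation`` is one
    of the 12 permitted rotations; ``gray`` is an 8-bit grayscale value;
    ``stroke_len`` is the segment length as a fraction of image height.
    """

    kind: str  # "T" or "L"
    x: float
    y: float
    orientation: int
    gray: int
    stroke_len: float = STROKE_LEN

    def __post_init__(self) -> None:
        if self.kind not in ("T", "L"):
            raise ValueError(f"letter kind must be 'T' or 'L', got {self.kind!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation {self.orientation} not in {ORIENTATIONS}")
        if not 0 <= self.gray <= 255:
            raise ValueError(f"gray {self.gray} outside 0-255")
        if not 0 < self.stroke_len < 1:
            raise ValueError(f"stroke_len {self.stroke_len} outside (0, 1)")


@dataclass
class DisplaySpec:
    """One search display: letters plus a background descriptor.

    ``background`` is either ``{"kind": "uniform", "gray": g}`` or
    ``{"kind": "noise", "seed": s, "exponent": e}``.  ``tb_contrast`` is the
    nominal target gray minus the nominal background gray (controlled in the
    exp2b dialect); ``quadrant`` names the target's spatial quadrant where the
    design controls it.
    """

    display_id: str
    letters: list[LetterSpec]
    target_present: bool
    set_size: int
    background: dict
    quadrant: str | None = None
    tb_contrast: int | None = None

    def validate(self) -> None:
        if len(self.letters) != self.set_size:
            raise ValueError(
                f"{self.display_id}: {len(self.letters)} letters != set_size {self.set_size}"
            )
        n_targets = sum(1 for let in self.letters if let.kind == "T")
        if n_targets != int(self.target_present):
            raise ValueError(
                f"{self.display_id}: {n_targets} targets but target_present={self.target_present}"
            )
        pts = np.array([(let.x, let.y) for let in self.letters])
        if len(pts) > 1:
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            if d.min() <= MIN_LETTER_DISTANCE:
                raise ValueError(
                    f"{self.display_id}: minimum letter distance {d.min():.4f} <= "
                    f"{MIN_LETTER_DISTANCE}"
                )
        if self.tb_contrast is not None and self.quadrant is not None:
            # exp2b dialect: controlled contrast level and quadrant membership
            if self.tb_contrast not in TB_LEVELS:
                raise ValueError(
                    f"{self.display_id}: tb_contrast {self.tb_contrast} not a controlled level"
                )
            if self.target_present:
                (x0, x1), (y0, y1) = QUADRANTS[self.quadrant]
                t = self.target
                if not (x0 <= t.x <= x1 and y0 <= t.y <= y1):
                    raise ValueError(
                        f"{self.display_id}: target ({t.x:.3f}, {t.y:.3f}) outside "
                        f"quadrant {self.quadrant}"
                    )

    @property
    def target(self) -> LetterSpec | None:
        for let in self.letters:
            if let.kind == "T":
                return let
        return None

    def min_pairwise_distance(self) -> float:
        pts = np.array([(let.x, let.y) for let in self.letters])
        if len(pts) < 2:
            return math.inf
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        return float(d.min())


@dataclass
class NoiseImage:
    """A synthesized 1/f^exponent noise background (8-bit grayscale)."""

    pixels: np.ndarray
    exponent: float
    seed: int


@dataclass(frozen=True)
class ScheduledTrial:
    """One slot in the trial schedule: which display, which copy, cued or not."""

    trial_index: int
    display_id: str
    copy: int  # 1 or 2
    cued: bool = False


@dataclass
class Design:
    """A full experiment design: the display set plus the two-copy schedule."""

    experiment: str
    displays: dict[str, DisplaySpec]
    schedule: list[ScheduledTrial]
    block_size: int
    cue_assignment: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        doc = {
            "experiment": self.experiment,
            "block_size": self.block_size,
            "displays": {k: asdict(v) for k, v in self.displays.items()},
            "schedule": [asdict(t) for t in self.schedule],
            "cue_assignment": self.cue_assignment,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "Design":
        with open(path) as fh:
            doc = json.load(fh)
        displays = {
            k: DisplaySpec(
                display_id=v["display_id"],
                letters=[LetterSpec(**let) for let in v["letters"]],
                target_present=v["target_present"],
                set_size=v["set_size"],
                background=v["background"],
                quadrant=v.get("quadrant"),
                tb_contrast=v.get("tb_contrast"),
            )
            for k, v in doc["displays"].items()
        }
        schedule = [ScheduledTrial(**t) for t in doc["schedule"]]
        return cls(
            experiment=doc["experiment"],
            displays=displays,
            schedule=schedule,
            block_size=doc["block_size"],
            cue_assignment=doc.get("cue_assignment", {}),
        )


# ---------------------------------------------------------------------------
# Noise synthesis


def generate_noise(
    height: int, width: int, exponent: float = 1.3, seed: int = 0
) -> NoiseImage:
    """Synthesize a 1/f^exponent noise image by frequency-domain shaping.

    A complex Gaussian spectrum is multiplied by an amplitude envelope
    proportional to f^(-exponent/2), inverse-transformed, and linearly
    rescaled to the full 0-255 range (DC is zeroed, so the rescale centers
    the image near mid-gray).  The result is deterministic given ``seed``.
    """
    if height < 32 or width < 32:
        raise ValueError(f"image dimensions must be >= 32, got {height}x{width}")
    if exponent < 0:
        raise ValueError(f"exponent must be >= 0, got {exponent}")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # placeholder; DC amplitude zeroed below
    amp = f ** (-exponent / 2.0)
    amp[0, 0] = 0.0
    spectrum = amp * (
        rng.standard_normal((height, width)) + 1j * rng.standard_normal((height, width))
    )
    img = np.fft.ifft2(spectrum).real
    lo, hi = img.min(), img.max()
    if hi == lo:  # pragma: no cover - cannot happen for nonzero spectra
        img = np.full_like(img, 127.5)
    else:
        img = (img - lo) / (hi - lo) * 255.0
    return NoiseImage(
        pixels=np.round(img).astype(np.uint8), exponent=exponent, seed=seed
    )


def fit_spectral_exponent(
    pixels: np.ndarray, f_lo: float | None = None, f_hi: float = 0.25
) -> float:
    """Estimate the 1/f exponent of an image from its radial power spectrum.

    The 2-D power spectrum is radially averaged into integer-radius bins and a
    line is fitted to log power versus log frequency over mid frequencies
    (by default from 4 cycles/image up to 0.25 cycles/pixel, avoiding both the
    noisy lowest bins and the anisotropic Nyquist corner).  Returns the
    negated log-log slope, so a 1/f^1.3 image yields ~1.3.
    """
    x = pixels.astype(float)
    x -= x.mean()
    h, w = x.shape
    power = np.abs(np.fft.fft2(x)) ** 2
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    n = min(h, w)
    if f_lo is None:
        f_lo = 4.0 / n
    # integer-radius ring bins in units of cycles/image (of the smaller axis)
    r = np.round(f * n).astype(int)
    mask = (f >= f_lo) & (f <= f_hi)
    rings = np.bincount(r[mask], weights=power[mask])
    counts = np.bincount(r[mask])
    valid = counts > 0
    radial_power = rings[valid] / counts[valid]
    radial_f = np.nonzero(valid)[0] / n
    slope = np.polyfit(np.log(radial_f), np.log(radial_power), 1)[0]
    return -slope


# ---------------------------------------------------------------------------
# Letter placement


def place_letters(
    set_size: int,
    region: tuple[float, float, float, float],
    min_dist: float = MIN_LETTER_DISTANCE,
    rng_seed: int | np.random.Generator = 0,
    existing: list[tuple[float, float]] | None = None,
    max_attempts: int = 10_000,
) -> list[tuple[float, float]]:
    """Sample ``set_size`` letter centers in ``region`` with pairwise distance > min_dist.

    ``region`` is (x0, y0, x1, y1) in screen-height units.  Rejection sampling
    with a total attempt budget; ``existing`` points (e.g. an already-placed
    target) are respected but not returned.  Raises :class:`PlacementError`
    when the budget is exhausted, which signals a region too small for the
    requested packing.
    """
    if set_size < 1:
        raise ValueError(f"set_size must be >= 1, got {set_size}")
    x0, y0, x1, y1 = region
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"degenerate region {region}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n_existing = len(existing) if existing else 0
    buf = np.empty((n_existing + set_size, 2))
    if existing:
        buf[:n_existing] = existing
    n = n_existing
    attempts = 0
    min_d2 = min_dist * min_dist
    while n < n_existing + set_size:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {set_size} letters in region {region} at "
                f"min_dist {min_dist} within {max_attempts} attempts"
            )
        attempts += 1
        x = rng.uniform(x0, x1)
        y = rng.uniform(y0, y1)
        if n:
            dx = buf[:n, 0] - x
            dy = buf[:n, 1] - y
            if np.min(dx * dx + dy * dy) <= min_d2:
                continue
        buf[n] = (x, y)
        n += 1
    return [tuple(p) for p in buf[n_existing:]]


# ---------------------------------------------------------------------------
# Design construction

#: Letter-center region of the exp1 dialect (0.7-side square, centered).
EXP1_REGION = (0.15, 0.15, 0.85, 0.85)
#: Letter-center region of the exp2 dialects.
EXP2_REGION = (0.15, 0.15, 0.85, 0.85)

SET_SIZES = (18, 36)
N_NOISE_BACKGROUNDS = 10


def _psychopy_gray(rng: np.random.Generator) -> int:
    """Uniform grayscale drawn as (rand()-0.5)*2 in [-1, 1], mapped to 0-255.

    The mapping is g255 = round((g+1)/2 * 255) with half-away-from-zero
    rounding (all values here are non-negative, so this equals floor(v+0.5)).
    """
    g = (rng.random() - 0.5) * 2.0
    return int(math.floor((g + 1.0) / 2.0 * 255.0 + 0.5))


def _sample_orientation(rng: np.random.Generator) -> int:
    return int(ORIENTATIONS[rng.integers(len(ORIENTATIONS))])


def _place_with_retries(
    set_size, region, rng, existing=None, retries: int = 20
) -> list[tuple[float, float]]:
    """Placement with whole-display restarts: dense packings occasionally jam."""
    for _ in range(retries):
        try:
            return place_letters(
                set_size, region, MIN_LETTER_DISTANCE, rng, existing=existing
            )
        except PlacementError:
            continue
    raise PlacementError(
        f"placement failed after {retries} restarts for set_size {set_size}"
    )


def _make_exp1_display(display_id, set_size, target_present, rng) -> DisplaySpec:
    positions = _place_with_retries(set_size, EXP1_REGION, rng)
    target_idx = int(rng.integers(set_size)) if target_present else -1
    letters = [
        LetterSpec(
            kind="T" if i == target_idx else "L",
            x=x,
            y=y,
            orientation=_sample_orientation(rng),
            gray=255,
        )
        for i, (x, y) in enumerate(positions)
    ]
    return DisplaySpec(
        display_id=display_id,
        letters=letters,
        target_present=target_present,
        set_size=set_size,
        background={"kind": "uniform", "gray": NOMINAL_BACKGROUND_GRAY},
    )


def _make_exp2a_display(display_id, set_size, target_present, rng, noise_seeds):
    positions = _place_with_retries(set_size, EXP2_REGION, rng)
    target_idx = int(rng.integers(set_size)) if target_present else -1
    letters = [
        LetterSpec(
            kind="T" if i == target_idx else "L",
            x=x,
            y=y,
            orientation=_sample_orientation(rng),
            gray=_psychopy_gray(rng),
        )
        for i, (x, y) in enumerate(positions)
    ]
    tb = (
        letters[target_idx].gray - NOMINAL_BACKGROUND_GRAY if target_present else None
    )
    spec = DisplaySpec(
        display_id=display_id,
        letters=letters,
        target_present=target_present,
        set_size=set_size,
        background={
            "kind": "noise",
            "seed": int(noise_seeds[rng.integers(len(noise_seeds))]),
            "exponent": 1.3,
        },
    )
    spec.tb_contrast = tb  # continuous dialect: not validated against levels
    spec.quadrant = None
    return spec


def _make_exp2b_display(
    display_id, set_size, target_present, tb, quadrant, rng, noise_seeds
) -> DisplaySpec:
    (qx0, qx1), (qy0, qy1) = QUADRANTS[quadrant]
    target_pos = None
    if target_present:
        target_pos = (rng.uniform(qx0, qx1), rng.uniform(qy0, qy1))
        existing = [target_pos]
        n_rest = set_size - 1
    else:
        existing = None
        n_rest = set_size
    positions = _place_with_retries(n_rest, EXP2_REGION, rng, existing=existing)
    letters = []
    if target_present:
        letters.append(
            LetterSpec(
                kind="T",
                x=target_pos[0],
                y=target_pos[1],
                orientation=_sample_orientation(rng),
                gray=NOMINAL_BACKGROUND_GRAY + tb,
            )
        )
    letters.extend(
        LetterSpec(
            kind="L",
            x=x,
            y=y,
            orientation=_sample_orientation(rng),
            gray=_psychopy_gray(rng),
        )
        for x, y in positions
    )
    return DisplaySpec(
        display_id=display_id,
        letters=letters,
        target_present=target_present,
        set_size=set_size,
        background={
            "kind": "noise",
            "seed": int(noise_seeds[rng.integers(len(noise_seeds))]),
            "exponent": 1.3,
        },
        quadrant=quadrant,
        tb_contrast=tb,
    )


def _two_copy_schedule(display_ids, rng, cue_assignment=None) -> list[ScheduledTrial]:
    """Randomly intermix two copies of every display; copy order follows slot order."""
    slots = [(did, k) for did in display_ids for k in (1, 2)]
    order = rng.permutation(len(slots))
    # renumber copies by presentation order, then assign cue flags
    first_seen: dict[str, int] = {}
    schedule = []
    for idx, slot in enumerate(order):
        did, _ = slots[slot]
        copy = 1 if did not in first_seen else 2
        first_seen.setdefault(did, idx)
        cued = bool(
            cue_assignment and copy == 2 and cue_assignment.get(did) == "nocue_cue"
        )
        schedule.append(
            ScheduledTrial(trial_index=idx, display_id=did, copy=copy, cued=cued)
        )
    return schedule


def build_design(experiment: str, rng_seed: int = 0) -> Design:
    """Build the display set and two-copy trial schedule of one dialect.

    exp1: 75 displays per (set size x presence) cell -> 300 displays, 600
    trials in six blocks of 100.  exp2a: as exp1 but noise backgrounds and
    random grayscales.  exp2b: the 128-combination factorial x 2 arrays ->
    256 displays, 512 trials in four blocks of 128.  exp3: the exp2b design
    plus a random 50/50 noCue-noCue / noCue-Cue split of the displays.
    """
    if experiment not in ("exp1", "exp2a", "exp2b", "exp3"):
        raise ValueError(f"unknown experiment dialect {experiment!r}")
    rng = np.random.default_rng(rng_seed)
    displays: dict[str, DisplaySpec] = {}

    if experiment in ("exp1", "exp2a"):
        noise_seeds = rng.integers(0, 2**31 - 1, size=N_NOISE_BACKGROUNDS)
        for set_size in SET_SIZES:
            for present in (True, False):
                for version in range(75):
                    did = (
                        f"{experiment}-s{set_size}-"
                        f"{'p' if present else 'a'}-{version:03d}"
                    )
                    if experiment == "exp1":
                        displays[did] = _make_exp1_display(did, set_size, present, rng)
                    else:
                        displays[did] = _make_exp2a_display(
                            did, set_size, present, rng, noise_seeds
                        )
        schedule = _two_copy_schedule(list(displays), rng)
        return Design(experiment, displays, schedule, block_size=100)

    # exp2b / exp3 factorial display set
    noise_seeds = rng.integers(0, 2**31 - 1, size=N_NOISE_BACKGROUNDS)
    for present in (True, False):
        for set_size in SET_SIZES:
            for tb in TB_LEVELS:
                for quadrant in QUADRANTS:
                    for array in (1, 2):
                        did = (
                            f"{experiment}-{'p' if present else 'a'}-s{set_size}"
                            f"-tb{tb:+d}-{quadrant}-{array}"
                        )
                        displays[did] = _make_exp2b_display(
                            did, set_size, present, tb, quadrant, rng, noise_seeds
                        )
    cue_assignment: dict[str, str] = {}
    if experiment == "exp3":
        ids = list(displays)
        cued_half = set(rng.permutation(len(ids))[: len(ids) // 2])
        cue_assignment = {
            did: ("nocue_cue" if i in cued_half else "nocue_nocue")
            for i, did in enumerate(ids)
        }
    schedule = _two_copy_schedule(list(displays), rng, cue_assignment)
    return Design(
        experiment, displays, schedule, block_size=128, cue_assignment=cue_assignment
    )


# ---------------------------------------------------------------------------
# Rendering and contrast measurement


def _letter_segments(letter: LetterSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stroke endpoints in screen-height units after rotation and centering.

    T: a horizontal bar centered atop a vertical stem.  L: two strokes joined
    at one end.  Rotation is about the letter's bounding-box center, which is
    also the (x, y) anchor.
    """
    L = letter.stroke_len
    if letter.kind == "T":
        segs = [((-L / 2, 0.0), (L / 2, 0.0)), ((0.0, 0.0), (0.0, L))]
        center = (0.0, L / 2)
    else:
        segs = [((0.0, 0.0), (0.0, L)), ((0.0, L), (L, L))]
        center = (L / 2, L / 2)
    theta = math.radians(letter.orientation % 360)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    out = []
    for a, b in segs:
        a = rot @ (np.asarray(a) - center) + (letter.x, letter.y)
        b = rot @ (np.asarray(b) - center) + (letter.x, letter.y)
        out.append((a, b))
    return out


def _paint_segment(mask: np.ndarray, a, b, half_width_px: float, scale: float) -> None:
    """Set mask pixels whose centers lie within half_width of segment ab (butt caps)."""
    h, w = mask.shape
    ax, ay = a[0] * scale, a[1] * scale
    bx, by = b[0] * scale, b[1] * scale
    x_lo = max(int(math.floor(min(ax, bx) - half_width_px - 1)), 0)
    x_hi = min(int(math.ceil(max(ax, bx) + half_width_px + 1)), w - 1)
    y_lo = max(int(math.floor(min(ay, by) - half_width_px - 1)), 0)
    y_hi = min(int(math.ceil(max(ay, by) + half_width_px + 1)), h - 1)
    if x_hi < x_lo or y_hi < y_lo:
        return
    ys, xs = np.mgrid[y_lo : y_hi + 1, x_lo : x_hi + 1]
    px = xs + 0.5
    py = ys + 0.5
    dx, dy = bx - ax, by - ay
    seg_len2 = dx * dx + dy * dy
    t = ((px - ax) * dx + (py - ay) * dy) / seg_len2
    perp = np.abs((px - ax) * dy - (py - ay) * dx) / math.sqrt(seg_len2)
    inside = (t >= 0.0) & (t <= 1.0) & (perp <= half_width_px)
    mask[y_lo : y_hi + 1, x_lo : x_hi + 1] |= inside


def letter_mask(letter: LetterSpec, shape: tuple[int, int]) -> np.ndarray:
    """Boolean pixel mask of one letter at the given image shape."""
    h, _ = shape
    mask = np.zeros(shape, dtype=bool)
    # stroke width is a convention (the designs specify only stroke length)
    half_width = max(1.0, 0.003 * h) / 2.0
    for a, b in _letter_segments(letter):
        _paint_segment(mask, a, b, half_width, scale=h)
    return mask


def render_display(spec: DisplaySpec, size: int = 1000) -> np.ndarray:
    """Rasterize a display to an 8-bit grayscale image (size x size).

    Each letter is drawn as two strokes of length ``stroke_len`` x height at
    its orientation on the background the spec describes.  Deterministic:
    the same spec always renders to the same pixels.
    """
    bg = spec.background
    if bg["kind"] == "uniform":
        img = np.full((size, size), bg["gray"], dtype=np.uint8)
    elif bg["kind"] == "noise":
        img = generate_noise(size, size, bg.get("exponent", 1.3), bg["seed"]).pixels.copy()
    else:
        raise ValueError(f"unknown background kind {bg['kind']!r}")
    for letter in spec.letters:
        pad = letter.stroke_len  # generous bound on the rotated letter extent
        if not (0 <= letter.x - pad and letter.x + pad <= 1 and
                0 <= letter.y - pad and letter.y + pad <= 1):
            raise ValueError(
                f"{spec.display_id}: letter at ({letter.x:.3f}, {letter.y:.3f}) "
                "extends outside the image"
            )
        img[letter_mask(letter, img.shape)] = letter.gray
    return img


def tb_contrast(
    image: np.ndarray, target: LetterSpec, patch_scale: float = 2.0
) -> float:
    """Target gray minus mean background gray around the target.

    The background patch is a square of side ``patch_scale`` x stroke length
    centered on the target; the target's own pixels are excluded from the
    background mean.  This is the rendered-image analogue of the nominal T-B
    level of the controlled-contrast dialect.
    """
    h, w = image.shape
    side = patch_scale * target.stroke_len * h
    cx, cy = target.x * h, target.y * h
    x_lo = max(int(math.floor(cx - side / 2)), 0)
    x_hi = min(int(math.ceil(cx + side / 2)), w)
    y_lo = max(int(math.floor(cy - side / 2)), 0)
    y_hi = min(int(math.ceil(cy + side / 2)), h)
    if x_hi <= x_lo or y_hi <= y_lo:
        raise ValueError("degenerate contrast patch after clipping to image bounds")
    patch = image[y_lo:y_hi, x_lo:x_hi].astype(float)
    own = letter_mask(target, image.shape)[y_lo:y_hi, x_lo:x_hi]
    bg_pixels = patch[~own]
    if bg_pixels.size == 0:
        raise ValueError("contrast patch contains no background pixels")
    return float(target.gray - bg_pixels.mean())
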