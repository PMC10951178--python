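# Methods

## The four-state miss model

Each target-present display is either fundamentally *unfindable* for a given
participant (its target will be missed for a display-bound, repeatable
reason) or *findable*.  Unfindability is a property of the
participant-display pair: it is drawn once and persists across the two
presentations — a findable display never becomes unfindable, while an
intervention on the second pass may convert unfindable displays to findable.
Independently, any trial can produce a *stochastic* miss (lapse, random
guess) with a per-pass probability.  A trial therefore ends in one of four
states: hit, stochastic miss on a findable display, deterministic miss on an
unfindable display, or an unfindable display that would have been missed
stochastically anyway.

With d1, d2 the unfindable proportions on pass 1 and 2 (d2 ≤ d1) and s1, s2
the per-pass stochastic rates, the observable miss rates compose as

    P1  = d1(1 − s1) + s1
    P2  = d2 + s2(d1 − d2) + (1 − d1)s2
    P12 = d2 + s2(d1 − d2) + s1(1 − d1)s2

Two special cases give the qualitative diagnostic: d = 0 implies
P12 = P1·P2 (the product rule of independent errors) and s1 = s2 = 0 implies
P12 = min(P1, P2).  Mixtures always satisfy P1·P2 ≤ P12 ≤ min(P1, P2).

**Uncued solver.**  With a fixed deterministic proportion (d = d1 = d2) the
system inverts uniquely:
d = (P12 − P1·P2)/(1 − P1 − P2 + P12), s1 = (P1 − P12)/(1 − P2),
s2 = (P2 − P12)/(1 − P1).

**Cued solver.**  When the second copy carries a cue, d2 ≤ d1 and the system
is under-determined.  d2 and s2 keep the same closed forms; s1 is recovered
by borrowing the participant's uncued-condition d as d1 (deterministic
errors persist when nothing intervenes): s1 = (P1 − d1)/(1 − d1).  The
borrow defaults to the participant level; a cohort-mean borrow is available
(`cue_d1_source="group"`).  Because the cue split of the displays is random
per participant, the borrowed d1 can overestimate the cued half's true d1;
when that makes s1 negative the estimate cell is excluded
(`negative_s1`).

**Estimator conventions.**  A solved d in [−0.002, 0) is treated as sampling
noise around zero and rounded to 0 (flagged `rounded_d`); d < −0.002
excludes the cell (`d_below_threshold`).  Denominators within 1e−9 of zero
exclude the cell (`degenerate_denominator`) instead of producing infinities.
Estimates are never silently clipped to [0, 1]: the raw solved d is kept in
`d_raw` so recovery analyses can see the undistorted estimator.  This
matters: the rounding and exclusion rules are one-sided, and at
128-pair scale with a true d of 0 they shift the retained cohort mean
visibly positive; recovery tests therefore assert on `d_raw`, while reported
tables apply the rules.  The cued solver applies only the negative-s1 rule —
clipping d2 would bias the d1-versus-d2 comparison that the cued design
exists to test.

## Design generation

Sizes are fractions of screen height (origin top-left, y downward), so a
rendered display is resolution-independent; the default raster is
1000×1000.  Letters are two strokes of length 0.03 screen height joined as a
T or an L, at orientations drawn from {30°, …, 360°}; stroke width is a
rendering convention (0.003 × height, minimum 1 px, butt caps, no
anti-aliasing) since only stroke length is constrained by the designs.

Dialects: `exp1` (white letters, uniform mid-gray background, 75 displays
per set-size × presence cell → 300 displays / 600 trials in six 100-trial
blocks), `exp2a` (as exp1 with uniform-random letter grayscales and noise
backgrounds, letter centers in [0.15, 0.85]), `exp2b` (factorial: presence ×
set size × eight target−background levels {±15, ±45, ±75, ±105} × four
target quadrants, two arrays per cell → 256 displays / 512 trials), and
`exp3` (the exp2b set plus a per-participant random 50/50 split into
noCue–noCue and noCue–Cue halves, the cue applying to second copies only;
cues are schedule metadata, not rasterized animations).  Grayscales sampled
in [−1, 1] map to 0–255 via round((g+1)/2·255), half away from zero.

Letter placement is rejection sampling with pairwise center distance
strictly > 0.1 screen height and a 10,000-attempt budget per display.
Thirty-six letters in the 0.7-side square is a dense packing (roughly 80% of
the random-sequential-adsorption jamming density once boundary effects are
counted), so a small fraction of attempts jam; the design generator restarts
the display with fresh draws (up to 20 restarts) rather than failing.

Noise backgrounds are synthesized in the frequency domain: a complex
Gaussian spectrum shaped by f^(−exponent/2) (exponent 1.3 by default, DC
zeroed), inverse-transformed and linearly rescaled to the full 0–255 range.
The spectral exponent is verified by radially averaging the power spectrum
into integer-radius rings and fitting the log-log slope over mid
frequencies (4 cycles/image to 0.25 cycles/pixel), which avoids both the
noisy lowest rings and the anisotropic Nyquist corner; 8-bit quantization
costs a few hundredths of the fitted exponent at most.

Target–background contrast of a rendered display is the target's gray minus
the mean background gray in a square patch centered on the target (side =
2 × stroke length), excluding the target's own pixels.

## Simulator scope

The simulator draws the stochastic process on every trial and records the
cause of each outcome (`latent_state`), so the model's taxonomy is fully
observable while the totals collapse to the composition equations above.
The cue acts only through unfindable→findable conversion (probability
1 − d2/d1 on eligible second copies) by default; an optional `s2_cued` knob
exists because the stochastic channel is the competing hypothesis.  An
optional contrast link makes per-display unfindability a decreasing
logistic function of |T−B| with ceiling d1, emulating low-contrast targets
being the deterministically missed ones.

Reaction times are lognormal with a set-size slope (doubled on
target-absent trials), an absent-trial intercept and a second-pass speed-up
on absent trials — a deliberately coarse qualitative match whose only job is
to give the exclusion pipeline realistic material.  RT outliers (×10),
motor-correction flags and false alarms are injected independently of the
miss process.  None of these RT parameters claims quantitative fidelity to
human data, and the simulator makes no attempt at cognitive-process realism
(no eye movements, no functional visual field, no speed–accuracy coupling);
passing recovery tests validate the estimators and pipeline plumbing, not
any claim about human behavior.

## Exclusion pipeline

Order: (1) extreme screen, RT > 100 s; (2) per-cell trim of RTs strictly
outside mean ± 2.5 sample SDs, cells being participant × presence × set
size (plus repetition × cue in the cued dialect), computed after the
extreme screen and before motor-correction removal (the listed order of the
procedure; a switch exists because the alternative order is defensible);
(3) motor-corrected trial removal; (4) pair removal, so surviving displays
contribute both copies or neither.  Boundary equality is retained
("outside" is strict), and a zero-SD cell removes nothing.  d′ =
z(HR) − z(FAR) with perfect rates replaced by (n − 0.5)/n and 0.5/n;
participants beyond 2.5 SD from the group-mean d′ are excluded (skipped
with a warning below 3 participants).  All removals are bookkept so that
extreme + trimmed + corrected + pair-removed + remaining = total.

## Statistics

Two-sided t-tests throughout, no multiple-testing correction; Cohen's d for
paired tests uses the SD of the paired differences.  Identical paired
samples return t = 0, p = 1 (a well-defined no-effect case) rather than an
error.  Binned hit-rate and RT summaries aggregate within participant
first, then report mean ± SEM across participants (n − 1 denominator).

## Problem sizes in the validation suite

The test suite exercises the chain at the native design sizes (300/600 for
exp1, 256/512 for exp2b/exp3).  Monte-Carlo recovery uses 100 replicate
cohorts of 20 participants with 128 present display-pairs each — the
controlled-contrast scale — for the d = 0 false-positive rate, the d = 0.1
power check, and the cued d1-versus-d2 detection; analytic round-trips use
10,000 random parameter draws at tolerance 1e−12, with parameters drawn in
(0.001, 0.9) so denominators stay away from the degenerate surface where
floating-point amplification would dominate.

## Known limitations

- The decomposition is method-of-moments, not likelihood-based; no
  per-participant confidence intervals beyond cohort t-tests.
- The negative-s1 and d < −0.002 exclusions induce selection on noisy
  estimates; at small pair counts this can visibly bias retained-cell
  means (documented above, and the reason `d_raw` exists).
- Cue animation (dot path, spiral square, item boxes) is represented as
  schedule metadata only; timing and rendering of cues are out of scope.
- The RT model is generative plumbing; RT analyses beyond per-cell
  descriptives (e.g. repeated-measures ANOVA) are out of scope.
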