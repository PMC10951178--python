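# doublepass

Are the targets people miss in visual search missed *at random*, or are some
displays reliably error-prone?  `doublepass` implements the repeated-display
("double-pass") analysis that separates the two: every search display is
shown twice, and the three observable miss rates — P1 (first pass), P2
(second pass) and P12 (missed on both passes) — pin down the answer.

- purely **stochastic** errors are independent across passes: P12 = P1·P2
- purely **deterministic** errors recur on the same displays: P12 = min(P1, P2)
- a mixture falls in between, and inverts in closed form:

```
d  = (P12 − P1·P2) / (1 − P1 − P2 + P12)      deterministic proportion
s1 = (P1 − P12) / (1 − P2)                     stochastic rate, pass 1
s2 = (P2 − P12) / (1 − P1)                     stochastic rate, pass 2
```

When the second pass carries an attention-guiding cue that may rescue
otherwise-unfindable targets, the deterministic proportion can drop
(d2 ≤ d1); d2 and s2 stay uniquely solvable and s1 is recovered by borrowing
the participant's uncued d as d1: s1 = (P1 − d1)/(1 − d1).

The package is aimed at visual-search and behavioral-error researchers.  It
contains the whole experimental chain, so the estimators can be validated by
parameter recovery without any human data:

- `stimulus_gen` — T-among-L display generation (set sizes 18/36, letter
  rotations in 30° steps, minimum inter-letter distance 0.1 screen height)
  on uniform or 1/f^1.3 noise backgrounds, including the controlled
  target-contrast factorial design and target–background contrast
  measurement on rendered images;
- `synthetic_behavior` — trial-level simulation under the four-state miss
  model with known (d1, d2, s1, s2), plus reaction times, motor corrections
  and false alarms;
- `preprocess` — the exclusion pipeline (extreme-RT screen, per-cell
  mean ± 2.5 SD trimming, motor-correction removal, paired-copy removal) and
  d′ participant screening;
- `decompose` — observed rates, prediction bounds and the closed-form
  solvers with their rounding/exclusion conventions;
- `report` — cohort t-tests with Cohen's d, contrast-binned hit rates,
  miss-rate differences and the P12 prediction scatter.

## Worked example

```python
from doublepass import (build_design, simulate_cohort, LatentParams, RTModel,
                        DoublePassModel)

design = build_design("exp2b", rng_seed=1)           # 256 displays, 512 trials
latent = LatentParams(d1=0.06, s1=0.10, s2=0.08, fa_rate=0.02)
sessions = simulate_cohort(20, design, latent,
                           RTModel(outlier_rate=0.01, correction_rate=0.01),
                           seed=42)
results = DoublePassModel.from_sessions(sessions, dialect="exp2b").fit()
print(results.summary())
```

prints

```
Double-Pass Miss-Error Decomposition
====================================================================
Dialect: exp2b    Participants: 20 (0 screened out by d')
Trials: 10240 -> 9710 after cleaning (94.8% remain; 1.71% RT outliers, 0.90% motor-corrected)

condition        n      P1      P2     P12      d1      d2      s1      s2
--------------------------------------------------------------------
all             20   0.145   0.126   0.058   0.051   0.051   0.099   0.079
--------------------------------------------------------------------
d = 0 (all): one_sample_t: t(19) = 11.757, p = 3.657e-10, Cohen's d = 2.63, n = 20
s1 vs s2 (all): paired_t: t(19) = 5.480, p = 2.753e-05, Cohen's d = 1.23, n = 20
```

The cohort-mean decomposition (d ≈ 0.051, s1 ≈ 0.099, s2 ≈ 0.079) recovers
the simulated ground truth (0.06, 0.10, 0.08); the d-versus-zero test
correctly detects the deterministic component, and the observed P12 (0.058)
sits between the stochastic bound P1·P2 (≈ 0.018) and the deterministic
bound min(P1, P2) (0.126).  `results.estimates` holds the per-participant
table, `results.plot_predictions()` the scatter against both bounds, and
`results.contrast_split()` the low/high-contrast decomposition.

A `doublepass` command-line group wraps the same chain
(`gen-design`, `render`, `simulate`, `preprocess`, `decompose`, `report`).

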