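# Methods

This note documents the models, conventions and numerical choices behind
the package, in the spirit of a statistical software methods appendix.

## Scale and sequence representation

Tones are Bohlen-Pierce scale degrees over a 440 Hz fundamental,
`F = k · 3^(n/13)`; degrees — not frequencies — are the canonical
representation, because the games operate on five keyboard keys mapped
to the fixed degrees {0, 4, 6, 7, 10}. Hz values are derived for display
(1-decimal rounding) and audio. The contour alphabet is ternary
{+1, 0, −1}: the seed material contains a monotone control signal, and
only a "repeat" symbol makes its contour entropy exactly 0 bits.

## Game measures

**Windows.** "Second half" of the 70-trial learning game is trials
36–70, the only even split consistent with the trial count.

**Modal codes.** Signals are tallied in tone space (a signal's identity
is its five degrees); contour-distance measures apply the contour
transform to the tone-modal signal. Ties break to the signal whose
maximal count was attained at the earliest trial, then to the lowest
lexicographic degree sequence, making every result deterministic.

**Coordination** offers two variants: `set_mean` (default), the mean
similarity between the sender's signal and *every* signal the receiver
mapped to the same emotion in the second half, and `modal`, the
similarity to the receiver's modal signal only. Both are exposed because
reasonable operationalizations differ; on a well-learned code they
coincide.

**Asymmetry** counts a sender change when a produced signal for a state
differs from that sender's most recent signal for the same state, and a
receiver change when a guess for a previously heard signal differs from
the most recent guess for the identical signal; first occurrences are
not changes. `(S − R)/(S + R)` is undefined (NaN, warned) when no
changes occurred.

**Entropy attribution.** Game-1 mean entropy (and ICR) is that of the
seed code the confederate played; Game-2 values are those of the
participant-as-sender modal code. The regularization deltas are
`H_g1 − H_g2` (positive = simplification) and `ICR_g2 − ICR_g1`
(positive = stronger interval compression). The ICR subtraction order is
a declared convention; the group-level sign of the underlying test is
unaffected up to reflection.

**ICR.** The numerator averages the mean absolute successive interval
(in scale steps) over position permutations of the five tones — by
default 100 permutations sampled uniformly with replacement from the
120, or an exact enumeration used as the test oracle. A constant
sequence (zero denominator) takes ICR = 1.0 by convention, flagged; the
per-code mean can include or exclude such degenerate signals (included
by default, so the monotone control contributes a neutral 1.0).

## Oddball design

Onset-to-onset spacing is 450 ms (five 50 ms tones with 50 ms gaps)
plus the 750 ms inter-sequence interval = 1200 ms, so the required
2400–4800 ms within-pair deviant gap corresponds to 2–4 stimulus
positions. Deviant pairs never interleave: same-type adjacent pairs are
separated by at least four standards, so a deviant's nearest same-type
neighbor is always its partner. Surplus standards are laid down in
chunks of 16 at random slots, guaranteeing enough long standard runs for
the balanced extraction (each modeled standard needs five standards on
both sides; a chunked run of length ≥ 17 yields ≥ 7 eligible events).
Registers transpose the whole sequence so its lowest tone sits at degree
0, 1 or 3 (≈ 440, 479, 567 Hz). Deviants change only the fourth tone:
the contour deviant flips the 3rd→4th interval direction at equal size,
the interval deviant doubles the step at equal direction — the minimal
degree changes satisfying each constraint.

## Synthetic cohort

No agent model exists for the original task, so the generator is a
deliberately minimal invention that produces the qualitative structure
the analysis tests, with one latent ability scalar per participant:

- *Learning*: the receiver's guess is correct with probability
  `logistic(logit(0.2) + learn_rate · exposures · exp(ability))` —
  chance at first exposure, rising with repetitions, faster for higher
  ability. Default `learn_rate = 0.25` puts an average participant near
  87% correct by the 13th exposure, a plausible learning curve for a
  five-alternative task.
- *Innovation*: each reproduced position mutates with probability
  `innovation_rate`, drawn per participant as
  `logistic(logit(0.35) − 0.8 · ability + Normal(0, 0.5))`, coupling
  transmission fidelity (positively) and innovation (negatively) to
  ability.
- *Regularization*: a mutated position copies its left neighbor's degree
  with probability `regularization_bias ~ Beta(2, 2)` (a
  contour-smoothing, interval-shrinking move), else takes a uniform
  random game key.
- *Connectivity*: each ROI-pair z value is
  `mean + loading · ability + Normal(0, 0.25)`; default loadings of 0.11
  on lHG–lSTG and lSTG–rSTG give a population correlation with ability
  of ≈ 0.4 for those pairs and 0 elsewhere.
- Emotions appear in balanced blocks of five, independently permuted —
  the real presentation schedule is unpublished, and block balancing
  gives every emotion 14 exposures in Game 1 and 6 in Game 2.

One master seed spawns independent per-participant substreams, so
cohorts are bit-reproducible and participants independent. Seed sets A
and B (each with contour entropies {1, 1, 0.81, 0.81, 0} bits over the
game keys) alternate across participants.

What the generator does *not* emulate: response times, confederate
errors, multi-generation chains, BOLD time series, or the human group
means. In particular, at default parameters the simulated cohort shows a
slight *increase* in contour entropy between games (random mutation
noise outweighs the copy-left smoothing at an average bias of 0.5),
whereas human participants regularize mildly; the generator's purpose is
the correlational sign structure and parameter-recovery properties, not
group-level point values. Passing tests therefore certify the measures
and the calibration of the inference machinery, not any claim about real
participants.

## Statistics

Pearson correlations are two-sided throughout, with pairwise-complete
deletion and the effective n reported per cell. Bonferroni correction is
applied per behavioral variable across its seven predictors (six FC
pairs + digit span): `0.05 / 7 = 0.007` at report precision. The
one-sample Wilcoxon signed-rank test drops zero differences, averages
tied ranks and uses the normal approximation (the cohort n of 51 is well
past the exact-table range). A permutation calibration utility shuffles
participant labels and verifies that the corrected threshold's false
positive rate matches its nominal level up to binomial error.

## Problem sizes and tolerances

Property tests use cohorts of 20–51 participants; parameter-recovery
sweeps use 200 simulated participants per level, which puts Monte-Carlo
error around 0.005 on a mean transmission value — small against the
sweep effects (~0.1 per step). Null calibration uses 1000 permutations
of a 51-row cohort (70 cells each); its acceptance interval
[0.002, 0.0151] is the ~3σ binomial envelope around 0.05/7 treating the
70 cells of one permutation as fully dependent (the conservative
direction). The Monte-Carlo ICR with 100 shuffles has a standard error
of ≈ 2–4% of the exact value for the game sequences, comfortably inside
the 5% documented bound; all stochastic routines take explicit seeds.

## Known limitations

- The asymmetry change-event rule is one defensible operationalization;
  logs with systematic signal reuse across emotions could be scored
  differently under other rules.
- The agent model's logistic learning has no forgetting, no confusion
  structure between compound and simple emotions, and no trial-order
  effects.
- `metrics` recovers the seed code from the Game-1 confederate's modal
  code, which assumes (as the design guarantees) a constant confederate.
- The Dryad-deposited behavioral archive can in principle be mapped to
  the game-log CSV, but no tolerant adapter is bundled; ingestion of the
  deposited layout is best-effort by hand.
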