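# Methods

## Rating model

Each (user, exercise) pair holds a Glicko2 state: rating *r* (base 1500),
deviation *RD* (uncertainty, points) and volatility *σ* (expected rating
fluctuation, dimensionless). The update is the standard Glicko2 step on
the internal scale (μ = (r − 1500)/173.7178, φ = RD/173.7178): match
variance *v*, improvement Δ, a new volatility solved from its defining
equation by bracketing regula falsi (Illinois variant, bracket tolerance
1e-9 so the equation residual at the root is below 1e-6, iteration cap
100), then the deviation/rating update. With no matches only the
deviation grows, `RD' = sqrt(RD² + (173.7178·σ)²)`. Ratings are floored
at 0 to keep long declining simulations finite-sane.

Parameters that matter:

| parameter | default | why |
|---|---|---|
| system constant τ | 0.5 | mid-range of the commonly recommended 0.3–1.2; bounds volatility change per update |
| initial rating | 1500 | scale convention |
| initial RD | 50 | *small*: a fresh exercise must not leap-frog established high ratings, and single results move a fresh rating by ~20 points rather than hundreds |
| initial σ | 0.06 | conventional starting volatility; idle deviation growth of ~10.4 points/period |
| same-band | ±2 percentage points, inclusive | completeness values within 2 points are treated as equivalent performances (a tie) |
| neutral reference | 50 % | see below |

### Match construction

When exercise *e* is performed with completeness *p*, every other allowed
exercise becomes an opponent at its *current* rating state, scored by its
own most recent completeness (win/tie/loss bands above). Only *e* is
re-rated; opponents receive one inactivity step. This keeps idle ratings
at their last earned value (with growing uncertainty), which is what the
documented four-exercise trace requires: peers of a performed exercise
stay at their printed values.

A **never-performed opponent's reference completeness is 50%** — an
unobserved ability is presumed average. This choice is load-bearing. With
reference 0, a never-performed opponent can never beat a performance
(0 > p + 2 is impossible for p ≥ 0), so one disastrous day yields at
worst two losses and a tie, which numerically cannot drag the performed
exercise below an untouched 1500 peer — yet that ordering ("falls even
lower than the never-performed exercise") is exactly the documented
behaviour of the reference trace. With a neutral 50, a first strong
performance (60%) still beats every fresh peer, while a genuinely poor
one (≲ 48%) loses to them, and all printed ordering relations of the
trace hold for any "poor" completeness in [0, 30]; the orderings were
verified by direct computation over this parameterisation.

### Suggestion policy

Highest rating wins among the allowed exercises minus the two most
recently suggested (window-2 no-repeat, which forces variety); exact
rating ties break uniformly at random from the run's seeded generator.
The scheduler is a plain cadence: next due = last trigger + interval
(4/8/12/24 h), or the registration time before any trigger.

Known limitation: with unilateral updates, exercises performed above the
neutral reference rise immediately above the fresh 1500 baseline, so
early iterations rotate through a growing top group plus random
tie-breaks rather than visiting all exercises round-robin. Longitudinal
studies still show the qualitative signature — diversity is highest in
the early iterations and late suggestions concentrate on the
highest-ability exercises — but not a strict first-k permutation.

### Profiler

Per exercise, over its completeness history: *declining* if the three
most recent values are strictly decreasing and the latest is below half
the historical maximum; *chronically_low* if at least two records exist
and all are below 25%. Declining is checked first; both rules need the
recent-window behaviour, not a model fit, because caregivers act on
simple, explainable triggers.

## Completeness score

Completeness = 100 · |LCS(observed, canonical)| / |canonical|, rounded to
2 decimals, where observed is the run-collapsed, padding-free pose
sequence. LCS (longest common subsequence) is the only order-respecting
subsequence measure consistent with the scoring convention that a
down–extended–down attempt at the five-pose arm raises
(down–extended–raised–extended–down) is 60% complete: 3 of 5 poses in
order. Poses are counted, not frames, for the same reason. The score is
monotone under extension of the observation and invariant to per-pose
dwell time (repeat counts) by construction.

## Recognizer

Input: integer pose-class sequences truncated/padded to length 47 (the
longest observed exercise recording; raw augmented sequences of the
five-pose exercises can reach 50 and are tail-truncated, keeping the
head, since padding them to 50 would contradict the fixed 47). The
network is an 8-dimensional learned embedding (padding row pinned at
zero, hidden state frozen across padded steps so padding carries no
information), a 32-unit GRU, and a dense softmax over the 15 exercise
classes; categorical cross-entropy, Adam at default hyperparameters
(lr 1e-3, β₁ 0.9, β₂ 0.999), batch 128. It is implemented directly in
NumPy with manual backpropagation through time; the backward pass is
verified against numerical differentiation in the test suite, and all
randomness (initialisation, shuffling) is threaded from one seeded
generator, making training runs bit-reproducible.

### Augmentation and catalogue design

Dwell-time augmentation draws, per sample and per canonical pose, a
uniform repeat count in {1..10}; collapsing any un-truncated sample
recovers the canonical sequence exactly (property-tested at 10,000
samples). Canonical sequences are 3–5 poses. The nine seated pose classes
of the original capture protocol map directly onto the twist, hip-march
and arm-raises definitions; the remaining vocabularies are this package's
design. Left/right sibling exercises (upper body twist, hip marching,
neck stretch) share their endpoint pose and differ only in the middle
pose — the minimal-evidence configuration — so residual classifier errors
concentrate in those pairs; every other exercise gets a distinct stance
or seat pose (a leg lift holds a chair, curls hold weights, and so on),
which keeps non-sibling classes separable on more than one position.

Because the augmented sequences carry no label noise (there is no
upstream per-frame pose estimator in this package), the GRU saturates
near-perfect accuracy at moderate sample sizes; confusion mass in the
left/right pairs is therefore small in absolute terms, and the
"errors concentrate in sibling pairs" property is checked as a fraction
of whatever errors remain.

### Problem sizes

Unit tests train 3-class models on 150 sequences/class for 25 epochs
(seconds). The scaled evaluation run uses the full 15-class catalogue at
500 train / 250 test per class for 10 epochs; the acceptance script uses
1000 / 500 per class. Accuracy plateaus well before these sizes on
noise-free augmented data, so larger (full-scale) runs change the
reported accuracies only in the second decimal.

## Persona simulation

A persona holds, per exercise, a completeness mean and standard deviation
plus an optional per-iteration drift; a draw is
Normal(mean + drift · iteration, sd) clipped to [0, 100] (clipping rather
than rejection sampling: simple, and the induced boundary mass is
irrelevant at the spreads used). The shipped default persona covers the
21-exercise senior programme with means mostly 40–70% and spreads 10–30%,
one strongly declining exercise (step up, drift −0.7 %/iteration from a
high start) and one chronically low exercise (sideways bend, mean 14%),
so a 100-iteration study reproduces both profiler trigger patterns. What
the simulator does **not** model: fatigue within a day, learning effects,
correlated abilities across similar exercises, or measurement error of a
real recognizer — so passing longitudinal tests demonstrate the
recommender's dynamics under clean feedback, not robustness to noisy
real-world completeness estimates.

## File formats

Catalogue and pose alphabet: YAML lists validated on load (distinct
errors for schema violations, duplicate names, unknown pose ids, invalid
canonical sequences). Histories: CSV `iteration,exercise,pct_completed`,
dot-decimal, two-decimal percentages, losslessly round-tripping.
User profiles: JSON with the rating triple per exercise. Models: NumPy
`.npz` plus a JSON sidecar with class names, input length and training
metadata. CLI runs log their seed and config/catalogue hashes; validation
failures exit with status 2.
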