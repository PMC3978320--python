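# Methods

This note records the model as implemented: its assumptions, the
parameters that matter, the choices made where the architecture's
published description leaves the mathematics open, and what the
simulations do and do not establish.

## Architecture and assumptions

The simulator embodies a strictly componential account of decimal
magnitude: a decimal fraction exists in the model only as its unit,
tenth and hundredth digits plus the length of its digit string. There
is no holistic magnitude for the fraction, no representation of the
decimal point, and no dedicated decimal-fraction code. Two consequences
are intended: string-length congruity effects arise because a
number-of-digits comparator feeds the same decision layer as the digit
comparators, and zero facilitation arises because the digit-frequency
bias during training strengthens the weights serving comparisons
against 0.

**Place coding.** Digit *j* (0–9) activates a 10-node bank as
`exp(-10 |i - (j+1)|)` for node *i* = 1..10, so the code is nearly
one-hot. String length ℓ (1–4) activates a 4-node bank as
`exp(-|i - ℓ|)`: length is treated as a non-symbolic quantity with
broad tuning, making neighbouring lengths substantially confusable.
The published index arithmetic (`peak at j+1`) is written for values
that start at 0; the length bank's values start at 1, so its peak sits
at node ℓ — the identical formula after shifting the value range onto
the bank. Tuning is fixed: no learned or noisy input codes.

**Comparators.** Each comparison network maps the concatenation of two
banks (left value ⊕ right value) through a full weight matrix onto two
comparison nodes ("left larger" L, "right larger" R) with fixed mutual
inhibition −2 and logistic outputs. Training uses the online delta rule
(`W ← W + η (target − σ(Wx)) xᵀ`, target (1,0) when the left value is
larger), weights initialised uniformly in [−1, 1], learning rate
η = 0.01 (unpublished; chosen small enough for stable convergence well
inside the schedule and exposed in `TrainingConfig`). Equal-value pairs
have no defined target and are excluded from sampling. Digit training
runs 120,000 trials with relative value frequencies 1.15 : 1.05 : 1 …
(digits 0, 1, rest); one digit network is trained and its weights are
shared by the unit, tenth and hundredth comparators. Length training
runs 100,000 trials uniformly over the 12 ordered unequal length pairs,
i.e. roughly 8,300 presentations per comparison versus roughly 1,300
per digit comparison. After training, both networks decide *all* their
ordered unequal pairs correctly (enforced; `fit` fails otherwise), and
decision margins grow with numerical distance — the substrate of the
distance effect — and are larger for pairs containing 0.

**Control network.** Per time step, with persistence τ = 0.8 and input
gain β_in = 0.2:

```
comparison:  a ← τ a + (1−τ) σ( β_in[(C + T_k)·ff + w_inh_comp·a_opp] + b_c + ε )
response:    r ← τ r + (1−τ) σ( g·(β_in[Σ_k v_k a_k + w_inh_resp·r_opp] + ε) + b_r )
conflict:    E ← λ_con E + (1−λ_con)·β_con·|w_inh_resp|·r_L·r_R
```

where `ff` is the comparator's raw feedforward net input for the
current pair, `T_k` the attribute's task coupling (0 / 1.5 / 0.01 / 1.0
for units / tenths / hundredths / length), `C = 0.7`,
`v_k` the comparison→response weights (0.1 / 1.0 / 0.1 / 0.7),
`w_inh_comp = −2`, `w_inh_resp = −0.5`, and ε i.i.d. Gaussian noise
with SD 0.11 per node per step. A trial starts with the comparison
layers at their no-input resting fixed point (≈ 0.29 under the default
biases; the layers idle between trials) and the response nodes at 0
(the previous overt response has been released), and ends when a
response node reaches θ = 0.8 — the response layer is the default
threshold site because its nodes code the overt decision; the
alternative literal reading (threshold on the comparison layer) is
selectable via `threshold_layer` but caps on same-tenth fillers, whose
comparison nodes never reach θ. Steps to threshold is the simulated RT;
trials that reach the 200-step cap, and trials whose wrong response
node crosses first, count as errors. Simultaneous crossings resolve to
the higher activation, exact ties uniformly at random.

A decimal without a hundredth digit contributes a zero input vector to
the hundredth comparator's bank; the 2-vs-3-digit information is
carried by the length network, which is the point of including it.

**Task-coupling adaptation.** After every trial each coupling updates
as

```
T_k ← λ_w T_k + (1−λ_w)·( baseline_k + β_w α_w E · post_k )
```

with λ_w = 0.7, α_w = 1, β_w = 0.5, `post_k` the mean end-of-trial
activation of network *k*'s comparison nodes, clipped to
[0, 5]. At zero conflict the couplings decay geometrically to their
baselines, so the published attentional weights are the operative
steady-state values; high-conflict (incongruent) trials transiently
strengthen the couplings that were active. The adaptation state
persists within a simulated participant and resets between
participants. β_w scales the conflict increment; the alternative
placement (β_w multiplying the baseline) would make the steady-state
couplings half the published attentional weights, which contradicts
their stated role.

## Under-specified transfer constants and their calibration

The published description fixes the dynamics constants listed above but
not the transfer functions of the two central layers (those live in an
external model the architecture descends from). Three constants
complete the specification here, and they are deliberate model choices,
not published values:

- `response_gain` g = 20 and `response_bias` b_r = 0.5. With the
  published response weights, a plain `σ(β_in[...])` response update is
  bounded below ≈ 0.6 and the θ = 0.8 threshold would never be reached;
  a gain and bias on the response sigmoid are the minimal completion
  that makes the printed threshold operative.
- `comparison_bias` b_c = −0.8. Sigmoid units without a negative bias
  rest at 0.5, so attribute channels whose inputs tie (units always;
  tenths on filler pairs) would inject a large common drive into both
  response nodes. Processing units in this model family conventionally
  carry negative biases so uninformative channels rest near silence.

The three constants were calibrated once, jointly, against the
simulated behavioural pattern this architecture is reported to produce
(mean RT near ten steps with the zero-facilitation ordering, a
string-length congruity effect of one to two steps, incongruent error
rates near 7%, overall loss near 3%), using 22-participant runs at
three pipeline seeds, and then frozen. Noise placement is part of the
same completion: ε perturbs each node's summed input *before* the
response gain, so the calibrated gain amplifies signal and noise alike.
Placing the noise after the gain leaves trial-level RT variance near
0.1 steps, which makes every microscopic systematic difference
statistically significant and critical-pair error rates exactly zero —
an empirically wrong regime.

## The stimulus generator

The generator emulates the constrained design of the comparison task:
440 items = 4 critical types × 80 pairs (40 per compatibility/congruity
cell) + 120 fillers. Structural constraints: values in [1.04, 9.96];
unit digits identical within a pair; one member of every critical pair
is an all-nonzero `a.bc` reference; all non-unit digits differ; fillers
share the tenth digit as well. Every critical pair is built with an
overall value distance in [0.32, 0.48] — centring items on distance
≈ 0.40 is what forces tenth distances into the 3–5 range and yields the
characteristic cell means (≈ 3.7 when the hundredth comparison points
the same way, ≈ 4.4 when it opposes, because the hundredth digits then
partially cancel the value difference). Cell means of overall distance,
tenth distance, hundredth distance and problem size (operationalised as
the *sum* of the two values, which reproduces the reported magnitude of
≈ 10.5–11.4) are matched to fixed targets by greedy resampling within a
10,000-iteration budget per cell; unmatched cells are reported, never
silently accepted. The larger member's screen position is
counterbalanced within every cell.

Fillers come in the two admissible forms — a three- and a two-digit
decimal sharing the tenth (`2.83 vs 2.8`) and two three-digit decimals
differing only in the hundredth (`7.91 vs 7.98`). The same-length form
is kept a small minority (12 of 120): with the hundredth digit
attentionally suppressed by design, such items are nearly undecidable
for the model, and more than a handful would push the overall error
loss far beyond the low single-digit percentage the design produces.

What the generator does *not* emulate: screen layout and font metrics,
the pseudo-randomisation rule for response buttons (simulated trial
order is a uniform shuffle per participant), and the accidental
per-participant item subsampling of the original empirical sessions —
every simulated participant sees the full 440-item set once.

## Simulated experiment and statistics

22 simulated participants, each an independent trial order and noise
stream derived from one master seed (`SeedSequence` spawning, so any
participant can be re-simulated in isolation). Error trials (wrong or
capped) are excluded before RT analysis; no further trimming is applied
to simulated step counts. Statistics mirror the behavioural
conventions: participant × cell means, 3 × 2 repeated-measures ANOVA
(decimal type × compatibility) for RT and for arcsine-square-root
transformed error rates (`arcsin √p`, the standard variance-stabilising
choice), Mauchly-gated Greenhouse–Geisser correction, partial eta
squared as SS_effect/(SS_effect+SS_error), Bonferroni-corrected
pairwise type comparisons (family size 3), and paired *t* tests for the
two-level congruity contrast reported as F(1, n−1) = t². The ANOVA
machinery is backed by pingouin and verified in the test suite against
a hand-rolled sums-of-squares decomposition; degenerate inputs (zero
variance anywhere) are reported as flagged null effects rather than
NaNs.

## Numerical choices

- Logistic sigmoid throughout (the published description names but does
  not parameterise it); `scipy.special.expit` for stability.
- Comparator fixed-point iteration (for standalone use of the mutual
  inhibition) runs to 1e−10 or 200 iterations; training uses the
  single-pass convention with the opposing node at 0, since the delta
  rule as cited is a single-layer supervised rule.
- Training samples pairs from the joint distribution proportional to
  w(a)·w(b) restricted to a ≠ b — exactly the distribution induced by
  redrawing equal pairs.
- All randomness flows through `numpy.random.Generator`; identical
  seeds give bit-identical weights, stimuli and trial tables.
- Trained weights serialise to CSV with a JSON metadata header
  (tuning, schedule, achieved accuracy).

## Known limitations

- **Congruent-side error rates are essentially zero.** With the
  published attentional weights the congruent correct-side drive is
  several times the incongruent net drive; at the noise level that
  produces ≈ 7% incongruent errors, congruent errors are at most a few
  trials per run (the reported architecture shows ≈ 1%). The congruity
  error-rate *effect* (incongruent ≫ congruent, significant after the
  arcsine transform) is robust; its congruent-side magnitude is not
  reproduced.
- **The compatibility null is marginal on RT.** The design's tenth
  distances differ between compatibility cells (≈ 3.7 vs ≈ 4.4), and
  the model's distance-sensitive drive makes incompatible pairs
  slightly (~0.2 steps) faster; at 22-participant power this reversed
  difference often reaches p < 0.05. Flattening the distance gradient
  would also erase the zero-facilitation effect, since both arise from
  the same sensitivity of the drive to trained weight margins. The
  interaction null and the error-rate nulls are robust, and raising the
  hundredth weights by an order of magnitude produces the predicted
  reliable compatibility effect.
- **Sequence (Gratton-type) effects are below the noise floor.** The
  conflict-gated coupling boost is present and deterministic tests show
  incongruent trials strengthen couplings more than congruent ones, but
  at the published adaptation constants the resulting next-trial RT
  advantage is ~0.02 steps against a trial SD near 2.
- **Comparator speeds tie at step resolution on the stimulus set.** The
  length network is faster than the digit network at matched numerical
  distance (distance-1 digit evidence does not even reach threshold
  alone), but on the generated items — tenth distances 3–5 versus
  length distance 1 — the two solo latencies both quantise to 8 steps.
- Simulated RT is a step count; no mapping to milliseconds is claimed.
  Proportion-congruity manipulations are predictions of the
  architecture, not simulated here.
- Passing tests show the architecture reproduces the *simulated*
  behavioural pattern under the stated design; they say nothing new
  about human data, which the synthetic design only emulates at the
  level of item structure and matching.
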