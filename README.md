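# decicomp

A connectionist simulator of **decimal-fraction magnitude comparison**,
for researchers in numerical cognition who want to test whether decimal
fractions need their own mental representations — or whether the digit
strings alone, processed like natural numbers, explain the behavioural
record (the *natural number conversion hypothesis*).

When people decide which of `2.7` and `2.91` is larger, two signatures
show up in their reaction times:

- a **string-length congruity effect** — pairs in which the number with
  more digits is also the larger one (`2.7 < 2.91`, congruent) are
  answered faster and more accurately than pairs where it is the smaller
  one (`7.14 < 7.6`, incongruent);
- **zero facilitation** — pairs containing a decimal with a zero tenth
  digit (`2.04`) are answered fastest;
- and, notably, **no** tenth–hundredth compatibility effect (the analogue
  of the unit–decade compatibility effect of two-digit numbers).

`decicomp` reproduces these effects with a fully componential
architecture that contains *no* decimal-fraction representation at all.

## The model

Four two-choice comparison networks feed a cognitive-control network:

- **Place coding.** A digit *j* activates node *i* of a 10-node bank as
  *f(i, j) = exp(−10·|i − (j+1)|)*; the number of digits ℓ ∈ {1..4}
  activates a 4-node bank with the broader non-symbolic tuning
  *exp(−|i − ℓ|)* (node ℓ peaks).
- **Comparators.** Units, tenths and hundredths share one digit network
  (2×10 inputs → comparison nodes L/R, lateral inhibition −2, logistic
  output) trained with the delta rule for 120,000 trials under a
  frequency bias (digit 0 sampled 15% and digit 1 sampled 5% more often
  than the rest), after which all 90 ordered digit pairs are decided
  correctly. The number-of-digits network gets 100,000 trials over only
  12 ordered pairs — each *length* comparison is trained far more often
  than each *digit* comparison.
- **Control layer.** Comparison nodes are leaky sigmoid units
  (persistence τ = 0.8, input gain β_in = 0.2) whose drive is scaled by
  `C + task_activation` of their attribute — attentional weights set to
  0 / 1.5 / 0.01 / 1.0 for units / tenths / hundredths / length. Two
  response nodes pool same-side comparison activations through weights
  0.1 / 1.0 / 0.1 / 0.7 and inhibit each other (−0.5). Gaussian noise
  (SD 0.11) perturbs every node's net input at every step. The trial
  ends when a response node reaches θ = 0.8; the step count is the
  simulated RT (cap 200; capped trials are errors). A conflict monitor
  (energy of response co-activation, smoothed at λ_con = 0.8) drives a
  Hebbian adaptation of the task couplings after every trial.

The stimulus module generates the constrained 440-item design: 80 pairs
each of types `a.0c`, `a.b0`, `a.bc`, `a.b` (split 40/40 by
compatibility or length congruity) plus 120 same-tenth fillers, with
overall distance, tenth distance, hundredth distance and problem size
matched per cell. The experiment module simulates 22 participants ×
440 trials; the analysis module runs the repeated-measures ANOVAs
(Greenhouse–Geisser corrected when Mauchly's test rejects), paired
*t* tests, and the arcsine-square-root transform for error rates.

## Worked example

```python
from decicomp import (DecimalComparisonModel, DecimalFraction,
                      StimulusPair, generate_stimulus_set)

model = DecimalComparisonModel()          # the published parameterisation
fit = model.fit(seed=0)                   # delta-rule training of both nets

pair = StimulusPair(a=DecimalFraction.parse("2.04"),
                    b=DecimalFraction.parse("2.91"), ptype="a.0c")
result = fit.run_trial(pair, seed=1)
print(result.response, result.steps)      # -> b 8   (second member larger)

pairs, _ = generate_stimulus_set(seed=0)  # the 440-item constrained set
run = fit.simulate(pairs, n_participants=22, seed=0)
print(run.summarize().report())
```

prints (abridged):

```
error loss: 3.74% of trials excluded

Mean simulated RT (steps) by decimal type:
  a.0c: 10.35
  a.b0: 10.75
  a.bc: 10.78
...
Pairwise type comparisons (Bonferroni):
  a.0c (10.35) vs a.b0 (10.75): p_bonf = 7.477e-07
  a.0c (10.35) vs a.bc (10.78): p_bonf = 1.551e-06
  a.b0 (10.75) vs a.bc (10.78): p_bonf = 1

String-length congruity (a.b pairs):
  RT: congruent 9.51 vs incongruent 11.85 steps
    string-length congruity (RT): F(1, 21) = 895.54, p = 1.049e-18, eta_p^2 = 0.977
  ER: congruent 0.11% vs incongruent 7.39%
    string-length congruity (arcsine ER): F(1, 21) = 171.48, p = 1.432e-11, eta_p^2 = 0.891
```

Reading the numbers: decimals with a zero tenth digit (`a.0c`) are
compared reliably faster than the other three-digit types, which do not
differ from each other (p = 1 after Bonferroni); length-incongruent
`a.b` pairs cost about two processing steps and produce most of the
errors; and the tenth–hundredth compatibility effect on error rates is
absent. All of this emerges from digit comparators, a string-length
comparator, and attentional weighting — with no holistic decimal
magnitude anywhere in the network.

A command-line interface wraps the same pipeline:

```bash
decicomp reproduce --seed 0 --out runs/default     # full artifact + report
decicomp generate-stimuli --seed 0 --out stimuli.csv
decicomp simulate --config my.yaml --out runs/x    # YAML overrides defaults
```

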