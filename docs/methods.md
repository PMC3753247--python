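# Methods

## The signal model

Each game presents the words rock, paper, scissors in random order at 4-s
onset spacing (defaults: onsets 1, 5, 9 s in a 14-s trace sampled at
120 Hz; the trace therefore covers the ~4-s response window after the last
word). The simulated pupil diameter is

```
d(t) = baseline + A·g(t − t_sel) + Σ_j A·r_j·g(t − t_j − δ_j) + ε(t)
```

where `g(t) = (t/tp)^s · exp(s(1 − t/tp))` is a gamma-like impulse
response with unit peak at latency `tp` (default 1.5 s, shape `s = 2`:
fast rise, slower decay — the averaged decision-locked dilation peaks
shortly after the selected word). `t_sel` is the onset of the selected
word; the per-game decision amplitude `A` is drawn N(3.35, 0.95) mm,
floored at zero. Each non-selected onset `t_j` carries a distractor
transient with probability 0.8, with amplitude a uniform multiple
`r_j ~ U(0.4, 1.15)` of `A` and latency jitter `δ_j ~ U(−0.4, 0.4)` s.
`ε` is white Gaussian measurement noise (SD 0.05 mm). Samples below a
0.5-mm positivity floor are clipped, with a logged warning; with the
default baseline this is essentially never triggered.

Distractor multiples above 1 are what make a game decode *invalid*
(global maximum outside the selected interval); with the defaults roughly
30% of games are naturally invalid, so rejection sampling in either
direction converges in a handful of attempts.

### Calibration

`baseline_mm = 3.13` and the amplitude distribution were chosen once so
that a default-config 75-game set reproduces the reference trace
statistics: grand-mean diameter 4.6 mm, mean within-game min–max range
3.8 mm, SD of the range across games 1.0 mm (each within ±10% at n = 75;
the SD of a sample SD is checked at a wider band in the unit tests since
its own sampling error at n = 75 exceeds 10%).

### What the generator does and does not emulate

It emulates: the event-locked dilation transient, substantial
within-game diameter variation, decoder validity at any requested exact
rate, and the opponents' interval-selection counts. It does **not**
emulate luminance or accommodation responses, pupillary hippus or slow
drift, emotional-arousal modulation, or blink artifacts (an optional
dropout-plus-linear-interpolation artifact model exists but is off by
default, since the pupil signal alone is the object of study). Passing
tests therefore demonstrate the correctness of the decoding and
statistical machinery under a controlled signal model, not the empirical
validity of the marker in recorded humans.

## Decoding

The decoded interval is the index of the latest word onset at or before
the time of the global diameter maximum, searched from the *first* word
onset to the end of the trace — a peak before any word cannot follow a
word. Interval windows are half-open `[onset_i, onset_{i+1})`, the last
extending to the trace end. Ties at the maximum break to the earliest
sample (arbitrary but deterministic). No smoothing is applied before the
argmax by default; a moving-average smoother of configurable width is
available. Because the argmax is invariant under positive affine
transforms, decoding is identical on raw millimeters and z-scored traces;
per-opponent z-normalization (pool = all samples of all games of one
opponent) is provided for visualization and cross-opponent averaging.

## Validity control

`generate_game_set` enforces an exact number of valid games by
regenerating each game's trace until the decoder's verdict matches the
requirement (cap: 1000 attempts per game; exceeding the cap raises,
signalling that the configuration makes the requested validity
practically unreachable). The packaged reference fixture is the
deterministic 75-game set with interval counts (28, 25, 22) and exactly
45 valid games, split (16, 15, 14) across intervals — an arbitrary split
chosen so each interval has at least the 10 valid games the
100%-validity subset construction needs. "Chronological order" for
synthetic data means ascending game id.

## Strategies and conditions

Players are abstracted by a follow probability `f`: with probability `f`
they play the counter-move to the decoded choice, otherwise uniformly at
random. A wrong decode can draw or lose against the player's counter but
never win, giving the closed-form win rate `f·v + (1−f)/3` at decoder
validity `v` (enumerated exhaustively in the tests). Defaults per
condition: naïve-eye and no-video use `f = 0` (naïve players perform at
chance; idiosyncratic naïve heuristics are not modeled); informed-eye and
reconstructed-pupil use `f = 1` (the 60%-validity performance ceiling —
real groups sit below it, and `f` is exposed as a configuration knob);
the reconstructed-pupil condition is computationally identical to
informed-eye, the stimulus difference being perceptual, and is kept as a
named condition for report parity. The 100%-validity condition plays the
curated 30-game subset in four independently randomized blocks with a
block-ramped schedule `f = (0, 1/3, 2/3, 1)` as a descriptive stand-in
for within-session learning, which is not modeled mechanistically.
Rewards are win = +1, draw/loss = 0, configurable. Game order is
randomized per player, so choice history is uninformative by design.

## Statistics

Individual performance is tested with the exact one-sided binomial upper
tail at chance 1/3 (one-sided because learning can only improve
performance), computed via the regularized incomplete beta function and
verified in the tests against exact rational term-by-term summation for
all n ≤ 30. With 10 players per condition, significance means
p < 0.05/10 = 0.005 (Bonferroni). Learning curves evaluate the running
tail over all preceding games; the per-`n` significance boundary is the
least `k` with tail < α. Group comparisons use two-sided t-tests
(one-sample against 1/3, paired, or pooled-variance Student's t for
unpaired; Welch is switchable). Degenerate zero-variance inputs — easy to
produce in simulation, e.g. every always-follow player winning exactly
45/75 — report t = 0, p = 1 when means are equal and p = 0 with a
runtime warning otherwise. P-values are carried as raw doubles with a
3-decimal presentation helper.

## Problem sizes and numerical choices

Default analyses use the 75-game fixture with 10 players per condition;
the chance control simulates 10,000 games; the type-I calibration check
runs 1,000 null sessions of 75 games. Monte-Carlo assertions use 3
standard errors. Trace serialization is repr-exact (full double
precision) so the decode argmax is stable across file round-trips;
manifests carry sha256 checksums and the generation seed. All randomness
flows through `numpy.random.Generator` seeds recorded in provenance;
identical seeds give bit-identical game sets and byte-identical reports.

## Known limitations

- The decoder is the same operation used to enforce validity during
  generation, so fixture validity is exact by construction; the
  chance-floor property (validity → 1/3 on label-independent traces) is
  what tests the decoder against an independent criterion.
- Group t-statistics for real player groups depend on per-player win
  counts that no synthetic default reproduces; the replication report
  computes them for the simulated groups only.
- The kernel's peak latency (1.5 s) and shape are judgment calls; only an
  averaged dilation curve constrains them, and decoding depends only on
  the peak falling inside the selected 4-s interval.
- Whether the opponents' button press contributes a separate motor
  dilation component is not separable here; the model uses a single
  decision-locked kernel.
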