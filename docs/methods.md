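# Methods

## Model

`hmm4d` treats each spatial site `(z, y, x)` of an aligned 4D label volume as
an independent hidden Markov chain over time. The hidden state `X_t` is the
true segmentation class of the site at time `t` (one of `N` classes); the
observation `E_t` is what the per-timepoint 3D segmenter reported. The joint
probability of a hidden path given the observations is

```
P(X_0) · O[X_0, E_0] · ∏_{t≥1} T[X_{t-1}, X_t] · O[X_t, E_t]
```

with `T` the `N×N` row-stochastic transition matrix, `O` the `N×M`
row-stochastic emission matrix and `P(X_0)` the starting distribution.
`viterbi_decode` returns the single most probable path; posterior-marginal
(forward–backward) decoding is deliberately out of scope.

Assumptions the model makes about the data:

- the 4D series is **spatially aligned**, so a fixed `(z, y, x)` index tracks
  the same physical location through time;
- segmentation errors are **independent across sites and time steps** given
  the true class (the emission model is a per-toxel categorical draw);
- the physical dynamics are **Markovian per site** — the plausibility of a
  class change depends only on the current class.

No parameter is learned from the 4D data. The transition matrix encodes prior
physical knowledge, the emission matrix is the segmenter's test confusion
matrix row-normalised, and the start vector is uniform (class imbalance is a
property of every time step, not of `t = 0` specifically).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `dissolve_prob` | 0.10 | per-step probability of the dissolving → product conversion in the default transition matrix (expected corrosion rate, dimensionless probability per time step) |
| `eps` | 1e-3 | cross-term for all other ordered class pairs; keeps rare transitions (misalignment, thermal drift) possible instead of forbidden |
| `n_bins` | 1 or 3 | confidence bins splitting the leading-class probability range `(1/N, 1]`; 1 = plain model, 3 = low/mid/high confidence |
| `boost` | 1.001 | multiplicative factor used by the same-title emission adjustment: a column's owner class is boosted just past the column maximum |
| median `window` | 5 | time steps in the baseline 1D median filter |

Baseline transition matrices: `hmm-t-naive` makes every transition (including
self) equally probable at `1/N` — under it every label sequence is already
"coherent", so refinement provably returns its input unchanged whenever the
emission's column argmax is the identity. `hmm-t-naive-stable` assigns
exactly 0.5 to staying and spreads 0.5 uniformly over the other classes.

## Numerical choices

- **Log space.** All decoding runs in log probabilities with `-inf` for hard
  zeros, so forbidden transitions are never traversed and sequences hundreds
  of steps long cannot underflow. If every complete path has zero probability
  the decoder raises an error naming the first fully blocked time step.
- **Tie-breaking.** Both the per-step maximization and the final-state
  selection resolve ties toward the lowest class index, making the decode
  deterministic across platforms. Note that two distinct paths can tie in
  total log score yet compare unequal at an intermediate dynamic-programming
  stage (the final addition's rounding can collapse a strict inequality into
  an exact tie), so the guaranteed contract is "an optimal path,
  deterministically chosen", not a specific member of the tied set.
- **Confidence binning.** Bins are lower-closed/upper-open with the top bin
  closed at 1; the degenerate case `p ≤ 1/N` (an exact tie between classes)
  clamps to bin 0. Composite observables are ordered class-major
  (`class · b + bin`), and serialized column labels record that ordering.
- **Emission adjustment.** The same-title adjustment iterates
  boost-then-row-renormalise to a fixed point, because a single
  renormalisation can hand column dominance back to a foreign class. At the
  fixed point the operation is exactly idempotent.
- **Constant-observation shortcut.** Sites whose observable never changes are
  assigned the emission-column argmax class without running Viterbi. This is
  an approximation: `audit_shortcut` compares it against full decoding for
  every observable (lengths 1–6) and warns on disagreement. It is enabled by
  default and bit-identical behaviour can be forced off with
  `use_shortcut=False`.
- **Chunking.** Sites are independent, so spatial chunking is bit-exact by
  construction; the test suite asserts it.

## The synthetic phantom

`generate_phantom` emulates the statistical structure of a time-resolved
corrosion acquisition: air around a base-material cylinder containing
spherical inclusions of a dissolving class that convert irreversibly to a
product class at 10% per step (the default hidden transition matrix is the
physical one — no `eps` cross-terms — so the truth contains no reverse
transitions). Observations corrupt the truth with a diagonal-dominant
categorical noise model (95% correct, errors uniform); interior confidences
are drawn from a Beta(18, 2) rescaled into `(1/N, 1]`, while toxels within
one voxel of a class boundary get near-tied confidences just above `1/N` and
a 50–50 label flicker between the two adjacent classes. Default shape is 21
time steps of 64³ voxels — a realistic series length at a problem size that
generates and refines in seconds on one CPU.

What the phantom does **not** emulate: tomographic reconstruction artefacts
(streaks, rings), spatially correlated errors (the CNN's mistakes cluster in
real data), class-dependent error rates beyond what the single emission
matrix expresses, and temporal misalignment. Passing tests on the phantom
therefore demonstrate that the refinement machinery is correct and that it
improves label quality under per-site categorical noise — not that the
specific IoU numbers transfer to any particular real acquisition.

## Design choices where the design was open

- The exact numeric transition/emission tables used in the original
  experiments are not redistributable here; the package ships *builders*
  parameterised by the stated constraints (10% conversion, small cross-terms,
  diagonal dominance) and loads user CSV matrices verbatim for exact
  reproduction.
- The same-title emission fix is automated (minimal multiplicative boost)
  rather than hand-edited, for reproducibility; hand-tuned matrices remain
  loadable from CSV.
- The median baseline takes the median of *integer class codes*, which is
  order-dependent for more than two classes; this reproduces the conventional
  baseline literally and is flagged as a caveat rather than "fixed".
- Classes absent from both prediction and truth score IoU 1.0 and are flagged
  in the report, so the convention is visible instead of silently skewing
  means.
- Axis order is `(t, z, y, x)`, 0-based, everywhere in the core; the CLI's
  evaluation report echoes height selections in both 0- and 1-based forms for
  cross-checking against slice numbering conventions.

## Known limitations

- Strictly per-site temporal modelling: no spatial regularisation, no 3D
  smoothing, no per-region transition matrices.
- One transition matrix for the whole volume; systems with spatially varying
  dynamics are modelled only on average.
- The wipe-recovery behaviour (a wiped time step is bridged by its
  neighbours) recovers the *refined* labels, not arbitrary lost detail; the
  test threshold of 95% recovered toxels on the default phantom is a package
  test parameter, not a universal guarantee.
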