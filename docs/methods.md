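# Methods

## Measurement model

`grimkit` treats a mouse profile frame as a set of up to 13 named 2-D
landmarks in pixel coordinates (y increasing downward, as in video
frames). Every facial parameter is a pure ratio of inter-landmark
distances or an angle in degrees, which makes the whole measurement
layer invariant under similarity transforms — camera translation,
rotation, zoom, and mirroring between left and right profiles. This is
the central design constraint: raw pixel quantities never appear in any
output, so measurements from different recordings, lenses and animal
sizes are directly comparable without calibration.

The parameter formulas are listed in the README. Two of them required a
genuinely open choice:

- **Eye corner for face inclination.** The profile angle is anchored at
  the posterior eye corner (`eye_back`), the corner adjacent to the ear
  orifice in a profile view. Anchoring at `eye_front` would change
  absolute values but not the direction of change.
- **Face axis for ear angle and ear position.** The axis `eye_back →
  ear_orifice` connects two skull-fixed points, so head tilt cancels out
  of both parameters, and `d(eye_back, ear_orifice)` is a rigid
  denominator that removes zoom from the ear-position ratio.

Degenerate geometry (two required landmarks closer than
`epsilon_coincident` = 1e-9 of the eye–ear-orifice distance) raises an
error rather than returning 0: a silent zero would flow into unit
averages and bias them. A partial-computation mode flags each parameter
`ok` / `missing` / `degenerate` per frame instead of aborting, which is
what the `measure` pipeline stage uses.

Angles are computed as `atan2(|cross|, dot)` of the two ray vectors,
which is numerically stable near 0° and 180° (the arccos form is not)
and guarantees outputs in [0, 180].

## Aggregation

Frames flagged for confounding behavior (licking, scratching) are always
excluded. For tastant conditions only frames within a 5-s window after a
recorded tasting event are analysable; the window is closed at both ends
(`[t, t+5]`) — the boundary convention is fixed for determinism.

Units are unweighted arithmetic means per (animal, condition); a
per-individual baseline unit normalizes each stimulus unit into the
proportional change `(stimulus − baseline)/baseline`. A baseline value of
exactly 0 (possible for ratio parameters, e.g. a fully closed eye) makes
that parameter's change undefined (NaN), never infinite.

The formalin time course is binned with half-open `[start, end)`
intervals — one averaged 30-min baseline reference plus six 5-min
post-injection bins — so the bins exactly partition the frames (a frame
at minute 5.0 belongs to bin 2). Early/late phase summaries (0–5 min and
20–30 min) reflect the biphasic nocifensive response to formalin.

## Statistics

- **Response profiles**: two-sided one-sample t against 0 per parameter,
  Bonferroni-adjusted by the experiment's comparison count `m`
  (`p_adj = min(1, m·p)`), which the caller supplies from the design.
- **One-way ANOVA** between groups with Tukey HSD on all pairs
  (studentized-range distribution via `scipy.stats.tukey_hsd`). Subject
  repetition is deliberately not modelled, since pooled designs do not
  expose every animal to every stimulus.
- **Two-way ANOVA**: fully between-subject designs use a Type II
  sum-of-squares decomposition (robust to the mild imbalance of pooled
  cohorts; the choice is recorded here because unbalanced designs make
  SS types diverge). Mixed designs (one between, one within factor) are
  fitted by the standard mixed-model ANOVA decomposition with a
  Greenhouse–Geisser correction whenever the repeated factor has more
  than two levels (with two levels sphericity holds trivially and
  ε = 1). Post hoc policy: Tukey on the main factor; Šidák-adjusted
  simple-effect comparisons when the interaction is significant.
- **Repeated-measures ANOVA + Dunnett**: the within-subject F carries the
  Greenhouse–Geisser ε (reported, and folded into fractional degrees of
  freedom). Many-to-one comparisons against the baseline bin use the
  repeated-measures error mean square with Dunnett's equicorrelated
  (ρ = 1/2) multivariate-t reference distribution, integrated
  numerically (`scipy.stats.multivariate_t.cdf`, quasi-Monte-Carlo with
  a fixed seed and 20 000 points per dimension, giving ≈1e-5 accuracy on
  adjusted p values). Subjects missing any bin are dropped with a
  warning; fewer than three complete subjects is an error.
- **ICC**: inter-observer reliability is ICC(2,1) — two-way random
  effects, absolute agreement, single measure — computed from the
  two-way ANOVA decomposition. This form is chosen because all observers
  rate the same frames and absolute agreement (not just consistency) is
  what matters for pooling measurements across observers.
- **Welch t** with Satterthwaite degrees of freedom for two-sample
  controls (sex differences etc.); fractional df are expected output.
- **Pearson controls** report ρ, df = n−2 and t = ρ·√(df/(1−ρ²)).

All tests are two-sided at α = 0.05 unless configured otherwise.

## Landscape analysis

- **PCA** standardizes the seven parameters first (correlation matrix):
  the parameters mix degrees (up to ~180) with ratios (~1), and
  covariance PCA would reduce to "angles have big numbers". Variable
  contributions are `100·loading²/eigenvalue`, i.e. 100 times the
  squared eigenvector entry; each component's contributions sum to 100
  and the eigenvalues sum to 7.
- **Horn's parallel analysis** compares observed correlation eigenvalues
  with eigenvalues of Monte-Carlo standard-normal datasets of the same
  shape (default 1000 iterations, seedable). The adjustment subtracts
  `reference_k − 1` where the reference is the **99th centile** of the
  random eigenvalue distribution, following Glorfeld's refinement of
  Horn's procedure. The mean reference is available (`centile=None`) but
  is not the default: the observed top eigenvalue of pure-noise data
  exceeds the null mean in roughly half of datasets, and even the 95th
  centile leaves a built-in 5% spurious-retention rate. Retention counts
  the leading run of adjusted eigenvalues > 1 and stops at the first
  failure, so an isolated chance exceedance at a low rank cannot inflate
  the count.
- **UMAP** embeds unit records on raw absolute values (no
  standardization) with Euclidean metric, 15 neighbors and minimum
  distance 0.1, seeded for exact reproducibility. Running on raw values
  means degree-valued parameters dominate the distances; this caveat is
  echoed in the result metadata rather than silently corrected.

## The synthetic-face simulator

The simulator emulates the experimental designs this measurement scheme
is used in: several animals per session, a baseline phase followed by
ordered stimulus conditions, 4–6 analysable frames per condition per
animal (mean ≈ 5, matching typical manual frame yields), or a per-minute
schedule (30 + 30 min → 60 frames/animal) for formalin-type time
courses.

Generative model, per frame: condition effect × animal random effect ×
frame noise for ratio parameters (multiplicative), condition shift +
scaled random effects for angles (additive, SDs expressed as fractions
of the template value). Defaults: 5% between-animal SD, 3% frame noise,
10% behavioral-exclusion rate. Two mechanisms are provided because
inverting all seven parameters at once in landmark space is
over-constrained:

- **parameter space** (default): values are drawn directly around the
  template's parameter vector — used for statistical power and
  calibration studies;
- **landmark space**: the template is deformed per parameter by exact
  geometric constructions (lid-separation scaling for eye opening, ear
  rotation about its base midpoint for ear angle, rigid ear translation
  along the face axis for ear position, …), then camera similarity
  jitter (rotation ±10°, scale 0.8–1.25, translation ±50 px) is applied
  per frame. Jitter never changes any parameter; this is tested to
  1e-9. Deformations are applied in a fixed order chosen so earlier ones
  are preserved where the constructions allow (the rigid ear translation
  preserves ear opening and ear angle); snout position and face
  inclination share the `lower_snout` landmark, so when both carry
  effects only the later one is exact.

What the simulator does **not** model: photo-realistic appearance, 3-D
head pose beyond similarity jitter, correlated measurement error between
parameters sharing landmarks, observer drift, or heavy-tailed manual
measurement blunders. Passing tests therefore demonstrate correctness of
the geometry, aggregation arithmetic and statistical calibration under a
Gaussian noise model — not robustness to real-world annotation
pathologies. The true magnitude of manual-measurement noise is unknown;
the 3%/5% defaults are stated choices, echoed into every manifest.

Ground truth: ratio effects are factors (truth = factor − 1), angle
effects are degree shifts (truth = shift / template value), so expected
proportional changes from baseline follow directly from the effect
specification. Identical (design, effects, seed) reproduce the frame
table bitwise.

## Problem sizes and tolerances used by the test suite

Geometry oracle and invariance suites run 1000 and 200 random landmark
sets respectively at 1e-9 absolute tolerance. Statistical calibration
runs 500 null replicates (familywise rejection ≤ 5% + 2·SE) and 100
power replicates (30 animals, 3% noise, −15%/+20% injected effects;
≥95% detection with correct signs). Parallel-analysis recovery uses 100
seeds each for the null and planted-two-factor regimes (n = 200,
100 Monte-Carlo iterations per run). These sizes were chosen to give
stable pass/fail behavior at desk scale; larger replicate counts change
the estimates only within their stated sampling error.

## Known limitations

- Absolute parameter values depend on the landmark placement
  conventions; different reference-point choices (e.g. the anterior eye
  corner for face inclination) produce shifted but monotonically related
  scales. Cross-study comparisons should use proportional changes.
- Lateral views cannot capture facial asymmetry; no attempt is made to
  model it.
- The Dunnett adjustment assumes the equicorrelated many-to-one
  structure implied by equal bin sample sizes; unbalanced bins would
  need the general correlation matrix.
- `two_way_anova` with a repeated factor expects every subject at every
  level of that factor (mixed-design completeness); incomplete subjects
  should be filtered beforehand.
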