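# Methods

## Membrane geometry and acquisition plans

The membrane is modelled as a disc of diameter 10 mm with the origin at
its centre; all coordinates are continuous millimetres. A full transect
of 40 contiguous square fields across one diameter fixes the field
width at 0.25 mm (the physical field size of a 1000× SEM image is not
published; the 40-image full transect pins it). Both quantities are
configurable through `MembraneSpec`.

**Transect plans.** The full transect tiles one diameter; half and
quarter transects are its central 20 and 10 fields, centred on the disc
centre (their placement along the diameter is otherwise unspecified, and
the centre is the symmetric choice). The double transect is two
orthogonal full transects. The fields nearest the origin overlap
geometrically, but both acquisitions are kept — the plan counts 80
images, matching the published protocol — and the overlapping fields
contribute both their counts and their areas to extrapolation, so the
estimator stays consistent.

**Scatter plans.** The published layouts (8/16/32/69 images) are shown
but not parameterised; a deterministic sunflower (Vogel spiral) lattice
is used: field *k* of *n* sits at radius `r_max·sqrt((k+0.5)/n)` and
angle `k·golden angle`, with `r_max` one field width inside the rim.
This gives reproducible, near-equidistant coverage; the minimum pairwise
centre distance of the 69-field layout is several field widths, so
scatter fields never overlap. Why the full scatter level is 69 images
rather than a rounder number is not explained in the source protocol;
the count is honoured as a constant. Arbitrary budgets (e.g. the
10-image layout used in the matched-budget comparison) go through
`sunflower_plan`.

**Clipped areas.** Fields at the rim extend past the membrane edge.
Their square∩disc intersection area is computed by adaptive quadrature
of the chord-height function with breakpoints at the arc/edge crossings
(relative error far below 1e-6; fully-interior and disjoint fields take
exact fast paths). Tests check a rim field against a seeded
rejection-sampling Monte-Carlo oracle to 0.1%.

## Deposition models

* `homogeneous` — complete spatial randomness: a Poisson number of
  points (mean `intensity·π r²`) placed uniformly on the disc. This is
  the null model under which the extrapolation estimator is exactly
  unbiased.
* `clustered` — a Neyman–Scott process: Poisson parents uniform on the
  disc (rate `cluster_rate` per mm²), each with a Poisson number of
  offspring (mean `cluster_size_mean`) displaced by an isotropic
  Gaussian of standard deviation `cluster_sd_mm`; offspring falling
  outside the disc are discarded rather than reflected (simplest rule,
  and the realised total stays exact). The source observations state
  only that deposition happens "in clusters or layers" without a model
  or strength estimate, so the defaults (0.5 clusters/mm², 40 diatoms
  per cluster, sd 0.3 mm — about 1500 diatoms in about 39 tight
  clusters) are an illustrative, deliberately heterogeneous regime of
  the same order as a diatom-rich water filtrate; they are not
  calibrated to real membranes. For the clustered process the realised
  intensity is `cluster_rate·cluster_size_mean`; the `intensity`
  argument applies to the homogeneous process only.

Every simulation routine takes an explicit seed and builds its own
`numpy.random.Generator`; no global state is used, and identical
(parameters, seed) give byte-identical serialised output.

## Abundance extrapolation and accuracy

Counting uses half-open field membership (`[lo, hi)` per axis) so points
on an edge shared by contiguous transect fields are counted once. The
whole-membrane estimate is area-proportional:

    estimated_total = (Σ counts / Σ clipped areas) · membrane area.

Under CSR this is unbiased (verified against a geometry-free
Poisson/Binomial resampling oracle and by a 1000-replicate bias check);
over the exhaustive grid plan, whose clipped areas sum to the disc area,
it is exact. The extrapolation formula itself is this package's design —
the source protocol compiles per-image counts to a per-filter total
without printing its formula — and area-proportional scaling with
clipped rim areas is the choice that avoids biasing rim-heavy plans.
At 0.25 mm tiling, full coverage of the 10 mm disc takes ≈1324 fields;
the protocol's ">1700 images" presumably includes overlap, and coverage
counts here are derived from geometry.

Accuracy against a reference total R is `100·(1 − |E − R|/R)`, floored
at zero. The formula is not printed in the source either; this is the
only form consistent with "≥95% accuracy" phrasing and the logarithmic
curves, and the floor keeps the regression stage well-behaved when a
sparse plan misses badly. For simulated membranes the reference is the
true simulated total; for real data it would be the combined
double-transect-plus-full-scatter extrapolation.

The strategy experiment pairs all plans over the same simulated
membranes, so strategy contrasts and monotonicity checks use paired
Monte-Carlo errors. Replicates whose simulated membrane holds zero
diatoms are skipped (accuracy is undefined without a reference); at the
default intensities this never occurs.

## The logarithmic accuracy model

Mean accuracy versus image count is fitted as `a·ln(n) + b` by
unweighted ordinary least squares (no weighting scheme across dilutions
is published). Accuracies above 100 are not clamped before fitting —
clamping is presentation-only. The minimum image budget for a target
accuracy t is the smallest integer n with predicted accuracy ≥ t,
computed as `ceil(exp((t − b)/a))` with a floating-point guard; on the
published coefficients this gives 78 transect and 50 scatter images at
t = 95. Targets at or below the intercept return 1; a non-positive
slope with a target above the intercept raises, as the target is
unreachable.

The empirical accuracy ladders (79.8→95.6% for transects, 86.1→97% for
scatter) were measured on physical membranes whose raw per-image counts
are unpublished; they are carried in `diatomtest.datasets` as inputs and
worked-example material, not as quantities this package can recompute.
Refitting the curve on the four published transect aggregates does not
reproduce the published coefficients exactly, because those were fitted
on underlying per-dilution data; the tests therefore compare the fit
against an independent closed-form OLS oracle instead.

## L/D diagnostics

Concentrations are plain ratios: diatoms per gram = count/mass, diatoms
per millilitre = count/volume. The L/D ratio is lung-per-gram over
medium-per-ml; classification uses the *unrounded* ratio (one-decimal
rounding is reporting-only, preventing boundary artifacts like 1.04
presenting as "1.0"), with L/D > 2 → `strong_drowning`,
1 < L/D ≤ 2 → `drowning_supportive`, L/D ≤ 1 → `immersion_compatible`.
Exactly 1 falls on the immersion side, following the stricter "≤ 1"
statement of the diagnostic rule. A zero or negative medium
concentration is rejected: without a measurable reference medium the
ratio is meaningless. A `debris` flag attaches a caveat that a
debris-laden medium may overstate the diatom content of the actually
aspirated water.

Replicability across aliquots of one tissue reports the per-gram
values, their range relative to their mean (`100·(max−min)/mean` — the
published "maximal deviation of 2.5%" has no stated formula and is not
reproducible from the printed weight/count triples, whose per-gram
values span ~98–114 for control case A), Spearman's rank correlation
between mass and count, and, when per-image count groups are supplied,
a Kruskal–Wallis test across them. The published Spearman r values
(0.406/0.681/0.573 at p = 0.000) cannot arise from three (mass, count)
pairs and presumably used unpublished per-image counts; they are
documented here and not asserted anywhere.

Digestion recommendations follow the validated discrete rules — ≤0.5 g
→ 5 ml, ≤1.0 g → 10 ml, >1.0 g → 15 ml, always 4:1 HNO₃:H₂O₂ — with the
boundaries closed on the right because only the three discrete masses
were tested. Requesting an oversized batch for a light sample attaches
a frustule-disintegration warning; undersized batches warn about
incomplete digestion. Masses outside (0, 2] g are rejected with advice
to adjust the sampled tissue mass.

Synthetic cases draw Poisson counts around known concentrations.
Classification recovery is tested at the four published drowning
concentration pairs (true L/D 2.34–10.88) under protocol-scale samples
(0.5 + 1.0 g tissue, 10 ml medium): ≥95% of 1000 replicates classify
`strong_drowning`. A case with true L/D exactly 2 sits on the class
boundary and would necessarily split ~50/50; recovery guarantees apply
to ratios strictly above 2 with adequate counts.

## Problem sizes and determinism

Monte-Carlo checks use 300–1000 replicates: large enough that the
3-standard-error bands are a fraction of the effects under test, small
enough that the whole suite runs in seconds. All stochastic stages
derive their seeds from one explicit seed (spawned via
`numpy.random.SeedSequence` in the experiment harness); pipeline outputs
contain no timestamps, so reruns with the same config are
byte-identical.

## Limitations

* The clustered-process defaults are illustrative; on-membrane
  clustering strength of real digests is unknown, so simulation results
  quantify the *ordering* of strategies, not real-world error levels.
  Passing tests show the estimator and harness behave correctly under
  the stated processes — not that a particular accuracy will be achieved
  on physical membranes.
* The synthetic case model treats aliquot counts as Poisson around a
  homogeneous concentration; real digests add membrane-level counting
  error and possible clogging, which the generator does not emulate.
* Species identification, contamination chemistry and drowning
  probability beyond the published class thresholds are out of scope.
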