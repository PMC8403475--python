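# Methods

## The estimation problem

A feeding trial feeds known biomass compositions and asks how faithfully
relative read abundance (RRA) from metabarcoding reproduces them. Both
quantities are compositions: each sample's expected diet
*x<sub>i</sub>* ∈ Δ<sup>D−1</sup> and its RRA *y<sub>i</sub>* ∈ Δ<sup>D−1</sup>
are non-negative vectors summing to one. `dietquant` models their
relationship linearly on the simplex,

    E[y_i] = x_i B,

with **B** a D<sub>x</sub> × D<sub>y</sub> row-stochastic matrix. Because
rows of **B** are themselves compositions, predictions never leave the
simplex and no log-ratio transform is needed; B<sub>jk</sub> is the
fraction of predictor component *j* recovered as outcome component *k*.
Perfectly quantitative metabarcoding corresponds to **B** = I; a taxon
that under-amplifies shows a collapsed diagonal entry with its mass
redistributed along the row.

### Fitting

**B** minimises the Kullback–Leibler divergence
D(B) = Σ<sub>i</sub> Σ<sub>k</sub> y<sub>ik</sub> log(y<sub>ik</sub>/μ<sub>ik</sub>),
μ<sub>i</sub> = x<sub>i</sub>B, with 0·log 0 = 0. The optimiser is an
EM-style multiplicative update: treat each observation weight
y<sub>ik</sub> as arising from a mixture over predictor components with
proportions x<sub>ij</sub>B<sub>jk</sub>/μ<sub>ik</sub>; the M-step is

    B_jk ← B_jk · Σ_i x_ij y_ik / μ_ik,   then renormalise each row.

The update preserves non-negativity and row-stochasticity exactly and
never increases D (standard EM argument; the objective trace is asserted
non-increasing in the property tests). Iteration stops when D improves by
less than `tol` (default 1e-8) or at `max_iter` (default 10 000).
Initialisation is the uniform matrix 1/D<sub>y</sub> — deterministic and
strictly interior, so no coefficient starts pinned at zero (multiplicative
updates cannot leave a zero). Model means are floored at 1e-12 before
division so an observed-positive cell with a vanishing mean cannot produce
infinities. Exact-fit problems (noiseless Y = XB₀) converge linearly with
a slow tail, so tests of exact recovery use `tol` 1e-12–1e-14; noisy fits
converge in a few hundred iterations at the default.

Identifiability: n ≥ D<sub>x</sub> samples are recommended (a warning is
emitted below that); a predictor component that is zero in every sample
leaves its row of **B** untouched by the updates, and that row is reported
as unidentified rather than invented. Permutation, bootstrap and
leave-one-out refits share problem shapes and run through a batched
implementation of the same update (identical arithmetic, stacked on a
leading axis) for speed.

### Inference

* **Permutation test** for overall linear dependence. The statistic is
  the divergence reduction T = D₀ − D(B̂), where D₀ is the divergence of
  the best sample-independent model (every sample predicted by the
  column-mean composition of Y — the KL-optimal constant). Permutations
  shuffle the rows of X against fixed Y and refit. The p-value
  (1 + #{T<sub>perm</sub> ≥ T<sub>obs</sub>})/(1 + n<sub>perm</sub>)
  counts ties as exceedances, making the test conservative and its null
  p-values super-uniform (checked by a one-sided Kolmogorov–Smirnov test).
  Default n_perm = 1000.
* **Bootstrap intervals**: percentile bootstrap over resampled samples
  (whole rows), default n_boot = 1000, level 95%. Resamples in which an
  identified predictor component vanishes entirely are redrawn and
  counted. Percentile intervals on strongly skewed small-sample
  distributions need not contain the point estimate; bounds are
  guaranteed ordered and inside [0, 1].
* **Leave-one-out cross-validation**: each sample predicted from a fit
  without it; reported as a predicted-vs-observed table (for 1:1 plots),
  per-sample Euclidean errors and the RMSE over all sample × taxon cells.

## The simulator

`synthetic.build_design` constructs the rotation design: with base
proportions (0.6, 0.3, 0.1) over taxa (Trifolium, Salix, Avenella), the
three cyclic shifts give mixtures T60_S30_A10, T10_S60_A30 and
T30_S10_A60, so every taxon takes every biomass share once. (Published
descriptions of this trial name the first mixture T10_S60_A30 in the
methods and T10_S30_A60 in the results; the generator follows the
methods-style naming, where the digits after each initial are that
taxon's own percentage.) Each mixture is eaten by `animals_per_mixture`
animals (default 9) and every sample is amplified in `pcr_replicates`
PCR replicates (default 3); single-plant reference samples and the meal
mixtures themselves are sequenced alongside the faeces.

For a sample of type *t* with expected composition *p*, the pre-noise
truth is the biased renormalisation

    q_j ∝ p_j · a_j · (d_j if t = faeces else 1),

with per-taxon amplification factors *a* (marker copy number × PCR
efficiency, relative recovery per unit biomass) and digestion factors *d*
(applied to faeces only). Structural zeros propagate: a taxon absent from
the meal yields zero diet reads regardless of factors.

Each replicate then draws

* depth ~ round(LogNormal(`depth_log_mean`, `depth_log_sd`)) — defaults
  log(18 000) and 0.35, chosen so the central mass of per-replicate depths
  spans roughly 10 000–30 000 reads, the range such trials report; only a
  min/mean range is typically published, hence a median + spread
  parameterisation;
* a replicate composition ~ Dirichlet(`overdispersion` × q), default
  precision 200 (replicate-to-replicate RRA s.d. ≈ 0.03 at a 60/30/10
  composition — tight but visibly noisy replicates); zero components stay
  exactly zero (gamma representation);
* integer counts ~ Multinomial(depth − contaminant reads, composition).

Contamination: a fixed catalogue of five named non-diet MOTUs (Festuca,
Maleae, Avena, Vaccinium, Betula — taxa plausibly carried over from
pre-trial food or field sampling); contaminant reads are binomial at
`contaminant_rate` (default 0.005, i.e. 0.5% of reads — real but below
the 1% filter, as observed contaminants typically are) and split across
the catalogue with table-level random weights. Contaminant MOTUs carry
reference identities drawn uniformly in [0.7, 1.0]; diet MOTUs carry 1.0
and status "ok". With probability `outlier_replicate_rate` (default
0.02) a replicate amplifies from a corrupted, vertex-heavy composition
instead of the truth — the aberrant-PCR failure mode the outlier filter
must catch. `spike_outlier` creates the same failure on demand at chosen
severity. All randomness flows from one integer seed through a single
`numpy` generator; identical seeds give byte-identical tables.

Every simulated trial carries a `TruthRecord`: per-sample post-bias
compositions, the spiked-replicate and contaminant lists, and the
*implied generating B* — the transition matrix fitted (noiselessly) to
the distorted mixture compositions against the expected ones, per sample
type. Parameter-recovery tests score fitted matrices against it; the
bias-to-B map is nonlinear (renormalisation), so this fitted summary is
the honest linear shadow of the generating process.

What the simulator does **not** emulate: raw reads, chimeras,
tag-jumping, sequencing-error-derived MOTUs (artefact flags are sampled
metadata, not the output of a de-noising algorithm), PCR stochasticity
beyond the Dirichlet, cross-contamination between samples, or real
digestion chemistry. Passing tests therefore demonstrate that the
*pipeline* recovers what it should under a plausible noise model — not
that any particular wet-lab system is quantitative.

## The filtering cascade

Stage order: drop flagged MOTUs → remove outlier PCR replicates →
average replicates per sample → 1% within-sample relative-frequency
filter → 85% reference-identity filter → taxon merge/drop map → RRA
normalisation. Choices worth stating:

* **Outlier replicates.** Replicates are compared as relative-frequency
  vectors. Per iteration: compute each replicate's Euclidean distance to
  its sample's mean vector and the pairwise distances between all sample
  means; flag replicates whose within-sample distance reaches the
  `alpha` (default 0.05) lower-tail quantile of the between-sample
  distribution **and** exceeds `floor_factor` (default 5) times the
  median within-sample distance; remove the worst flagged replicate per
  sample; repeat until clean or `max_iter`. The floor term exists
  because feeding-trial designs contain many samples with *identical*
  compositions, which drags the low between-sample quantile down to the
  replicate-noise scale; without the floor the quantile rule alone
  flags ordinary replicates en masse (verified in development on the
  default design). Samples left with fewer than two replicates are
  discarded — averaging a single replicate is not meaningful, and
  discarded samples are reported, never silently dropped.
* **1% filter.** Applied to the averaged per-sample frequencies by
  default (a per-replicate variant is available), with a strict `<`
  comparison so exactly-1% survives. Cells are zeroed per sample; a MOTU
  is dropped globally only when zeroed everywhere, since a taxon can be
  real in one sample and noise in another.
* **Identity filter.** Inclusive ≥ 0.85 by default.
* **Taxon map.** Merges are count-additive and applied after all count
  filters; `DROP` removes a taxon before normalisation. This is also the
  mechanism for restricting to a known diet (whitelisting): the study
  driver re-normalises over the design's taxa and reports the dropped
  off-design share instead of hiding it.
* **Audit.** Each stage logs MOTU/sample/replicate/read counts; these
  are non-increasing by construction and tested as such.

## The study driver

`run_study` filters, splits samples by type, and fits two regressions
against the expected biomass compositions: meal-mixture RRA (molecular
bias only) and faecal RRA (bias + digestion). Single-plant references
are purity-checked (own-taxon RRA share) but excluded from both
regressions. A regression with fewer than three retained samples is
reported "not estimable" rather than fitted. Sub-seeds for permutation
and bootstrap derive from the config seed via `SeedSequence`, so a report
is a pure function of (input table, design, config). A pre-filtered RRA
matrix can be supplied directly, bypassing the cascade — the entry point
for externally deposited, already-filtered datasets. Ternary coordinates
(x = (2b + c)/2(a+b+c), y = √3·c/2(a+b+c)) are emitted for three-taxon
studies for plotting; no figures are rendered.

## Verification scales

The test suite and `scripts/acceptance.py` run everything at reduced but
representative sizes, chosen as the package's own verification budget:
dense 2×2 grid oracles at step 0.001 (20 problems), noiseless recovery at
n = 20, noisy diagonal-ordering recovery over 50 simulated trials of 30
faecal samples at depth 2×10⁴, permutation calibration with 200 null
simulations × 200 permutations at n = 12, and outlier detection/false
removal over 100 simulated trials at ~5000 reads per replicate. Spike
detection rates are measured on mixture-fed samples; corrupting a
single-plant vertex sample towards a random vertex coincides with its own
composition about a third of the time and is then not an outlier by any
definition.

## Known limitations

* The bias model is multiplicative and per-taxon; interaction effects
  (e.g. template competition that depends on co-occurring taxa) are not
  modelled.
* The regression admits no covariates (animal, trial day, extraction
  batch); that is inherent to this transformation-free formulation.
* Percentile bootstrap at n = 3 (meal mixtures) is close to vacuous; the
  intervals are reported but should be read as descriptive.
* With D<sub>x</sub> = D<sub>y</sub> = 3 and n = 3 the fit interpolates;
  only the faecal regression (larger n) supports real out-of-sample
  claims, which is why LOOCV is attached to it.
* EM convergence to the exact optimum is slow on noiseless data; for
  high-precision recovery use a tighter `tol` than the default.
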