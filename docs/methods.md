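# Methods

This note documents the models, conventions and design choices behind
`plumspec`: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## 1. Spectral calibration

Raw detector counts are converted to absorbance with the standard
diffuse-reflectance convention, `A(λ) = −log10((S−D)/(W−D))`, where `S`,
`D`, `W` are the sample scan, dark frame (source off) and white reference
on a shared wavelength grid. The conversion demands `W > D` everywhere and
`S > D` (a signal at or below the dark level has no defined reflectance and
raises an error naming the wavelength). Replicate scans per fruit — four
probe positions in the reference protocol — are averaged with an unweighted
arithmetic mean *after* the absorbance transform; the replicate grouping is
always supplied explicitly rather than inferred from sample-id patterns.
The analysis window defaults to the closed interval [510, 1100] nm: silicon
CCD arrays have poor signal-to-noise below ~510 nm. Wavelength grids are
arbitrary strictly-increasing floats; nothing assumes integer-nanometre
spacing, since instruments routinely report sub-nanometre pixel positions.

Spectra travel as wide CSV (`sample_id, cultivar, <λ₁>, <λ₂>, …`, comma
separator, `.` decimal, UTF-8, 12-significant-digit floats, which makes the
write→read round trip exact to well below 1e−10); reference activities as
two-column CSV.

## 2. Synthetic campaigns

The generator produces datasets with the statistical structure the analysis
assumes, plus a ground-truth record (`PhantomTruth`) that makes recovery
claims checkable. A campaign is, per sample:

    x(λ) = b·[ baseline(λ) + Σ bands(λ) + g(PPO)·profile(λ) ] + a + baseline_dev(λ) + ε(λ)

* **Activities.** Per-cultivar truncated normals with the published
  descriptive statistics as defaults (Khoni: mean 0.003165, SD 0.001614,
  range [0.00012, 0.005849]; Khormaei: mean 0.003256, SD 0.002062, range
  [0.000145, 0.006374]; units absorbance·min⁻¹·g⁻¹; 80 samples each).
  Sampling is by rejection — exact and simple; with the default parameters
  roughly 90 % of proposals are accepted, so cost is negligible.
* **Baseline and bands.** A fixed quadratic baseline (0.45 − 0.25u +
  0.10u², u = normalized wavelength) plus Gaussian absorption bands:
  pigments at 560 nm (amplitude 0.50, width 50 nm) and 670 nm (0.45, 30 nm),
  water at 970 nm (0.60, 35 nm — the O–H second-overtone feature), organics
  at 1030 nm (0.25, 25 nm). Band shapes are free parameters of this
  generator, chosen to look like fruit spectra; no claim is made that they
  match any particular instrument trace.
* **Planted signal.** Ten wavelengths between 519 and 667 nm carry an
  activity-dependent absorbance increment `g(PPO)`. Each planted feature is
  a narrow Gaussian of spectral width 2.5 nm (single-pixel spikes are not
  physical; finite width is also what makes smoothing filters genuinely
  helpful). Two response forms:
  - `linear` (default): `g = amp·(PPO − min)/(max − min)`, one global affine
    map, amplitude 0.1 absorbance units.
  - `threshold`: a smooth step `g = offset·amp + amp·σ(s·(PPO − μ)/w)` with
    logistic σ, breakpoint μ = pooled configured mean, transition width
    w = 0.5 pooled SD. The step is *cultivar-oriented*: Khormaei rises
    (browning pigments accumulate on a dark background, s = +1, offset 0)
    while Khoni falls from an elevated plateau (native anthocyanin
    absorbance at these wavelengths is bleached by oxidation, s = −1,
    offset = 1·amp). This orientation matters: if both cultivars shared one
    monotone step, a linear latent-variable model could read the step out
    as well as a tree can invert it — the qualitative "trees beat PLSR"
    phenomenon only exists when the spectra→activity map interacts with
    cultivar, which is also the standard explanation for cultivar-specific
    calibration models. The plateau offset doubles as the cultivar marker:
    in threshold mode the planted columns themselves separate the
    cultivars, while in linear mode no cultivar nuisance touches them.
* **Scatter and noise.** Per-sample multiplicative factor b ~ N(1, 0.002),
  additive offset a ~ N(0, 0.001), and a random per-sample quadratic
  baseline deviation with coefficient SD 0.001; detector noise is i.i.d.
  N(0, 0.01) per wavelength — one tenth of the planted amplitude. The
  scatter defaults are deliberately small: averaging four probe positions
  per fruit removes most position-specific scatter before modeling, and
  multiplicative artifacts enter here only so that SNV/MSC have something
  real to remove.
* **Seeding.** One master seed spawns named substreams (`ppo`, `scatter`,
  `noise`), so switching noise off never shifts the activity or scatter
  draws — important when comparing noisy and noiseless versions of the same
  campaign.

What the generator does **not** emulate: radiative-transfer effects,
wavelength-dependent detector response, temperature drift, correlated
(pink) noise, cultivar-specific biochemistry beyond the band/response
parameters, and any relationship between PPO and the water or sugar bands.
Tests that pass on these campaigns therefore certify the *pipeline* — its
operators, protocol and optimizers — not the field performance of any
spectrometer.

## 3. Preprocessing conventions

All row-wise operators (normalization, SNV, detrending, the three filters)
are independent across samples; MSC and mean centering carry fitted state
(reference spectrum / column means) estimated from training rows only, so
no information leaks into validation or test partitions. Conventions that
differ across the literature are fixed as follows:

* "Normalization" means per-spectrum min–max scaling to [0, 1] (the most
  common reading in applied NIR work); a unit-norm variant is available via
  `PreprocessingSpec(normalization_variant="unit")`.
* SNV uses the sample (n−1) standard deviation.
* The Gaussian filter uses σ = 2 grid points truncated at 4σ; all filters
  use reflect padding, so constants pass through unchanged and output
  length equals input length.
* MSC regresses each spectrum on the mean *training* spectrum by OLS and
  returns `(x − a)/b`; a zero slope (spectrum uncorrelated with the
  reference) is an error rather than a silent division.

## 4. Models

* **ε-SVR** (scikit-learn/libsvm): C = 1 throughout — the study design
  explicitly forgoes a C/γ grid search. ε defaults to IQR(y)/13.49, the
  convention of the original modeling environment. The "auto" kernel scale
  is the median pairwise Euclidean distance among training rows (seeded
  subsample of ≤ 1000 rows); the RBF kernel is `exp(−‖x−y‖²/scale²)`
  (γ = 1/scale²) and the polynomial kernel `(1 + x·y/scale²)³`. Predictors
  are not internally standardized — scaling is the preprocessing module's
  job.
* **CART regression** is grown best-first by SSE reduction with
  `max_leaf_nodes = max_splits + 1`, which makes the split budget an exact
  cap on the number of internal splits rather than a depth proxy. Minimum
  leaf size 1.
* **PLSR** fits centred (unscaled) components; predictions, not loadings,
  are the contract — with full-rank predictors and as many components as
  columns it reproduces OLS. Component selection scans k = 1…10 (capped at
  the training rank bound) and takes the smallest k whose validation RMSE
  is within a 1e−9 relative band of the minimum, so a redundant extra
  component never wins on floating-point dust.
* Degenerate constant targets yield a constant predictor in every family
  rather than an error; all fits are deterministic given (spec, X, y).

## 5. Evaluation protocol

RMSE uses the 1/N divisor; SD is the sample (n−1) standard deviation of the
*observed* values of the partition being scored (the usual RPD convention);
RPD = SD/RMSE, reported as +∞ on a zero-error fit and classified into the
Chang bands (the 2.0–2.5 band is closed at 2.5). R² is reported as the
squared Pearson correlation — the convention under which a badly biased
model can show R² > 0 alongside RPD < 1, a pattern real calibration tables
exhibit. The variance form R²ᵥ = 1 − MSE/Var(observed) is also computed; by
construction RPD = 1/√(1 − R²ᵥ) exactly, and the test suite asserts that
identity. A constant prediction vector has undefined correlation; R² is
then 0 with a `constant_predicted` flag.

Splits are uniform random permutations cut by floor allocation (60/20/20,
remainder to training: 160 → 96/32/32). The protocol repeats the split
`n_reps` times (study default 200; the packaged tests and the acceptance
script use 10–20 to keep runtimes in seconds) and records a full metrics
report per preprocessing × model cell; cell failures are recorded, never
fatal. The fixed "best split" is the repetition with the highest mean test
RPD among repetitions whose mean validation RPD is at or above the median —
the guard keeps a lucky test set from winning on test RPD alone; infinite
RPDs are capped at the largest finite value observed before averaging.
Ties go to the lower repetition index. This rule is explicit because "best
split by the statistical criteria" is not by itself operational.

Significance: the per-model association test is the two-sided t-test on the
Pearson correlation (df = n−2); the between-model comparison is the
two-sided Wilcoxon signed-rank test on |residual_A| − |residual_B|, exact
for ≤ 25 non-zero differences, p = 1 when every difference is zero.

## 6. Wavelength selection

Candidates are binary masks over the truncated grid with at most `k_max`
(default 15) active wavelengths. Fitness is the validation RMSE of the
configured model (default: linear-kernel SVR — fast and deterministic)
refitted on the masked training columns of one fixed split; an empty mask
scores +∞ instead of raising, and a memoizing evaluator guarantees no mask
is ever refitted. Cardinality repair trims an overfull mask to the `k_max`
wavelengths with the best single-wavelength fitness ranks (computed once
per run) and activates one random wavelength in an empty mask. All
algorithms keep an elitist best-ever archive, so convergence traces are
non-increasing by construction; initial populations are uniform random
subsets of uniform cardinality 1…k_max (dense random masks pushed through
repair would all collapse onto the same rank-favoured columns).

Per-algorithm designs (population sizes and rates follow the study's
hyperparameter table; the shared iteration budget defaults to 30):

* **PSO** — binary PSO, 40 particles, sigmoid transfer on velocities
  clipped to ±6, inertia 0.9→0.4 linearly, cognitive = social = 2.0, lbest
  ring neighbourhood of size 8.
* **GA** — 120 individuals, tournament selection (size 2), uniform
  crossover at rate 0.30 per pair, mutation at rate 0.30 per individual
  (then per-bit 1/L), generational with one elite.
* **ACO** — per-wavelength pheromone τ ∈ [0.01, 1] initialized at 0.5; each
  of 40 ants samples `k_max` distinct wavelengths with probability ∝ τ; the
  iteration-best ant deposits, τ ← (1−ρ)τ + ρ·best with ρ = 0.04 (the
  printed "evaporation 4" read as 4 %).
* **ICA** — 40 countries, 11 imperialists, colonies allotted by normalized
  power; assimilation copies each differing bit at 0.9; revolutions (rate
  0.1) flip bits at 2/L; a fully absorbed colony is replaced by a fresh
  random country; empires compete by imperialist cost + 0.1 × mean colony
  cost, the weakest losing its worst colony and collapsing when empty.
* **LA** — one linear reward–inaction automaton per wavelength (inclusion
  probability, init 0.5); per iteration 40 candidate masks are drawn, and
  the generation-best mask's bit choices are rewarded with learning rate
  0.1.
* **HTS** — 15 molecules with continuous scores in [0,1]ᴸ thresholded at
  0.5; per iteration one phase chosen uniformly: conduction (step toward a
  random partner, scaled 1/CDF = 1/2), convection (step toward the best
  molecule, scaled 10/COF = 1) or radiation (uniform kick of half-width
  1/RDF = 1/2); greedy per-molecule acceptance.
* **LCA** — 8 teams; each iteration is one round of random pairings whose
  matches are decided over `match_time = 2` bootstrap replays of the
  validation residuals, both sides scored on the *same* resampled indices
  (a paired comparison — unpaired replays made match outcomes too noisy to
  preserve good line-ups). Losers imitate winners (uniform bit copy at
  0.3 plus 1/L mutation); a loser identical to its winner rebuilds from
  scratch; the current league leader is never overwritten mid-round and
  gets one greedy "practice" swap per round (bench one active wavelength,
  field a random inactive one, keep on strict improvement); the iteration
  budget divides into the configured 10 seasons, each ending in a transfer
  window that replaces the weakest team with a fresh side. The transfer,
  immunity and practice mechanics are standard league-metaphor devices;
  without them an 8-team league collapses onto one line-up long before the
  budget is spent.

The exhaustive enumerator evaluates every subset of cardinality 1…k in
lexicographic order (ties therefore resolve to the lexicographically
smallest subset) and refuses upfront if the subset count exceeds 10⁵. On a
12-wavelength pool with k = 3 (298 subsets) every algorithm above reaches
the exhaustive optimum in at least 80 % of 20 seeded runs under a
50-iteration budget — the packaged equivalence test.

Multi-run statistics (`n_runs`) use seeds derived from the run seed by a
fixed stride; the selector comparison reports subset size, mean fitness,
mean test-set correlation of the refitted model and mean wall time per
algorithm, sorted by mean fitness.

## 7. Pipeline, configuration, provenance

A single YAML/JSON document configures a run (generator or CSV inputs,
truncation window, preprocessing and model grids, protocol size, selector
set); CLI flags override file scalars and the merged effective
configuration is persisted into the output directory. Every report row
carries the seed and a hash of the scientific configuration (the output
path is excluded from the hash, so re-running the same experiment into a
different directory yields byte-identical reports — asserted in the test
suite). Logging goes to stderr and `logs/run.log`; per-evaluation detail
only at DEBUG.

## 8. Problem sizes and numerical choices

The packaged tests and the acceptance script run the protocol at 10–20
repetitions on the default 160 × 591 campaign, selector comparisons at 30
iterations, and the optimizer-equivalence study on a 12-wavelength pool —
sizes chosen so the whole suite completes in about a minute while every
statistical claim still has margin. Noteworthy numerical conventions:
sample (n−1) SD everywhere a dispersion is reported; PLSR tie band 1e−9
relative; infinite RPDs capped at the largest finite observed value inside
the best-split rule (a saturated tree would otherwise dominate the
average); kernel-scale median falls back to the smallest positive pairwise
distance when more than half the training pairs coincide, and errors only
when all rows are identical.

## 9. Known limitations

* The generator's band shapes and scatter magnitudes are stylized; real
  orchard campaigns have drift, outlier fruit and reference-assay error the
  pipeline never sees in testing.
* The threshold response encodes one specific nonlinearity (a
  cultivar-oriented step). Trees dominating PLSR on it demonstrates the
  protocol can detect that structure, not that trees win on every fruit
  dataset.
* Wrapper selection optimizes validation RMSE on a single fixed split; with
  32 validation samples the optimizer can and does exploit validation noise
  (subsets mixing planted and reference wavelengths sometimes score better
  than the pure planted set). Recovery percentages should be read with that
  in mind.
* The per-model significance test and the paired comparison are both
  provided, but which a given published table used is often ambiguous;
  results should state the test by name.
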