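# Methods

This note documents the models and procedures implemented in
`phenoconcord`, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Semantic similarity by optimal transport

Each sub-score *s* is represented as the uniform discrete measure on the
unit-normalized embedding vectors of its items. The ground metric is the
great-circle distance d(u,v) = arccos⟨u,v⟩ (inner products clamped to
[−1,1] as a floating-point guard; arccos near 1 limits absolute precision
to about 1e−8, which is why "zero distance" assertions use that
tolerance). The distance between sub-scores is the first-order Wasserstein
distance W₁ — transport cost linear in the ground metric, the convention of
embedding-based document distances. Item weights are uniform: no
item-importance information exists in an instrument catalog.

The solver is exact. For equal-size clouds the optimum of the uniform
transportation polytope is a permutation matrix (Birkhoff), so the problem
reduces to linear assignment, solved with the Hungarian algorithm; unequal
sizes solve the full transportation linear program with HiGHS. Entropic
regularization is deliberately avoided — an approximate solver would break
the brute-force permutation oracle used in the tests.

Similarity is the min-max inversion `1 − d/d_max`, with `d_max` the largest
off-diagonal distance of the analyzed set. "Normalize and invert"
under-determines the map, and the alignment coefficients below scale with
it; the raw distance matrix is therefore always emitted alongside, so any
other affine renormalization can be applied post hoc.

## Score concordance and alignment

Sub-score concordance is the Pearson correlation matrix over all complete
participants (tables are complete by construction — incomplete rows are
dropped at load time, never imputed — so every pair shares the same n).
The per-sub-score alignment coefficient is the no-intercept least-squares
slope

    βᵢ = ⟨wᵢ, aᵢ⟩ / ⟨wᵢ, wᵢ⟩

over off-diagonal entries of the similarity row wᵢ and correlation row aᵢ.
The regression uses *signed* correlations: with nonnegative similarities, a
negative β is only possible if a carries sign, and negative alignment
coefficients are an empirically meaningful outcome (a sub-score whose
behavioral correlations run against its semantic neighbors). Correlation
*magnitudes* are used for heatmap display only.

## Stratification stability

Participants are clustered per instrument with Lloyd's k-means, one random
initialization from k distinct data points per run (scikit-learn,
`init="random"`, `n_init=1`). Features are z-standardized per sub-score
before clustering; sub-scores have very different raw ranges and unscaled
k-means would be dominated by the widest scale. Standardization happens
once on the full table, so every bootstrap replicate sees the same feature
geometry.

Congruence of two partitions is the percentage of co-assigned participants
after matching cluster labels with the Hungarian algorithm on the k×k
contingency table. Because the matching is optimal, the chance floor for
independent partitions exceeds 1/k (for k = 2 it sits well above 50%);
overlap numbers must be read against that floor, not against 1/k.

Each bootstrap replicate draws one sample of participants with replacement
at full n, shared by both instruments (keeping the two partitions
comparable), re-clusters each instrument on that sample, and records the
matched overlap; duplicated participants count with multiplicity.
Replicate seeds derive from the master seed by a counter scheme
(`seed*1000 + replicate`), so the entire distribution is reproducible.

## Diagnostic agreement

Classification rules are inclusive (score ≥ cutoff diagnoses); a strict
mode (>) is available behind a flag since verbal descriptions of such rules
are ambiguous between the two readings. The conventional pair bracketed by
the default grids is ADOS total ≥ 9 against the ADI-R sub-score conjunction
A ≥ 10, B ≥ 7, C ≥ 3; grids default to ADOS 5–14 and ADI-R total 20–40
step 2. Cohen's κ = (p_o − p_e)/(1 − p_e) from the 2×2 table; the
degenerate case p_e = 1 (both classifications constant and equal) is
reported as κ = 1 with a warning, while constant-but-unequal labels fall
through to the formula (κ = 0).

## Biomarker association

*Median split*: values ≤ median go to the low group. Integer scores tie
heavily at the median, so a deterministic tie rule is required; ties-to-low
is used throughout. *Group test*: Welch's unequal-variance t with
Satterthwaite degrees of freedom, two-sided p, BH-FDR across the instrument
family at q = 0.05. The imaging and connectivity correlations are instead
annotated with raw-p tiers (p<0.05, p<0.10, p<0.15) without FDR — they are
descriptive screens, not confirmatory families. Connectivity is the raw
Pearson correlation between network-mean time series (no Fisher-z); with
the default 8 networks this yields 28 unique pairs, each correlated against
instrument totals (a sub-score mode is available, since both conventions
appear in practice).

## Synthetic-data generator

The generator defines the conditions under which the pipeline is tested.

*Embeddings*: each construct has a center on the sphere; an item picks a
construct by its sub-score's mixture weights and is sampled as
center + isotropic Gaussian noise of scale 1/concentration, re-projected to
the sphere. This gives a single tightness knob without a specialized
directional-distribution sampler; concentrations at or above 1e8 (or ∞)
collapse a cloud to its center exactly.

*Scores*: a Gaussian copula. Latents are multivariate normal with residual
correlation C plus a shared severity factor with loadings λ, giving total
correlation √(1−λᵢ²)√(1−λⱼ²)Cᵢⱼ + λᵢλⱼ; each latent maps to its ordinal
range through equiprobable standard-normal quantile cut-points. Binning is
monotone, so rank structure survives up to a known attenuation — tests that
compare recovered correlations to targets first calibrate that attenuation
with a brute-force binned-bivariate-normal simulation rather than assuming
it away. The default study-shaped cohort uses within-instrument latent
r = 0.7, cross-instrument r = 0.18 and severity loading 0.3, so the
*effective* cross-instrument latent correlation is ≈ 0.25 and the
within-instrument one ≈ 0.73: the strong-within / weak-cross regime the
concordance analysis is designed to probe. Score ranges follow the
instruments' published raw-score scales (e.g. ADI-R A 0–30, SRS
Communication 0–66, SCQ 0–39).

*Raters*: two-rater duplicates re-bin the same latents under independent
Gaussian rater noise; sd 0 reproduces the table exactly.

*Biomarkers*: the PRS-like scalar is slope·severity + N(0,1), the slope
calibrated in closed form so a median split on standard-normal severity
yields the requested Cohen's d (using E[s|s>0] − E[s|s≤0] = 2√(2/π) and
within-half variance 1 − 2/π). Imaging scalars are affine in severity with
noise set by the target correlation, then shifted into realistic units
(volume ≈ 1.2×10⁶ ± 1.1×10⁵ mm³, thickness ≈ 2.55 ± 0.12 mm). Network time
series are i.i.d. multivariate-normal draws with the configured
inter-network correlation.

What the generator does *not* emulate: item-level response processes (no
IRT), floor/ceiling effects and skew of real raw-score distributions,
informant-specific biases beyond symmetric Gaussian rater noise, temporal
autocorrelation or motion artifacts in BOLD series, and site effects.
Passing tests therefore demonstrate that the *procedures* recover known
structure and control error rates under a clean data-generating process —
not that real cohorts satisfy that process.

## Problem sizes and numerical choices

The test suite and acceptance script use cohorts of 80–5000 participants,
100 bootstrap replicates, 50-seed Monte-Carlo batches for error-rate
checks, and T = 150 time points for connectivity: sizes at which each
Monte-Carlo tolerance stated in the tests holds with comfortable margin
while the full suite runs in well under a minute per heavy check.
Cholesky factorizations add a 1e−10 diagonal jitter to tolerate singular
PSD targets; near-correlation projection clips eigenvalues at 1e−8 and
rescales to unit diagonal; assignment-problem ties resolve to the solver's
deterministic lowest-index convention. All randomness flows from
`numpy.random.default_rng` seeded with (master seed, stream id) pairs, and
pipeline stages derive sub-seeds from the master seed by CRC-32 of the
stage name, so enabling or disabling one stage never perturbs another's
stream.

## Known limitations

The min-max similarity normalization makes β values set-dependent: adding
or removing a sub-score rescales every similarity and hence every β (raw
distances are emitted for that reason). Bootstrap overlap standardizes
features on the full sample, which leaks a small amount of information into
replicates but keeps them comparable. Cohen's κ is reported without
confidence intervals. The LP route for unequal-size clouds is exact but
dense — fine for instrument catalogs (tens of items), not intended for
thousands of points per cloud.
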