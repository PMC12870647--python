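# phenoconcord

Concordance analysis of standardized behavioral-assessment instruments.

Clinical phenotyping in autism research leans on a handful of standardized
instruments — the clinician-administered ADOS, the caregiver-interview
ADI-R, the caregiver-questionnaire SRS, and the SCQ screener. These tools
target overlapping constructs, and downstream work (patient stratification,
biomarker discovery, genetic association) typically treats them as
interchangeable severity anchors. `phenoconcord` quantifies whether that
assumption holds: it measures how much the instruments overlap *semantically*
(in the text of their items) and how much they agree *empirically* (in the
scores they assign), then propagates score disagreement into the analyses
that consume the scores.

## What it computes

1. **Semantic similarity** between sub-scores. Each sub-score is a cloud of
   item-embedding vectors on the unit sphere (any sentence encoder; the
   synthetic generator stands in when embeddings are unavailable). The
   distance between two sub-scores is the exact first-order Wasserstein
   (earth mover's) distance between uniform measures on the two clouds under
   the geodesic metric d(u,v) = arccos⟨u,v⟩; distances are min-max inverted
   into similarities in [0,1].
2. **Score concordance**. Pearson correlations r between raw sub-scores
   across participants, and per-sub-score *alignment coefficients*
   βᵢ = ⟨wᵢ,aᵢ⟩/⟨wᵢ,wᵢ⟩ — the no-intercept regression of the behavioral
   correlation row aᵢ on the semantic similarity row wᵢ (diagonal excluded).
   β ≈ 1 means behavior tracks semantics; β ≈ 0 means semantically twin
   sub-scores measure different things in practice.
3. **Stratification stability**. k-means clustering of participants per
   instrument (k = 2…5), with cross-instrument congruence measured as the
   percentage of co-assigned participants after Hungarian label matching,
   over 100 bootstrap resamples.
4. **Diagnostic agreement**. Threshold-based classification (total-score
   cutoffs or the conventional ADI-R sub-score conjunction A≥10, B≥7, C≥3),
   percent agreement over a cutoff grid, and Cohen's κ.
5. **Biomarker association**. Median-split Welch t-tests of a scalar
   biomarker (e.g. a polygenic risk score) with Benjamini–Hochberg FDR;
   tiered Pearson correlations of scores with imaging scalars; and
   8-network functional-connectivity (28 unique pairs) associations with
   instrument totals.

A synthetic-data module generates every input — embedding clouds with
controllable construct overlap, Gaussian-copula ordinal score tables with a
target latent correlation structure and a shared severity factor, two-rater
duplicates, and biomarkers with known effect sizes — so the whole pipeline
is testable against ground truth.

## Worked example

Simulate a study and run the full pipeline:

```bash
phenoconcord simulate --out study --seed 1 --n 500
phenoconcord run --config examples/run_config.yaml --out results/example
```

Or at the library level:

```python
import phenoconcord as pc
from phenoconcord.synthetic_data import (
    default_cohort_config, generate_score_table, example_catalog)

catalog = example_catalog()
cfg = default_cohort_config(catalog, n_participants=500, seed=1)
table = generate_score_table(cfg, catalog)
corr = pc.correlation_matrix(table)
inst = {s: catalog.instrument_of(s) for s in corr.subscores}
print(abs(corr.cross_instrument_values(inst)).mean())
```

On the default synthetic study at seed 1 the pipeline reports (via
`scripts/acceptance.py`, see below):

* mean cross-instrument |r| = 0.222 vs. mean within-instrument |r| = 0.694 —
  sub-scores correlate strongly inside an instrument but only weakly across
  instruments, despite high semantic overlap (mean alignment β = 0.744);
* median k = 2 cluster overlap = 60.2% — data-driven stratifications built
  from different instruments mostly disagree;
* conventional-cutoff diagnostic agreement = 58.6% with Cohen's κ = 0.147 —
  little agreement beyond chance;
* two raters scoring the same cohort (rater noise sd 1.0) produce SRS totals
  sharing R² = 0.50 with a mean deviation of 36.0%.

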