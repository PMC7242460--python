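# Methods

## Scope and data model

`refstab` analyses a wide Ct matrix (genes × samples, technical replicates
as `<sample>_r1..rK` columns) plus a sample-metadata table (group, subgroup,
age, BMI). Replicates are collapsed to a per-well arithmetic mean Ct — the
scale on which instrument noise is approximately additive — with the n−1
replicate SD kept alongside. Wells are flagged, never silently altered:
`noisy-replicates` above a 0.5-cycle replicate-SD threshold (a package
convention; instrument vendors publish no standard), `single-replicate`,
`missing`, and `non-detect` at mean Ct ≥ 40 (kept, not truncated).

Each analysis set (a pool of groups, by default control + type 1 and
control + type 2) is complete-case: genes with any missing well among the
retained samples are dropped with a logged notice. Imputation is
deliberately not offered — both the geometric-mean normalisation factor and
the per-sample centering of the variance model require a full matrix, and
imputing Ct values would manufacture stability.

## Relative quantities

`q_ij = E_i^(minCt_i − Ct_ij)` with per-gene amplification factor `E_i`
(default 2.0, i.e. 100% efficiency; assays are typically certified at
100 ± 10%, so the admissible range is bounded to [1.5, 2.2]). The calibrator
is the per-gene minimum mean Ct, so the most-expressed sample has q = 1 and
q is scale-free. Both downstream methods are invariant to per-gene scaling,
so this choice affects presentation, not results.

## geNorm

Pairwise variation `V_jk` is the n−1 SD over samples of `log2(q_j/q_k)`;
`M_j` is the mean of `V_jk` over the other active genes. Iterative
elimination removes the argmax-M gene and recomputes until two remain. All
SDs use the n−1 denominator throughout, matching the sample-statistic
convention of the original method.

Numerical and reporting choices:

- **Tie-break at elimination** (exactly equal M values, e.g. duplicated
  genes or degenerate panels): the lexicographically last gene symbol is
  removed first. Deterministic, documented, test-pinned, and recorded in
  the run log.
- **Headline M per gene** is its M at the iteration of its elimination (the
  convention behind the familiar monotone stability bar charts); the final
  pair report their two-gene M and share rank 1, listed alphabetically.
  The full per-iteration trace (`m_trace_`) is kept for transparency.
- **V series**: `V(n/n+1)` for n = 2 … K−1, computed as the SD of the
  difference of running means of log2 quantities (identical to the
  geometric-mean definition, cheaper and exact). `optimal_n` is the
  smallest n with V strictly below the threshold (default 0.15). When no V
  drops below the threshold, `optimal_n` is reported as undefined with the
  minimum-V position as advisory — the standard references do not cover
  this case, and silently picking a number would overstate confidence.
- The normalisation factor is the geometric mean of relative quantities
  (not of raw Ct): a geometric mean of Ct values would mix units, and on the
  log scale the quantity-based NF is the arithmetic mean of log2 q, which is
  what the V statistic needs. Field usage that says "geometric mean of the
  Ct values" is shorthand for this.

`GeNorm` is a scikit-learn transformer: `fit` on a samples × genes positive
matrix; `transform` divides each sample by its fitted normalisation factor
(top `n_select` genes, defaulting to the fitted optimal count).

## NormFinder-type variance model

For log2 expression `y_igj` (gene i, group g, sample j), per-sample
centering `z = y − mean_genes(y)` removes global abundance exactly. With
`s²_ig` the within-group n−1 variance of z and I genes:

```
σ²_ig  = max(0, (I/(I−2)) · [ s²_ig − (1/(I(I−1))) Σ_i' s²_i'g ])
d̂_ig   = z̄_ig − mean_g'(z̄_ig')
τ²     = max(0, Σ_ig d̂²/(G(I−1)) − Σ_ig (σ²_ig/n_g)/(G·I))
d̃_ig   = d̂_ig · τ²/(τ² + σ²_ig/n_g)        (0 when τ² = 0)
ρ_ig   = |d̃_ig| + sqrt( (σ²_ig/n_g) · τ²/(τ² + σ²_ig/n_g) )
ρ_i    = mean_g ρ_ig
```

The σ² correction follows from `E[s²_ig] = σ²_ig(1 − 2/I) + (1/I²)Σσ²_i'g`
under gene-centering, and is exactly unbiased; it requires I ≥ 3. Negative
moment estimates are truncated at zero and every truncation is logged.
Pairs are scored by the same ρ applied to the pseudo-gene with
`d = (d_a + d_b)/2` and `σ² = (σ²_a + σ²_b)/4`, searched exhaustively
(≤ 496 pairs at K = 32). With a single group the intergroup machinery is
skipped and stability reduces to the intragroup SD. The reference tool for
this model is closed-source, so exact estimator forms were fixed by the
derivations above and validated by parameter recovery on simulations rather
than by bit-matching published figures.

Group structure for the study design is G = 2 (control vs cancer) within
each analysis set; histological subgroups are metadata only.

## Cohort statistics

Per-label arithmetic mean and n−1 SD for age and BMI, at subgroup and
pooled-group level; values are kept at full precision and rounded only for
display. The bundled `study_cohort()` table carries the 24 published
per-patient ages and BMIs (9 controls, 9 type 1, 6 type 2). One-way ANOVA
uses `scipy.stats.f_oneway`; Dunnett two-sided many-to-one comparisons use
`scipy.stats.dunnett` (multivariate-t with pooled within-group variance,
QMC integration seeded for determinism, accurate to roughly 1e-3 in p).
Zero pooled variance is reported as a flagged degenerate result, not an
error.

## Synthetic data generator

The generator emulates the study design on the Ct scale:

```
Ct(i, g, j, r) = B_i + d_ig + a_gj + b_igj + e_igjr
```

gene baseline `B_i`; group shift `d_ig` (zero-sum across groups for
regulated genes); sample abundance effect `a_gj ~ N(0, 0.5 cycles)` shared
by all genes of a sample (mimicking RNA input/RT-yield differences);
biological noise `b_igj ~ N(0, σ_ig)`; replicate noise
`e_igjr ~ N(0, τ = 0.15 cycles)`. Noise is Normal on the Ct (log-abundance)
scale, matching qPCR error behaviour. Defaults mirror the study shape:
32 genes named as a standard endogenous-control panel, 9 control + 9 type 1
+ 6 type 2 samples in triplicate, stability tiers graded σ = 0.15–0.30
(stable), 0.40–0.90 (moderate), 1.0–2.0 (unstable) cycles, and four
group-regulated genes with zero-sum shifts of 0.6–1.2 cycles chosen among
cancer-associated transcripts. Age/BMI metadata are drawn from per-group
Normal distributions matching the published cohort means ± SD.

Determinism: one integer seed fully determines the output. Four independent
`SeedSequence` substreams drive abundance, biology, replicates and metadata,
and all draws are standard-normal before scaling — so changing one noise SD
leaves every other realised draw untouched. This is what makes the
abundance-invisibility property assertable exactly: results at abundance
SD 0 and 2.0 cycles agree to 1e-9 because both methods cancel `a_gj`
analytically.

`truth_ranking` orders genes by pooled intragroup SD plus mean absolute
centered shift — a design score, independent of seed, with ties broken by
symbol. `GroundTruth` also converts the design to the log2 scale at E = 2
(σ cycles → σ log2 units; replicate averaging adds τ²/R; shifts are centered
the same way the estimator centers) for parameter-recovery checks.

Two fixed validation designs ship with the generator:
`recovery_spec` (12 genes, 2 × 200 samples, single replicates, τ = 0, one
designed reference at σ = 0.15 against a 0.5–1.2 field with three biased
genes) and `split_stability_spec` (two σ = 0.02 genes among 30 noisy ones at
study size). In the recovery design the separation between the reference
and the runner-up is deliberately wide: per-sample gene-centering couples
every gene's noise into every other's (a contamination term of order
Σσ²/I²), which puts a floor under what any estimator can resolve, and the
design keeps the intended ordering above that floor.

### What passing tests do and do not show

The generator reproduces the study's dimensions, noise structure on the Ct
scale, global abundance effects and group-level regulation. It does not
simulate amplification-curve artefacts, efficiency drift between assays,
inter-plate effects, RNA-quality gradients correlated with disease state, or
non-Normal outliers. Recovery of the designed ranking therefore shows the
estimators are correct and well-conditioned at study scale — not that any
particular real panel's published ranking would be reproduced, which would
require the original raw Ct data.

## Problem sizes used in validation

Oracle-equivalence checks run brute-force reimplementations on panels of
up to 6 genes (M, elimination, V series; agreement to 1e-12) and 10 genes
(exhaustive pair search). Parameter recovery uses 100 seeded replicates at
n = 200 per group: the mean intragroup-variance estimate lands within 5% of
truth on average across gene × group cells, the designed reference gene
ranks first in ≥ 95% of replicates, and the two designed ultra-stable genes
take the tied top geNorm rank in ≥ 95% of replicates. Mean intergroup
differences are checked against truth with a simultaneous
(Bonferroni-calibrated) standard-error bound across the 12 panel genes,
since a per-cell 2-SE rule would falsely fail a large fraction of runs by
construction.

## Known limitations

- Complete-case handling can drop many genes if non-detects cluster in one
  sample; the pipeline warns when more than 25% of the panel is lost.
- The V(n/n+1) rule is a heuristic; near-threshold values (±0.01) should
  not be over-interpreted, and the package reports the full series rather
  than only the selected n.
- Dunnett p-values depend on a numerical multivariate-t integration and are
  reproducible only to the quadrature tolerance; they are reported for
  description, not as a precision instrument.
- Efficiencies are inputs; no standard-curve estimation is performed.
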