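# refstab

Reference-gene (housekeeping-gene) stability analysis for qRT-PCR.

Quantitative RT-PCR measures a transcript relative to one or more reference
genes, so the choice of references decides whether a fold-change is biology
or artefact. `refstab` implements the two standard selection methods for a
candidate panel — the **geNorm** pairwise-variation measure with iterative
elimination and the **NormFinder** variance-component model — together with
Ct-table I/O, the ΔCt relative-quantity transform, cohort descriptive
statistics (means ± SD, one-way ANOVA with Dunnett many-to-one comparisons),
and a seeded synthetic Ct-data generator with known ground truth so the whole
pipeline is testable end to end. It is written for studies shaped like a
typical clinical panel: ~32 candidate genes measured in triplicate on a few
samples per patient group (e.g. controls vs two tumour subtypes).

## The two stability measures

Let `q_ij = E^(minCt_i − Ct_ij)` be gene *i*'s relative quantity in sample
*j* (amplification factor `E`, 2.0 at 100% efficiency).

**geNorm.** For genes *j*, *k* the pairwise variation
`V_jk = SD_samples( log2(q_j / q_k) )` and the stability measure
`M_j = mean_{k≠j} V_jk`. The gene with the largest M is eliminated and M
recomputed until two genes remain, giving a ranking (the final two tie at
rank 1; `M ≤ 1.0` is the conventional stability call). The normalisation
factor `NF_n` is the per-sample geometric mean of the top-*n* genes'
quantities, and `V(n/n+1) = SD_samples( log2(NF_n / NF_{n+1}) )` selects the
number of references: the smallest *n* with `V < 0.15` suffices.

**NormFinder.** Log2 expression is centered per sample across genes (which
absorbs global RNA-input differences), then decomposed per gene × group into
an intergroup difference `d` and intragroup variance `σ²`, estimated by
bias-corrected moment estimators. The spread of true differences across
genes, `τ²`, shrinks each difference empirically-Bayes style
(`d̃ = d̂ · τ²/(τ² + σ²/n)`), and the stability value

```
ρ_ig = |d̃_ig| + sqrt( (σ²_ig/n_g) · τ²/(τ² + σ²_ig/n_g) ),   ρ_i = mean_g ρ_ig
```

ranks genes lowest-ρ-first. Candidate pairs are scored on the pseudo-gene
with averaged differences and quartered variance, so two oppositely biased
genes can beat any single gene.

Both are exposed as scikit-learn estimators (`GeNorm`, `NormFinder`) with
thin functional wrappers (`rank_genes`, `fit_variance_model`, …).

## Worked example

Three genes over three samples, mean Ct rows `(20, 21, 22)`, `(25, 26, 27)`,
`(30, 30, 30)` at `E = 2`: genes A and B fall in lock-step (perfectly
co-regulated) while C is flat.

```python
import pandas as pd, refstab as rs

genes, samples = ["A", "B", "C"], ["s1", "s2", "s3"]
ct = pd.DataFrame([[20, 21, 22], [25, 26, 27], [30, 30, 30]],
                  index=genes, columns=samples, dtype=float)
agg = rs.AggregatedCt(genes=genes, samples=samples, mean_ct=ct,
                      rep_sd=ct * 0.0)
qm = rs.relative_quantities(agg, efficiency=2.0)
print(rs.m_values(qm))
res = rs.rank_genes(qm)
print(res.final_ranking, res.v_series)
```

prints

```
A    0.5
B    0.5
C    1.0
dtype: float64
['A', 'B', 'C'] [(2, 0.33333333333333337)]
```

A and B have M = 0.5 (their only disagreement is with C, whose log-ratio
against either has SD exactly 1), C has M = 1.0 and is eliminated first, and
adding C to the two-gene normalisation factor changes it by V(2/3) = 1/3 —
well above the 0.15 cut-off, so C is not worth including.

The same analysis runs from the shell on a simulated study:

```sh
refstab simulate --seed 1 --out sim/
refstab run --ct sim/ct.csv --meta sim/meta.csv --out report/
cat report/summary.txt
```

The report contains, per analysis set (control + type 1, control + type 2),
the geNorm ranking and M values, the V series with the selected number of
reference genes, 3/4/5-gene recommended normaliser sets, and the NormFinder
stability table with best gene and best pair.

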