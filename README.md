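# tcrdyn

Longitudinal single-cell TCR repertoire dynamics and immune signature
scoring for checkpoint-inhibitor-treated cohorts.

`tcrdyn` analyses paired scRNA/scTCR data from peripheral blood drawn
repeatedly during neoadjuvant chemotherapy + immunotherapy (the emulated
design: 7 breast-cancer patients × 4 draws — baseline, post-chemo,
post-ICI, endpoint — split into responders, RCB 0/I, and non-responders,
RCB II/III). It answers four questions a tumor-immunology group asks of
such data:

1. **How clonal is each T-cell compartment?** Cells are keyed by the
   amino-acid CDR3 of their best-supported productive TRB chain; a
   clonotype is *clonal* when more than 3 cells of a patient share it
   (pooled across timepoints), and clusters are summarised as
   `pct_clonal = 100 · n_clonal_cells / n_assigned`.
2. **Which peripheral clones are tumor-associated?** By exact CDR3 overlap
   with the clonotype list assembled from the same patient's tumor biopsy
   (MiXCR-style export), never across patients.
3. **How stable is the clonal repertoire over treatment?** Per patient,
   the clonal clonotypes observed at each timepoint form sets; `tcrdyn`
   emits the exact presence-pattern (Venn) partition, the fraction present
   in ≥ k timepoints (`shared_ge_k`), pairwise Jaccard `|A∩B|/|A∪B|`, and
   forward maintenance `|A∩B|/|A|`, per patient and pooled per response
   group.
4. **Do expression programs shift with therapy?** Counts are pseudobulked
   per sample (exact integer sums), log-CPM normalised and scored with
   ssGSEA — for each unit, genes ranked by expression, running sum gaining
   `rank^α / Σ_in rank^α` at in-set genes and losing `1/(N−m)` at
   out-of-set genes, score = sum of the running sum (α = 0.25) — then
   compared across timepoints with an exact paired Wilcoxon signed-rank
   test, or between groups with t / rank-sum tests. Per-gene rank-sum
   differential expression applies the conventional marker thresholds
   (|log2FC| ≥ 0.5, BH-adjusted p ≤ 1e-5).

The statistical toolbox (exact signed-rank via dynamic programming with
ties, ANOVA + Tukey HSD, Kruskal–Wallis + tie-corrected Dunn, BH) and a
seeded synthetic-cohort generator with recorded ground truth are part of
the package, so every stage is testable without any data download.

## Worked example

```python
from tcrdyn import (SimConfig, simulate_cohort, assign_clonotypes, is_clonal,
                    clonal_sets_by_timepoint, group_sharing)
from tcrdyn.dynamics import patient_sharing

cohort = simulate_cohort(SimConfig(seed=1), include_counts=False)
cd8 = cohort.cells[cohort.cells["cell_type"] == "CD8_T"]
assignment = assign_clonotypes(cd8, cohort.contigs)
sets = clonal_sets_by_timepoint(cd8, assignment, is_clonal(assignment))
_, summaries = patient_sharing(sets)
print(group_sharing(summaries, sets, cohort.cells).round(1))
```

prints (abridged):

```
  response        statistic             metric  value_pct  n_patients
    RCB0_I per_patient_mean        shared_ge_2       14.4           4
    RCB0_I per_patient_mean maintained_forward        8.8           4
RCB_II_III per_patient_mean        shared_ge_2       39.8           3
RCB_II_III per_patient_mean maintained_forward       29.6           3
```

Read: in the responder group only ~14% of clonal CD8 clonotypes recur at a
second timepoint and ~9% of a timepoint's clonal set is still found at a
later draw — a turning-over repertoire — while the non-responder
repertoire is stable (~40% recurring, ~30% maintained), the behaviour the
generator plants through its group persistence rates (0.10 vs 0.35).

The `examples/` directory holds one short script per capability
(simulation, clonality + tumor match, longitudinal sharing, pseudobulk
ssGSEA with paired contrasts, differential expression); each prints its
numbers with a line on what they mean. A thin CLI mirrors the stages:

```bash
tcrdyn simulate --seed 4 --out bundle/
tcrdyn run-all --config config.yaml
```

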