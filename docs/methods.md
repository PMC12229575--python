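# Methods

## Clonotype model

A cell's clonotype key is a CDR3 string. Three key modes exist:

* `TRB_aa` (default) — amino-acid CDR3 of the cell's productive TRB contig
  with the highest UMI count. Beta-chain amino-acid keying is the field
  convention and the only mode that can be matched against bulk-RNA-derived
  tumor clonotype exports, which report amino-acid CDR3s per clone.
* `TRB_nt` — nucleotide CDR3 of the same contig (distinguishes convergent
  recombination).
* `TRA_TRB_aa` — joined `TRA|TRB` amino-acid key, requiring both chains.

UMI ties between two productive chains are broken lexicographically on the
CDR3 string so assignment is deterministic and independent of contig row
order. Cells without the required productive chain(s) receive no key; they
are counted, logged and excluded from clonality denominators (which use
`n_assigned`, not `n_cells`).

Clone sizes are indexed **within patient, pooled across timepoints**: a
patient's clone is one biological entity across the longitudinal series,
and the presence/absence set algebra treats it as such. Per-sample sizing
is available via `assign_clonotypes(per_sample=True)` (see "Persistence
estimation" for where that matters). A clonotype is **clonal** when its
pooled size is *strictly greater than* the threshold (default 3, i.e.
≥ 4 cells) — the strict inequality is deliberate and tested.

## Tumor association

`build_tumor_repertoire` collapses a tumor clonotype table to distinct
uppercased amino-acid CDR3s with summed clone counts. A peripheral cell is
tumor-matched iff its key is in its **own** patient's set; cross-patient
matching is a contract violation, not an option. Exact string equality is
the default because repertoire "overlap" without a stated edit-distance
relaxation is conservatively read as identity; a Hamming-distance-1 mode
exists behind a flag for sensitivity analyses. By default all assigned
cells are eligible; `clonal_only=True` restricts matching to clonal
clonotypes.

## Longitudinal set algebra

Per patient, the clonal clonotypes observed (≥ 1 cell) at each sampled
timepoint form a set. `venn_partition` assigns every clonotype in the
union to exactly one presence-pattern bucket by direct per-element
enumeration; conservation (bucket counts sum to the union size) is
asserted on every call. Derived statistics:

* `shared_ge_k` = fraction of the union present in ≥ k timepoints,
  k = 2..(#sampled timepoints). Thresholds run over *sampled* timepoints so
  patients missing a draw are not penalised; patients with < 2 sampled
  timepoints are excluded with a warning.
* pairwise Jaccard `|A∩B|/|A∪B|` and forward maintenance `|A∩B|/|A|` for
  every chronologically ordered pair.

"Shared longitudinally" has no single canonical denominator, so the module
emits every candidate reading — `shared_ge_2/3/4`, all pairwise metrics —
labelled, rather than committing to one. Group summaries report both the
per-patient mean and the pooled variant (clonotype keys namespaced per
patient before pooling, since CDR3 identity across patients is not clonal
identity). Percentages are kept at full precision internally and rounded
only for display.

## Pseudobulk and ssGSEA

`aggregate_pseudobulk` computes exact integer sums of raw counts per
sample, optionally restricted to one cell type first; samples left with
zero passing cells are omitted with a warning. Expression fed to ssGSEA is
`log2(1e6·count/colsum + 1)` (log-CPM); since ssGSEA depends on expression
only through within-unit ranks, any within-unit monotone normalisation
yields identical scores — the choice is documented, not load-bearing.

ssGSEA per unit: rank genes by expression (average ranks on ties), walk
the list in descending order (stable tie order), add
`rank_g^α / Σ_in rank^α` at in-set genes, subtract `1/(N−m)` at out-of-set
genes, and integrate: the score is the sum of the running-sum values over
all N steps. Defaults α = 0.25 and matrix-wide min–max normalisation
(divide by global max − min), the common ssGSEA convention; both are
configurable. Per-cell scoring reuses the same operation on per-cell
log-CPM with no imputation. Gene sets are intersected with the expression
genes; empty intersections are skipped with a warning.

## Statistics

* **Paired Wilcoxon signed-rank** — zero differences dropped (classic
  convention; Pratt mode behind a flag). For ≤ 25 informative pairs the
  p value is exact: the null PMF of the positive-rank sum is built by
  dynamic programming over doubled ranks (doubling makes average ranks
  from ties integral), equivalent to full 2^n enumeration but O(n·Σr).
  Above 25 pairs, normal approximation with continuity correction and tie
  correction. Two-sided p = 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)), capped at 1.
* **t tests** — scipy; zero-variance cases return flagged degenerate
  results instead of NaN propagation.
* **ANOVA + Tukey HSD** — scipy `f_oneway` + `tukey_hsd`
  (studentized-range adjustment). Groups with < 2 observations are
  excluded with a warning.
* **Kruskal–Wallis + Dunn** — scipy omnibus; Dunn z from pooled mean ranks
  with tie-corrected variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`, BH across
  the pairwise family.
* **BH adjustment** — standard step-up (statsmodels), capped at 1.
  Step-up BH is monotone but *not* idempotent in general (re-adjusting
  (0.2, 0.6) gives (0.4, 0.6)); tests assert monotonicity and the genuine
  fixed points, not idempotence.
* **Rank-sum DE** — genes are pre-filtered to |log2FC| ≥ 0.5 on group
  means (pseudocount 1e-9) *before* testing, mirroring marker-finder
  semantics where the fold-change threshold gates the tested family; BH
  runs over tested genes only; `passes` requires both thresholds
  (p_adj ≤ 1e-5 by default). Because the pre-filter conditions on large
  observed effects, type-I calibration of the test is run with the filter
  off (threshold 0) — with the filter on, null genes that pass it are
  selected for extremity and their rejection rate is inflated by
  construction, which would measure the selection step, not the test.

## Synthetic cohort generator

What it emulates: 7 patients (4 responders RCB0_I, 3 non-responders
RCB_II_III) × 4 timepoints × 2,000 cells per sample (study scale is
~2,800); cell-type fractions per timepoint encode the classical-monocyte
dip after chemotherapy and rebound after ICI.

* **Clone sizes** — each patient keeps a pool of 200 active clones with
  latent weights ~ Geometric(p = 0.15) (mean ≈ 6.7); CD8 T cells draw
  clonotypes multinomially ∝ weight, CD4 T cells carry singleton TCRs,
  non-T cells carry none. The geometric law is the simplest heavy-tailed
  choice; it is configurable, and the pool size/tail were chosen so that
  genuinely expanded clones are detected as clonal from a single sample —
  a requirement for the persistence recovery described below.
* **Persistence** — between consecutive timepoints each active clone
  survives with probability ρ(group): responders 0.10, non-responders
  0.35; dead clones are replaced by fresh ones. This is the simplest
  mechanism producing the emulated qualitative contrast (a turning-over
  responder repertoire, < 15% shared, vs a stable non-responder one,
  ~20–40% maintained), and because clone sizes pool across timepoints,
  longer-lived clones also make non-responders more clonal — the group
  clonality difference is emergent, not separately planted.
* **Tumor lists** — sampled from baseline-active clones of latent weight
  ≥ 3 with probability ∝ weight^bias (bias 1.0), plus 80 tumor-private
  clones; expanded-clone cells sit in effector-like CD8 subclusters and
  small-clone cells in naive-like ones, so naive clusters carry no
  tumor-matched TCRs by construction.
* **Counts** — NB(mean = per-gene lognormal base × 2^effect, dispersion 2)
  with a per-cell lognormal size factor; default planted effects are a
  +1 log2 shift of the interferon-like set and a −1 log2 shift of the
  complement-like set at post_chemo in all patients. The shipped gene sets
  are synthetic hallmark-like stand-ins (30 genes each), not any curated
  collection.
* CDR3 strings are "CASS" + 8 random residues + "F" — cosmetic only.

Everything is driven by one `numpy` Generator seeded from `SimConfig.seed`;
identical seeds give byte-identical bundles. The truth record stores clone
weights, per-timepoint active sets, tumor lists and planted effects.

What the generator does **not** model: V(D)J recombination statistics,
transcriptional state coupled to clonotype, batch effects, doublets or
ambient RNA, library-size differences between samples beyond the per-cell
factor, and biological correlation between clone size and phenotype beyond
the subcluster assignment rule. Passing recovery tests therefore
demonstrates that the pipeline's estimators are correct under the stated
generative assumptions, not that they are robust to all failure modes of
real data.

## Persistence estimation

`recover_parameters` estimates ρ per group as forward maintenance over
consecutive timepoint pairs with the earlier set restricted to clones
clonal **within that sample alone** (per-sample sizing) and detection
defined as ≥ 1 cell later. Conditioning set membership at time t on
time-t information only is essential: under patient-pooled clonality, a
clone's clonal status depends on how long it survived, so pooled-clonal
sets select survivors and inflate maintenance (measured bias ≈ +0.07–0.10
against true ρ); the time-t-only estimator is unbiased up to sampling
dropout (clones clonal in one sample are large enough that missing them
entirely at the next draw is rare), with measured mean absolute error
≈ 0.02 across seeds.

## Problem sizes used in validation

The test suite and acceptance script scale simulations to what the checks
need: repertoire-level recovery runs 20 cohorts at full default scale
without the count layer (the TCR and count layers are independent by
construction); signature detection power runs 50 planted + 50 null
replicates at 300 cells/sample and 400 genes, since pseudobulk detection
power is set by the 7 patient pairs and the planted effect, not by cell
count; type-I calibration uses 2,000 null replicates. These sizes are the
package's validation choices and are stated here so they can be rescaled
deliberately.

## Degenerate inputs and tie-breaks

All-zero difference vectors return p = 1 with a `degenerate` flag; zero
variance with non-zero effect returns p = 0 with a `zero_variance` flag.
Groups with no assigned cells keep their report rows with NA percentages
(undefined, never 0). Empty tumor tables and empty gene-set intersections
warn and continue. UMI ties, expression ties and rank ties all break
deterministically (lexicographic / average ranks / stable sort), so every
pipeline output is reproducible bit-for-bit for a fixed input and config.
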