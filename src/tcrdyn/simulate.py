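"""Seeded synthetic-cohort generator with known ground truth.

The generator emulates the statistical structure of a longitudinal PBMC
scRNA/TCR cohort from a neoadjuvant chemo + checkpoint-inhibitor trial:

* 7 patients (4 responders RCB0_I, 3 non-responders RCB_II_III), each
  sampled at baseline, post_chemo, post_ici and endpoint;
* heavy-tailed (geometric) clone-size law over each patient's active TCR
  clone pool; CD8 T cells draw clonotypes proportional to clone weight,
  CD4 T cells carry singleton TCRs, non-T cells carry none;
* per-clone Bernoulli persistence between consecutive timepoints with a
  group-dependent rate (non-responders retain clones at a higher rate than
  responders, whose repertoires turn over) — the simplest mechanism
  producing group-dependent longitudinal sharing. Because clone sizes are
  pooled per patient, higher persistence also yields higher clonality, so
  the group clonality contrast is emergent, not separately planted;
* tumor clonotype lists sampled from the baseline-active *expanded* clones
  with probability proportional to clone_weight^tumor_overlap_bias, plus
  tumor-private clones; expanded-clone cells sit in effector-like CD8
  subclusters while small-clone cells sit in naive-like subclusters, so
  naive clusters carry no tumor-matched TCRs by construction;
* negative-binomial gene counts with per-(gene-set, group, timepoint)
  log2 multipliers planting signature signal (default: an interferon-like
  set shifted at post_chemo in all patients).

CDR3 strings are generated as "CASS" + 8 random residues + "F" to look
like beta-chain CDR3s; this is purely cosmetic. Every latent quantity is
recorded in a truth dictionary for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    RESPONSES,
    TIMEPOINTS,
    CountsMatrix,
    write_cell_table,
    write_contigs,
    write_counts_mtx,
    write_gmt,
    write_tumor_clones,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"

EXPANDED_SUBCLUSTERS = ("GZMB_early", "GZMB_late_EM", "GZMK_early", "GZMK_late")
NAIVE_SUBCLUSTERS = ("naive_cm", "transitioning")

DEFAULT_CELLTYPE_FRACTIONS = {
    # classical-monocyte dip after chemotherapy and rebound after ICI
    "baseline":   {"CD8_T": 0.25, "CD4_T": 0.24, "B": 0.12, "classical_mono": 0.20,
                   "nonclassical_mono": 0.05, "NK": 0.14},
    "post_chemo": {"CD8_T": 0.29, "CD4_T": 0.27, "B": 0.15, "classical_mono": 0.10,
                   "nonclassical_mono": 0.03, "NK": 0.16},
    "post_ici":   {"CD8_T": 0.25, "CD4_T": 0.23, "B": 0.11, "classical_mono": 0.22,
                   "nonclassical_mono": 0.06, "NK": 0.13},
    "endpoint":   {"CD8_T": 0.26, "CD4_T": 0.24, "B": 0.12, "classical_mono": 0.19,
                   "nonclassical_mono": 0.05, "NK": 0.14},
}


def default_gene_sets(n_genes_per_set: int = 30) -> dict[str, list[str]]:
    """Synthetic hallmark-like gene sets (interferon-, complement-, and a
    null control set); not derived from any curated collection."""
    return {
        "IFN_RESPONSE_SIM": [f"IFNS{i:03d}" for i in range(n_genes_per_set)],
        "COMPLEMENT_SIM": [f"COMPS{i:03d}" for i in range(n_genes_per_set)],
        "NULL_CONTROL_SIM": [f"NULLS{i:03d}" for i in range(n_genes_per_set)],
    }


@dataclass
class SimConfig:
    """Generator parameters; defaults encode the emulated study conditions.

    ``persistence_rho`` is the per-clone probability that an active clone at
    one timepoint remains active at the next; non-responder repertoires are
    stable (0.35) while responder repertoires turn over (0.10).
    ``signature_effects`` entries are (set_name, response or None for both
    groups, timepoint, log2 multiplier) applied to the NB mean of the set's
    genes in the matching samples.
    """

    n_patients_per_group: dict[str, int] = field(
        default_factory=lambda: {"RCB0_I": 4, "RCB_II_III": 3}
    )
    timepoints: tuple[str, ...] = TIMEPOINTS
    cells_per_sample: int = 2000
    n_clones: int = 200                    # active clone pool per timepoint
    clone_geom_p: float = 0.15             # geometric clone-weight law P(w) ~ p(1-p)^(w-1)
    persistence_rho: dict[str, float] = field(
        default_factory=lambda: {"RCB0_I": 0.10, "RCB_II_III": 0.35}
    )
    tumor_overlap_bias: float = 1.0        # tumor sampling weight ~ clone_weight^bias
    n_tumor_clones: int = 120              # blood-overlapping tumor clones per patient
    n_tumor_private: int = 80              # tumor-only clones per patient
    expanded_weight_min: int = 3           # latent weight >= this -> effector-like subcluster
    n_genes: int = 1500
    nb_dispersion: float = 2.0
    base_mean_log_mu: float = -1.0         # lognormal law of per-gene NB means
    base_mean_log_sigma: float = 1.0
    signature_effects: list[tuple[str, str | None, str, float]] = field(
        default_factory=lambda: [
            ("IFN_RESPONSE_SIM", None, "post_chemo", 1.0),
            ("COMPLEMENT_SIM", None, "post_chemo", -1.0),
        ]
    )
    celltype_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {tp: dict(fr) for tp, fr in DEFAULT_CELLTYPE_FRACTIONS.items()}
    )
    seed: int = 0

    def validate(self) -> None:
        for tp, fr in self.celltype_fractions.items():
            total = sum(fr.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"celltype_fractions[{tp}] sum to {total}, expected 1")
            if any(v < 0 for v in fr.values()):
                raise ValueError(f"celltype_fractions[{tp}] contains negative fractions")
        for g, r in self.persistence_rho.items():
            if not 0 <= r <= 1:
                raise ValueError(f"persistence_rho[{g}]={r} outside [0,1]")
        if not 0 < self.clone_geom_p <= 1:
            raise ValueError("clone_geom_p must lie in (0, 1]")
        if self.cells_per_sample < 1 or self.n_clones < 1 or self.n_genes < 2:
            raise ValueError("cells_per_sample, n_clones >= 1 and n_genes >= 2 required")


@dataclass
class SimulatedCohort:
    cells: pd.DataFrame
    contigs: pd.DataFrame
    tumor_clones: dict[str, pd.DataFrame]
    counts: CountsMatrix | None
    gene_sets: dict[str, list[str]]
    truth: dict
    config: SimConfig


def _random_cdr3(rng: np.random.Generator) -> tuple[str, str]:
    mid = "".join(rng.choice(list(AA), size=8))
    aa = f"CASS{mid}F"
    nt = "".join(rng.choice(list(NT), size=3 * len(aa)))
    return aa, nt


class _ClonePool:
    """Patient-level latent clone registry."""

    def __init__(self, rng: np.random.Generator, geom_p: float, expanded_min: int):
        self.rng = rng
        self.geom_p = geom_p
        self.expanded_min = expanded_min
        self.weights: list[int] = []
        self.cdr3_aa: list[str] = []
        self.cdr3_nt: list[str] = []
        self.tra_aa: list[str] = []
        self.tra_nt: list[str] = []
        self.subcluster: list[str] = []

    def new_clones(self, n: int) -> np.ndarray:
        ids = np.arange(len(self.weights), len(self.weights) + n)
        w = self.rng.geometric(self.geom_p, size=n)
        for wi in w:
            aa, nt = _random_cdr3(self.rng)
            tra_aa, tra_nt = _random_cdr3(self.rng)
            self.weights.append(int(wi))
            self.cdr3_aa.append(aa)
            self.cdr3_nt.append(nt)
            self.tra_aa.append("CAV" + tra_aa[4:])
            self.tra_nt.append(tra_nt)
            pool = EXPANDED_SUBCLUSTERS if wi >= self.expanded_min else NAIVE_SUBCLUSTERS
            self.subcluster.append(str(self.rng.choice(pool)))
        return ids


def simulate_repertoire(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame], dict]:
    """Cell table, contig table and per-patient tumor clone tables."""
    patients: list[tuple[str, str]] = []
    for resp in RESPONSES:
        for i in range(cfg.n_patients_per_group.get(resp, 0)):
            patients.append((f"PT{len(patients) + 1:02d}", resp))

    cell_rows, contig_rows = [], []
    tumor_tables: dict[str, pd.DataFrame] = {}
    truth: dict = {
        "persistence_rho": dict(cfg.persistence_rho),
        "signature_effects": [list(e) for e in cfg.signature_effects],
        "patients": {},
    }
    celltypes_by_tp = {
        tp: (list(fr.keys()), np.array(list(fr.values()))) for tp, fr in cfg.celltype_fractions.items()
    }

    for patient, resp in patients:
        pool = _ClonePool(rng, cfg.clone_geom_p, cfg.expanded_weight_min)
        rho = cfg.persistence_rho[resp]
        active = pool.new_clones(cfg.n_clones)
        active_by_tp: dict[str, np.ndarray] = {}
        cd4_counter = 0
        for t_i, tp in enumerate(cfg.timepoints):
            if t_i > 0:
                survive = rng.random(len(active)) < rho
                survivors = active[survive]
                fresh = pool.new_clones(cfg.n_clones - len(survivors))
                active = np.concatenate([survivors, fresh])
            active_by_tp[tp] = active.copy()

            sample_id = f"{patient}_{tp}"
            names, fracs = celltypes_by_tp[tp]
            ct_counts = rng.multinomial(cfg.cells_per_sample, fracs)
            cell_i = 0
            w_active = np.array([pool.weights[c] for c in active], dtype=float)
            p_active = w_active / w_active.sum()
            for ct, n_ct in zip(names, ct_counts):
                if n_ct == 0:
                    continue
                if ct == "CD8_T":
                    clone_ids = active[rng.choice(len(active), size=n_ct, p=p_active)]
                for k in range(n_ct):
                    barcode = f"{sample_id}:BC{cell_i:05d}"
                    cell_i += 1
                    sub = pd.NA
                    if ct == "CD8_T":
                        cid = int(clone_ids[k])
                        sub = pool.subcluster[cid]
                        umis = int(1 + rng.poisson(3))
                        contig_rows.append(
                            (barcode, sample_id, "TRB", pool.cdr3_aa[cid],
                             pool.cdr3_nt[cid], "True", umis)
                        )
                        contig_rows.append(
                            (barcode, sample_id, "TRA", pool.tra_aa[cid],
                             pool.tra_nt[cid], "True", max(1, umis - 1))
                        )
                    elif ct == "CD4_T":
                        aa, nt = _random_cdr3(rng)
                        cd4_counter += 1
                        contig_rows.append(
                            (barcode, sample_id, "TRB", aa, nt, "True",
                             int(1 + rng.poisson(2)))
                        )
                    cell_rows.append(
                        (barcode, sample_id, patient, tp, resp, ct, sub)
                    )

        # tumor biopsy: expanded baseline clones, sampled by weight^bias, plus private clones
        base = active_by_tp[cfg.timepoints[0]]
        weights = np.array([pool.weights[c] for c in base], dtype=float)
        expanded = base[weights >= cfg.expanded_weight_min]
        w_exp = weights[weights >= cfg.expanded_weight_min] ** cfg.tumor_overlap_bias
        n_pick = min(cfg.n_tumor_clones, len(expanded))
        picked = rng.choice(len(expanded), size=n_pick, replace=False, p=w_exp / w_exp.sum())
        rows = []
        for cid in expanded[picked]:
            cid = int(cid)
            rows.append(
                (len(rows), int(pool.weights[cid] * rng.integers(10, 100)),
                 pool.cdr3_aa[cid], pool.cdr3_nt[cid])
            )
        for _ in range(cfg.n_tumor_private):
            aa, nt = _random_cdr3(rng)
            rows.append((len(rows), int(rng.geometric(cfg.clone_geom_p) * rng.integers(10, 100)), aa, nt))
        tumor_tables[patient] = pd.DataFrame(
            rows, columns=["clone_id", "clone_count", "cdr3_aa", "cdr3_nt"]
        )

        truth["patients"][patient] = {
            "response": resp,
            "rho": rho,
            "active_cdr3_by_timepoint": {
                tp: [pool.cdr3_aa[int(c)] for c in ids] for tp, ids in active_by_tp.items()
            },
            "clone_weights": {pool.cdr3_aa[i]: int(w) for i, w in enumerate(pool.weights)},
            "tumor_cdr3": sorted(set(tumor_tables[patient]["cdr3_aa"])),
        }

    cells = pd.DataFrame(
        cell_rows,
        columns=["barcode", "sample_id", "patient_id", "timepoint", "response",
                 "cell_type", "subcluster"],
    )
    contigs = pd.DataFrame(
        contig_rows,
        columns=["barcode", "sample_id", "chain", "cdr3_aa", "cdr3_nt", "productive", "umis"],
    )
    contigs["productive"] = contigs["productive"] == "True"
    return cells, contigs, tumor_tables, truth


def simulate_counts(
    cfg: SimConfig, cells: pd.DataFrame, gene_sets: dict[str, list[str]],
    rng: np.random.Generator,
) -> tuple[CountsMatrix, dict]:
    """Negative-binomial gene x cell counts with planted signature effects."""
    set_genes = [g for gs in gene_sets.values() for g in gs]
    n_filler = cfg.n_genes - len(set_genes)
    if n_filler < 0:
        raise ValueError("n_genes smaller than the union of gene-set genes")
    genes = set_genes + [f"G{i:05d}" for i in range(n_filler)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    base_mean = rng.lognormal(cfg.base_mean_log_mu, cfg.base_mean_log_sigma, size=len(genes))
    effect_log2 = {}  # (response, timepoint) -> per-gene log2 shift vector
    for set_name, group, tp, lfc in cfg.signature_effects:
        targets = [RESPONSES[0], RESPONSES[1]] if group is None else [group]
        for g in targets:
            vec = effect_log2.setdefault((g, tp), np.zeros(len(genes)))
            for gene in gene_sets[set_name]:
                vec[gene_pos[gene]] += lfc

    blocks, cell_order = [], []
    r = cfg.nb_dispersion
    for sample_id, sub in cells.groupby("sample_id", sort=True):
        resp = sub["response"].iloc[0]
        tp = sub["timepoint"].iloc[0]
        mean = base_mean * 2.0 ** effect_log2.get((resp, tp), 0.0)
        size_factor = rng.lognormal(0.0, 0.3, size=len(sub))
        m = mean[:, None] * size_factor[None, :]
        p = r / (r + m)
        block = rng.negative_binomial(r, p).astype(np.int32)
        blocks.append(sp.csc_matrix(block))
        cell_order.append(sub[["barcode", "sample_id"]])
    matrix = sp.hstack(blocks, format="csc")
    cell_df = pd.concat(cell_order, ignore_index=True)
    truth_counts = {"base_mean_first5": base_mean[:5].tolist()}
    return CountsMatrix(genes=genes, cells=cell_df, matrix=matrix), truth_counts


def simulate_cohort(cfg: SimConfig | None = None, include_counts: bool = True) -> SimulatedCohort:
    """Generate a full synthetic cohort; deterministic given ``cfg.seed``."""
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cells, contigs, tumor_tables, truth = simulate_repertoire(cfg, rng)
    gene_sets = default_gene_sets()
    counts = None
    if include_counts:
        counts, truth_counts = simulate_counts(cfg, cells, gene_sets, rng)
        truth["counts"] = truth_counts
    return SimulatedCohort(
        cells=cells, contigs=contigs, tumor_clones=tumor_tables, counts=counts,
        gene_sets=gene_sets, truth=truth, config=cfg,
    )


def write_bundle(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write the complete input bundle + truth JSON into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cell_table(cohort.cells, outdir / "cell_table.csv")
    contigs = cohort.contigs.copy()
    contigs["productive"] = np.where(contigs["productive"], "True", "False")
    write_contigs(contigs, outdir / "contigs.csv")
    tumor_dir = outdir / "tumor_clones"
    tumor_dir.mkdir(exist_ok=True)
    for patient, df in cohort.tumor_clones.items():
        write_tumor_clones(df, tumor_dir / f"{patient}.tsv")
    write_gmt(cohort.gene_sets, outdir / "gene_sets.gmt")
    if cohort.counts is not None:
        write_counts_mtx(cohort.counts, outdir / "counts")
    truth = dict(cohort.truth)
    truth["config"] = {
        k: v for k, v in asdict(cohort.config).items() if not isinstance(v, tuple)
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))


def recover_parameters(cohort: SimulatedCohort) -> dict:
    """Run the pipeline on a simulated cohort and compare against truth.

    Reports (i) estimated per-group clone persistence against the
    configured rho, (ii) detection of the planted signature effects via
    paired score contrasts on pseudobulk ssGSEA, and (iii) the
    between-group clonality difference (per-patient percent clonal CD8 T
    cells).

    The persistence estimator is the consecutive-pair forward maintenance
    |A∩B|/|A| with A the clones *clonal within the earlier sample alone*
    (per-sample sizing) and B all clones observed at the later timepoint.
    Conditioning set membership at time t on time-t cells only is essential
    for an unbiased transition-rate estimate: under patient-pooled
    clonality a clone's "clonal" status depends on how long it survived, so
    pooled-clonal sets select survivors and inflate maintenance.
    """
    from .clonotype import assign_clonotypes, clonality_report, is_clonal
    from .dynamics import clonal_sets_by_timepoint, group_sharing, patient_sharing
    from .enrichment import aggregate_pseudobulk, normalize_log_cpm, score_contrast, ssgsea
    from .stats import unpaired_t

    cd8 = cohort.cells[cohort.cells["cell_type"] == "CD8_T"]
    assignment = assign_clonotypes(cd8, cohort.contigs)
    flags = is_clonal(assignment)
    sets = clonal_sets_by_timepoint(cd8, assignment, flags)
    _, summaries = patient_sharing(sets)
    pat2resp = cohort.cells.drop_duplicates("patient_id").set_index("patient_id")["response"]

    # persistence: per-sample clonal sets at t, any observation at t+1
    ps = assign_clonotypes(cd8, cohort.contigs, per_sample=True)
    samp2tp = cohort.cells.drop_duplicates("sample_id").set_index("sample_id")["timepoint"]
    cs = ps.clone_sizes.assign(timepoint=lambda d: d["sample_id"].map(samp2tp))
    tps = [tp for tp in cohort.config.timepoints]
    maint_rows = []
    for patient, sub in cs.groupby("patient_id"):
        by_tp = {tp: g for tp, g in sub.groupby("timepoint")}
        for a, b in zip(tps[:-1], tps[1:]):
            if a not in by_tp or b not in by_tp:
                continue
            clonal_a = set(by_tp[a].loc[by_tp[a]["n_cells"] > 3, "clonotype_key"])
            obs_b = set(by_tp[b]["clonotype_key"])
            if clonal_a:
                maint_rows.append(
                    {"patient_id": patient, "step": f"{a}->{b}",
                     "maintained": len(clonal_a & obs_b) / len(clonal_a)}
                )
    maint = pd.DataFrame(maint_rows)

    report: dict = {"persistence": {}, "sharing": {}, "signatures": {}, "clonality": {}}
    for resp in RESPONSES:
        pats = [p for p in summaries if pat2resp[p] == resp]
        vals = maint[maint["patient_id"].isin(pats)]["maintained"] if len(maint) else pd.Series(dtype=float)
        est = float(vals.mean()) if len(vals) else np.nan
        true = cohort.truth["persistence_rho"][resp]
        report["persistence"][resp] = {
            "true_rho": true, "estimated": est, "abs_error": abs(est - true),
        }

    gs = group_sharing(summaries, sets, cohort.cells)
    ge2 = gs[(gs["metric"] == "shared_ge_2") & (gs["statistic"] == "per_patient_mean")]
    ge2_by = dict(zip(ge2["response"], ge2["value_pct"]))
    report["sharing"] = {
        "shared_ge_2_pct": ge2_by,
        "nonresponder_exceeds_responder": bool(
            ge2_by.get("RCB_II_III", np.nan) > ge2_by.get("RCB0_I", np.nan)
        ),
    }

    rep = clonality_report(cohort.cells[cohort.cells["cell_type"] == "CD8_T"],
                           assignment, group_by="cell_type", per="patient")
    pct = rep.set_index("patient_id")["pct_clonal"]
    a = pct[[p for p in pct.index if pat2resp[p] == "RCB_II_III"]].to_numpy()
    b = pct[[p for p in pct.index if pat2resp[p] == "RCB0_I"]].to_numpy()
    res = unpaired_t(a, b)
    report["clonality"] = {
        "mean_pct_clonal": {"RCB_II_III": float(a.mean()), "RCB0_I": float(b.mean())},
        "nonresponder_more_clonal": bool(a.mean() > b.mean()),
        "t_p": res.p,
    }

    if cohort.counts is not None:
        pbm = aggregate_pseudobulk(cohort.counts, cohort.cells)
        expr = normalize_log_cpm(pbm)
        scores = ssgsea(expr, cohort.gene_sets)
        meta = pbm.meta.rename(columns={"sample_id": "unit"})
        for set_name, _group, tp, lfc in cohort.truth["signature_effects"]:
            res_tbl = score_contrast(scores, meta, ("baseline", tp), paired=True)
            row = res_tbl[res_tbl["set"] == set_name]
            report["signatures"][set_name] = {
                "timepoint": tp, "true_log2_effect": lfc,
                "p": float(row["p"].iloc[0]) if len(row) else np.nan,
                "detected": bool(len(row) and row["p"].iloc[0] < 0.05),
            }
    return report
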