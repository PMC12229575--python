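"""End-to-end orchestration: a declarative config, staged execution, and a
run manifest for reproducibility.

Stages run in dependency order: io -> clonotype -> tumor_match ->
longitudinal_dynamics -> pseudobulk_enrichment -> stats/abundance. Each
stage communicates with the next only through the declared artifacts, so
stages can also be run in isolation on the same bundle. A failed stage
aborts the run with its name; the manifest (config hash, seed, package
version, artifact list) makes reruns comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .clonotype import assign_clonotypes, clonality_report, is_clonal
from .dynamics import (
    clonal_sets_by_timepoint,
    consecutive_maintenance,
    group_sharing,
    patient_sharing,
)
from .enrichment import aggregate_pseudobulk, normalize_log_cpm, score_contrast, ssgsea
from .stats import anova_tukey, kruskal_dunn, paired_wilcoxon
from .tumormatch import build_tumor_repertoire, tumor_match_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative run configuration; see ``PipelineConfig.from_yaml``."""

    cell_table: str
    contigs: str
    tumor_clone_dir: str | None = None
    gene_sets: str | None = None
    counts_dir: str | None = None
    output_dir: str = "tcrdyn_out"
    key_mode: str = "TRB_aa"
    clonal_threshold: int = 3            # clonal iff clone size strictly > this
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = True
    enrichment_cell_type: str | None = None   # restrict pseudobulk to one cell type
    contrast_timepoints: tuple[str, str] = ("baseline", "post_chemo")
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        if "contrast_timepoints" in kwargs:
            kwargs["contrast_timepoints"] = tuple(kwargs["contrast_timepoints"])
        return cls(**kwargs)

    def validate(self) -> None:
        if self.clonal_threshold < 1:
            raise ValueError("clonal_threshold must be >= 1")
        for name in ("cell_table", "contigs"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: {p} does not exist")
        for name in ("tumor_clone_dir", "gene_sets", "counts_dir"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: {p} does not exist")

    def content_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts; returns the manifest.

    Outputs (TSV unless noted): clonality_report, clone_sizes,
    tumor_match_report, venn_partitions, sharing_summaries,
    pairwise_overlap, group_sharing, abundance + abundance_tests,
    enrichment_scores + enrichment_tests, and manifest.json.
    """
    from . import __version__

    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    stage = "io"
    try:
        cells = tio.read_cell_table(cfg.cell_table)
        contigs = tio.read_contigs(cfg.contigs)

        stage = "clonotype"
        t_cells = cells[cells["cell_type"].isin({"CD8_T", "CD4_T"})]
        cd8 = cells[cells["cell_type"] == "CD8_T"]
        assignment = assign_clonotypes(t_cells, contigs, key_mode=cfg.key_mode)
        cd8_assignment = assign_clonotypes(cd8, contigs, key_mode=cfg.key_mode)
        _write(assignment.clone_sizes, out / "clone_sizes.tsv", artifacts)
        group_col = "subcluster" if cd8["subcluster"].notna().any() else "cell_type"
        rep = clonality_report(cd8, cd8_assignment, group_by=group_col,
                               threshold=cfg.clonal_threshold)
        _write(rep, out / "clonality_report.tsv", artifacts)

        stage = "tumor_match"
        if cfg.tumor_clone_dir is not None:
            reps = {}
            for path in sorted(Path(cfg.tumor_clone_dir).glob("*.tsv")):
                patient = path.stem
                reps[patient] = build_tumor_repertoire(tio.read_tumor_clones(path), patient)
            tm = tumor_match_report(cd8, cd8_assignment, reps, group_by=group_col)
            _write(tm, out / "tumor_match_report.tsv", artifacts)

        stage = "longitudinal_dynamics"
        flags = is_clonal(cd8_assignment, threshold=cfg.clonal_threshold)
        sets = clonal_sets_by_timepoint(cd8, cd8_assignment, flags)
        partitions, summaries = patient_sharing(sets)
        _write(pd.concat([p.pattern_table() for p in partitions.values()],
                         ignore_index=True) if partitions else pd.DataFrame(),
               out / "venn_partitions.tsv", artifacts)
        _write(pd.DataFrame([s.to_row() for s in summaries.values()]),
               out / "sharing_summaries.tsv", artifacts)
        _write(pd.concat([s.pairwise for s in summaries.values()], ignore_index=True)
               if summaries else pd.DataFrame(),
               out / "pairwise_overlap.tsv", artifacts)
        _write(group_sharing(summaries, sets, cells), out / "group_sharing.tsv", artifacts)
        _write(consecutive_maintenance(summaries), out / "consecutive_maintenance.tsv",
               artifacts)

        stage = "abundance"
        ab = celltype_abundance(cells)
        _write(ab, out / "abundance.tsv", artifacts)
        _write(abundance_tests(ab), out / "abundance_tests.tsv", artifacts)

        stage = "pseudobulk_enrichment"
        if cfg.counts_dir is not None and cfg.gene_sets is not None:
            counts = tio.read_counts_mtx(cfg.counts_dir)
            sets_gmt = tio.read_gmt(cfg.gene_sets)
            pbm = aggregate_pseudobulk(counts, cells, cell_filter=cfg.enrichment_cell_type)
            expr = normalize_log_cpm(pbm)
            scores = ssgsea(expr, sets_gmt, alpha=cfg.ssgsea_alpha,
                            normalize=cfg.ssgsea_normalize)
            _write(scores.rename_axis("unit").reset_index(), out / "enrichment_scores.tsv",
                   artifacts)
            meta = pbm.meta.rename(columns={"sample_id": "unit"})
            tests = score_contrast(scores, meta, cfg.contrast_timepoints, paired=True)
            _write(tests, out / "enrichment_tests.tsv", artifacts)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "tcrdyn",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.content_hash(),
        "config": asdict(cfg),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    if (out / "FAILED").exists():
        (out / "FAILED").unlink()
    return manifest


def _write(df: pd.DataFrame, path: Path, artifacts: list[str]) -> None:
    df.to_csv(path, sep="\t", index=False)
    artifacts.append(path.name)


def celltype_abundance(cells: pd.DataFrame) -> pd.DataFrame:
    """Percent of each cell type among a sample's PBMCs."""
    tot = cells.groupby("sample_id").size().rename("n_total")
    ab = (
        cells.groupby(["patient_id", "sample_id", "timepoint", "response", "cell_type"])
        .size()
        .rename("n")
        .reset_index()
        .merge(tot, on="sample_id")
    )
    ab["pct"] = 100.0 * ab["n"] / ab["n_total"]
    return ab


def abundance_tests(ab: pd.DataFrame) -> pd.DataFrame:
    """Longitudinal and between-group abundance comparisons per cell type.

    Longitudinal: paired Wilcoxon per consecutive timepoint pair (pairing on
    patient). Multi-group: one-way ANOVA + Tukey and Kruskal-Wallis + Dunn
    across timepoints.
    """
    rows = []
    for ct, sub in ab.groupby("cell_type"):
        wide = sub.pivot_table(index="patient_id", columns="timepoint", values="pct")
        tps = [t for t in tio.TIMEPOINTS if t in wide.columns]
        for a, b in zip(tps[:-1], tps[1:]):
            pair = wide[[a, b]].dropna()
            if len(pair) < 2:
                continue
            res = paired_wilcoxon(pair[a].to_numpy(), pair[b].to_numpy())
            rows.append({"cell_type": ct, "test": "paired_wilcoxon",
                         "contrast": f"{a} vs {b}", "n": res.n,
                         "statistic": res.statistic, "p": res.p})
        groups = {t: wide[t].dropna().to_numpy() for t in tps}
        groups = {t: v for t, v in groups.items() if len(v) >= 2}
        if len(groups) >= 2:
            omni, _ = anova_tukey(groups)
            rows.append({"cell_type": ct, "test": "anova", "contrast": "timepoints",
                         "n": omni.n, "statistic": omni.statistic, "p": omni.p})
            omni_k, _ = kruskal_dunn(groups)
            rows.append({"cell_type": ct, "test": "kruskal", "contrast": "timepoints",
                         "n": omni_k.n, "statistic": omni_k.statistic, "p": omni_k.p})
    return pd.DataFrame(rows, columns=["cell_type", "test", "contrast", "n", "statistic", "p"])
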