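"""Clonotype assignment from CDR3 sequences and clonality reporting.

A cell's clonotype key is derived from its TCR CDR3: by default the
amino-acid CDR3 of its most-supported (highest UMI) productive TRB chain,
the field convention that also maximises matchability against bulk-tumor
clonotype exports. Clone sizes are indexed within patient, pooling that
patient's timepoints, so that a clone is one entity per patient across the
longitudinal series; per-sample sizing is available by flag.

A clonotype is *clonal* when strictly more than ``threshold`` cells of the
patient share its CDR3 (default threshold 3, i.e. clonal means >= 4 cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

KEY_MODES = ("TRB_aa", "TRB_nt", "TRA_TRB_aa")

#: Default clonal-size threshold: clonal iff clone size > 3 cells.
CLONAL_THRESHOLD = 3


@dataclass
class ClonotypeAssignment:
    """Per-cell clonotype keys plus the per-patient clone-size index.

    Attributes
    ----------
    per_cell
        DataFrame with columns ``barcode, sample_id, patient_id, clonotype_key``;
        one row per cell that received a key.
    clone_sizes
        DataFrame with columns ``patient_id, clonotype_key, n_cells``: number
        of assigned cells per (patient, clonotype), pooled across timepoints
        unless built with ``per_sample=True`` (then a ``sample_id`` column is
        present and sizes are within sample).
    key_mode
        One of ``TRB_aa`` (default), ``TRB_nt``, ``TRA_TRB_aa``.
    n_cells_total, n_assigned
        Input cell count and number of cells that received a key.
    """

    per_cell: pd.DataFrame
    clone_sizes: pd.DataFrame
    key_mode: str
    n_cells_total: int
    n_assigned: int


def _best_chain(contigs: pd.DataFrame, chain: str, seq_col: str) -> pd.DataFrame:
    """Highest-UMI productive contig of ``chain`` per cell; UMI ties broken
    lexicographically on the sequence (smallest wins) for determinism."""
    sub = contigs[(contigs["chain"] == chain) & contigs["productive"]]
    sub = sub[sub[seq_col] != ""]
    if sub.empty:
        return pd.DataFrame(columns=["barcode", "sample_id", seq_col])
    sub = sub.sort_values(
        ["barcode", "sample_id", "umis", seq_col],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return sub.drop_duplicates(subset=["barcode", "sample_id"])[
        ["barcode", "sample_id", seq_col]
    ]


def assign_clonotypes(
    cells: pd.DataFrame,
    contigs: pd.DataFrame,
    key_mode: str = "TRB_aa",
    per_sample: bool = False,
) -> ClonotypeAssignment:
    """Assign each cell a clonotype key from its contigs.

    Under ``TRB_aa`` (default) the key is the CDR3 amino-acid sequence of the
    cell's productive TRB contig with the highest UMI count; ``TRB_nt`` uses
    the nucleotide CDR3 of that contig; ``TRA_TRB_aa`` joins the best TRA and
    TRB amino-acid CDR3s as ``"TRA|TRB"`` and requires both chains. Cells
    without the required productive chain(s) receive no key — a normal
    outcome that is counted and logged, never an error. Contigs whose
    barcode is absent from ``cells`` are ignored.
    """
    if key_mode not in KEY_MODES:
        raise ValueError(f"key_mode must be one of {KEY_MODES}, got {key_mode!r}")
    idx = cells[["barcode", "sample_id", "patient_id"]]
    contigs = contigs.merge(idx[["barcode", "sample_id"]], on=["barcode", "sample_id"])

    if key_mode == "TRB_aa":
        best = _best_chain(contigs, "TRB", "cdr3_aa").rename(columns={"cdr3_aa": "clonotype_key"})
    elif key_mode == "TRB_nt":
        best = _best_chain(contigs, "TRB", "cdr3_nt").rename(columns={"cdr3_nt": "clonotype_key"})
    else:  # TRA_TRB_aa
        tra = _best_chain(contigs, "TRA", "cdr3_aa").rename(columns={"cdr3_aa": "tra"})
        trb = _best_chain(contigs, "TRB", "cdr3_aa").rename(columns={"cdr3_aa": "trb"})
        best = tra.merge(trb, on=["barcode", "sample_id"])
        best["clonotype_key"] = best["tra"] + "|" + best["trb"]
        best = best[["barcode", "sample_id", "clonotype_key"]]

    per_cell = idx.merge(best, on=["barcode", "sample_id"])
    n_total, n_assigned = len(cells), len(per_cell)
    logger.info(
        "assign_clonotypes: %d/%d cells assigned under %s (%d without TCR)",
        n_assigned, n_total, key_mode, n_total - n_assigned,
    )

    size_keys = ["patient_id", "clonotype_key"] if not per_sample else [
        "patient_id", "sample_id", "clonotype_key"
    ]
    clone_sizes = (
        per_cell.groupby(size_keys, as_index=False).size().rename(columns={"size": "n_cells"})
    )
    return ClonotypeAssignment(
        per_cell=per_cell.reset_index(drop=True),
        clone_sizes=clone_sizes,
        key_mode=key_mode,
        n_cells_total=n_total,
        n_assigned=n_assigned,
    )


def is_clonal(assignment: ClonotypeAssignment, threshold: int = CLONAL_THRESHOLD) -> pd.Series:
    """Boolean per (patient_id, clonotype_key): clonal iff clone size is
    STRICTLY greater than ``threshold`` (default 3, i.e. >= 4 cells)."""
    if threshold < 1:
        raise ValueError(f"clonal threshold must be >= 1, got {threshold}")
    cs = assignment.clone_sizes
    if "sample_id" in cs.columns:  # pool per-sample sizes back to patient level
        cs = cs.groupby(["patient_id", "clonotype_key"], as_index=False)["n_cells"].sum()
    flags = cs.set_index(["patient_id", "clonotype_key"])["n_cells"] > threshold
    flags.name = "clonal"
    return flags


def clonality_report(
    cells: pd.DataFrame,
    assignment: ClonotypeAssignment,
    group_by: str = "subcluster",
    per: str = "sample",
    threshold: int = CLONAL_THRESHOLD,
) -> pd.DataFrame:
    """Percent clonal cells per (``group_by`` x sample-or-patient) group.

    ``pct_clonal = 100 * n_clonal_cells / n_assigned``; groups with zero
    assigned cells keep their row with ``pct_clonal`` as NA (undefined, not
    zero). ``group_by`` is ``subcluster`` or ``cell_type``; ``per`` is
    ``sample`` or ``patient``. Clonality of a cell follows its clonotype's
    patient-pooled size, so two clusters sharing a clone both count its
    cells as clonal.
    """
    if group_by not in cells.columns:
        raise ValueError(f"grouping column {group_by!r} absent from cell table")
    if per not in {"sample", "patient"}:
        raise ValueError(f"per must be 'sample' or 'patient', got {per!r}")
    unit = "sample_id" if per == "sample" else "patient_id"

    flags = is_clonal(assignment, threshold=threshold)
    pc = assignment.per_cell.merge(
        flags.reset_index(), on=["patient_id", "clonotype_key"], how="left"
    )
    merged = cells.merge(
        pc[["barcode", "sample_id", "clonotype_key", "clonal"]],
        on=["barcode", "sample_id"],
        how="left",
    )
    merged["assigned"] = merged["clonotype_key"].notna()
    merged["clonal"] = merged["clonal"].astype("boolean").fillna(False).astype(bool)

    keys = ["patient_id", unit, group_by] if unit != "patient_id" else ["patient_id", group_by]
    grp = merged.groupby(keys, dropna=False)
    rep = grp.agg(
        n_cells=("barcode", "size"),
        n_assigned=("assigned", "sum"),
        n_clonal_cells=("clonal", "sum"),
    ).reset_index()
    rep["pct_clonal"] = 100.0 * rep["n_clonal_cells"] / rep["n_assigned"].where(rep["n_assigned"] > 0)
    return rep
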