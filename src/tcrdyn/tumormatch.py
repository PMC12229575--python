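"""Tumor association of peripheral T-cell clusters by CDR3 overlap.

A peripheral cell is *tumor-matched* when its clonotype CDR3 also occurs in
the clonotype list assembled from its OWN patient's baseline tumor biopsy.
Matching is exact string equality on normalised (uppercased) amino-acid
CDR3s — the conservative reading of repertoire "overlap"; a Hamming-
distance-1 relaxed mode exists behind a flag, default off. Cross-patient
matching is never performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .clonotype import CLONAL_THRESHOLD, ClonotypeAssignment, is_clonal

logger = logging.getLogger(__name__)


@dataclass
class TumorRepertoire:
    """Distinct tumor CDR3s of one patient with summed clone weights."""

    patient_id: str
    cdr3_set: set[str]
    weights: dict[str, float] = field(default_factory=dict)


def build_tumor_repertoire(clones: pd.DataFrame, patient_id: str) -> TumorRepertoire:
    """Collapse a tumor clonotype table to a distinct-CDR3 set with summed weights.

    Duplicate CDR3s (convergent or re-called clones) are merged, their clone
    counts summed. An empty table yields an empty repertoire with a warning.
    """
    if clones.empty:
        logger.warning("build_tumor_repertoire(%s): empty clone table", patient_id)
        return TumorRepertoire(patient_id=patient_id, cdr3_set=set(), weights={})
    aa = clones["cdr3_aa"].str.strip().str.upper()
    weights = clones.assign(cdr3_aa=aa).groupby("cdr3_aa")["clone_count"].sum().to_dict()
    return TumorRepertoire(patient_id=patient_id, cdr3_set=set(weights), weights=weights)


def _hamming1_closure(cdr3_set: set[str]) -> set[str]:
    """All sequences within Hamming distance 1 of the set (same length only)."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    out = set(cdr3_set)
    for s in cdr3_set:
        for i in range(len(s)):
            for a in alphabet:
                out.add(s[:i] + a + s[i + 1 :])
    return out


def tumor_match_report(
    cells: pd.DataFrame,
    assignment: ClonotypeAssignment,
    repertoires: dict[str, TumorRepertoire],
    group_by: str = "subcluster",
    per: str = "sample",
    clonal_only: bool = False,
    clonal_threshold: int = CLONAL_THRESHOLD,
    hamming1: bool = False,
) -> pd.DataFrame:
    """Percent tumor-matched cells per (``group_by`` x sample-or-patient) group.

    A cell is matched iff its clonotype key is in its own patient's tumor
    CDR3 set (``pct_tumor_matched = 100 * matched / assigned``). Patients
    without a tumor repertoire are reported with NA percentages and flagged
    in the ``tumor_data`` column so they can be excluded from statistics.
    With ``clonal_only`` the match additionally requires the clonotype to be
    clonal. Requires ``assignment`` built in amino-acid mode when matching
    against amino-acid tumor exports.
    """
    if group_by not in cells.columns:
        raise ValueError(f"grouping column {group_by!r} absent from cell table")
    unit = "sample_id" if per == "sample" else "patient_id"
    if per not in {"sample", "patient"}:
        raise ValueError(f"per must be 'sample' or 'patient', got {per!r}")

    sets = {
        p: (_hamming1_closure(r.cdr3_set) if hamming1 else r.cdr3_set)
        for p, r in repertoires.items()
    }
    missing = sorted(set(cells["patient_id"]) - set(sets))
    if missing:
        logger.warning("tumor_match_report: no tumor repertoire for patient(s) %s", missing)

    pc = assignment.per_cell.copy()
    pc["matched"] = [
        key in sets.get(pat, frozenset())
        for pat, key in zip(pc["patient_id"], pc["clonotype_key"])
    ]
    if clonal_only:
        flags = is_clonal(assignment, threshold=clonal_threshold)
        clonal = flags.reindex(
            pd.MultiIndex.from_frame(pc[["patient_id", "clonotype_key"]])
        ).fillna(False).to_numpy()
        pc["matched"] &= clonal

    merged = cells.merge(
        pc[["barcode", "sample_id", "clonotype_key", "matched"]],
        on=["barcode", "sample_id"],
        how="left",
    )
    merged["assigned"] = merged["clonotype_key"].notna()
    merged["matched"] = merged["matched"].astype("boolean").fillna(False).astype(bool)

    keys = ["patient_id", unit, group_by] if unit != "patient_id" else ["patient_id", group_by]
    rep = (
        merged.groupby(keys, dropna=False)
        .agg(
            n_cells=("barcode", "size"),
            n_assigned=("assigned", "sum"),
            n_tumor_matched_cells=("matched", "sum"),
        )
        .reset_index()
    )
    rep["tumor_data"] = rep["patient_id"].isin(set(sets))
    pct = 100.0 * rep["n_tumor_matched_cells"] / rep["n_assigned"].where(rep["n_assigned"] > 0)
    rep["pct_tumor_matched"] = pct.where(rep["tumor_data"])
    return rep
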