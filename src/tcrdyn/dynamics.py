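"""Per-patient set algebra over clonal clonotypes across timepoints.

Each patient's clonal clonotypes (patient-pooled size above the clonal
threshold) form one set per sampled timepoint; the module partitions their
union by exact presence pattern (the Venn partition), derives longitudinal
sharing fractions (present in >= k timepoints), pairwise Jaccard overlap
and forward maintenance |A∩B|/|A|, and pools these per response group.

"Shared longitudinally" has no single canonical denominator, so every
candidate reading is computed and labelled: shared_ge_2/3/4 over the union
of clonal clonotypes, plus all pairwise metrics, per patient and pooled per
group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TIMEPOINTS
from .clonotype import ClonotypeAssignment

logger = logging.getLogger(__name__)


def clonal_sets_by_timepoint(
    cells: pd.DataFrame,
    assignment: ClonotypeAssignment,
    clonal_flags: pd.Series,
) -> dict[str, dict[str, set[str]]]:
    """Map patient -> timepoint -> set of clonal clonotype keys observed there.

    A clonotype enters a timepoint's set iff at least one cell bearing it is
    observed at that timepoint AND the clonotype is clonal (patient-pooled
    size above threshold, per ``clonal_flags`` from :func:`is_clonal`).
    Patients with fewer than 2 sampled timepoints are excluded with a
    warning — no sharing can be defined for them.
    """
    pc = assignment.per_cell.merge(
        cells[["barcode", "sample_id", "timepoint"]], on=["barcode", "sample_id"]
    )
    clonal = clonal_flags.reindex(
        pd.MultiIndex.from_frame(pc[["patient_id", "clonotype_key"]])
    ).fillna(False).to_numpy()
    pc = pc.loc[clonal]

    sampled = cells.groupby("patient_id")["timepoint"].agg(lambda s: set(s))
    out: dict[str, dict[str, set[str]]] = {}
    for patient, tps in sampled.items():
        if len(tps) < 2:
            logger.warning(
                "clonal_sets_by_timepoint: patient %s has <2 sampled timepoints; "
                "excluded from sharing statistics", patient,
            )
            continue
        sub = pc[pc["patient_id"] == patient]
        out[patient] = {
            tp: set(sub.loc[sub["timepoint"] == tp, "clonotype_key"])
            for tp in TIMEPOINTS
            if tp in tps
        }
    return out


@dataclass
class VennPartition:
    """Exact presence-pattern partition of one patient's clonal clonotypes.

    ``counts`` maps a presence pattern (frozenset of timepoints) to the
    number of distinct clonal clonotypes observed in exactly those
    timepoints. ``timepoints`` lists the patient's sampled timepoints in
    chronological order. Bucket counts always sum to ``n_union``.
    """

    patient_id: str
    timepoints: tuple[str, ...]
    counts: dict[frozenset[str], int]
    members: dict[frozenset[str], set[str]]

    @property
    def n_union(self) -> int:
        return sum(self.counts.values())

    def pattern_table(self) -> pd.DataFrame:
        """Patterns as bitstrings in timepoint order (e.g. "1011"), with counts."""
        rows = [
            {
                "patient_id": self.patient_id,
                "pattern": "".join("1" if tp in pat else "0" for tp in self.timepoints),
                "n_timepoints": len(pat),
                "count": c,
            }
            for pat, c in sorted(self.counts.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["patient_id", "pattern", "n_timepoints", "count"])


def venn_partition(sets: dict[str, set[str]], patient_id: str = "") -> VennPartition:
    """Partition the union of per-timepoint clonotype sets by presence pattern.

    Each clonotype is assigned to exactly one bucket — the frozenset of
    timepoints where it appears — by direct per-element enumeration, so the
    bucket counts sum to the union size by construction (asserted).
    Requires >= 2 timepoints.
    """
    if len(sets) < 2:
        raise ValueError(f"venn_partition requires >=2 timepoints, got {len(sets)}")
    order = tuple(tp for tp in TIMEPOINTS if tp in sets)
    if set(order) != set(sets):
        order = tuple(sets)  # non-standard labels: preserve insertion order
    union = set().union(*sets.values())
    members: dict[frozenset[str], set[str]] = {}
    for key in union:
        pat = frozenset(tp for tp in order if key in sets[tp])
        members.setdefault(pat, set()).add(key)
    counts = {pat: len(m) for pat, m in members.items()}
    assert sum(counts.values()) == len(union), "Venn partition failed conservation"
    return VennPartition(patient_id=patient_id, timepoints=order, counts=counts, members=members)


@dataclass
class SharingSummary:
    """Longitudinal sharing statistics for one patient.

    ``shared_ge`` maps k (2..#timepoints) to the percentage of the union of
    clonal clonotypes present in >= k sampled timepoints. ``pairwise`` has
    one row per ordered timepoint pair with Jaccard |A∩B|/|A∪B| and forward
    maintenance |A∩B|/|A| (both as percent). All fractions are NA when the
    union is empty.
    """

    patient_id: str
    n_union: int
    shared_ge: dict[int, float]
    pairwise: pd.DataFrame

    def to_row(self) -> dict:
        row = {"patient_id": self.patient_id, "n_union": self.n_union}
        for k, v in self.shared_ge.items():
            row[f"shared_ge_{k}_pct"] = v
        return row


def sharing_summary(partition: VennPartition) -> SharingSummary:
    """Derive sharing fractions and pairwise overlap metrics from a partition.

    k thresholds run over the patient's *sampled* timepoints (2..len), not
    the nominal 4, so missing samples are not penalised. Pairwise rows cover
    all chronologically ordered pairs; ``maintained_forward_pct`` is
    |A∩B|/|A| with A the earlier timepoint (NA when A is empty).
    """
    tps = partition.timepoints
    n_union = partition.n_union
    n_in_ge_k = {
        k: sum(c for pat, c in partition.counts.items() if len(pat) >= k)
        for k in range(2, len(tps) + 1)
    }
    shared_ge = {
        k: (100.0 * v / n_union if n_union else np.nan) for k, v in n_in_ge_k.items()
    }

    per_tp = {
        tp: set().union(*(m for pat, m in partition.members.items() if tp in pat), set())
        for tp in tps
    }
    rows = []
    for a, b in itertools.combinations(tps, 2):
        A, B = per_tp[a], per_tp[b]
        inter, uni = len(A & B), len(A | B)
        rows.append(
            {
                "patient_id": partition.patient_id,
                "timepoint_a": a,
                "timepoint_b": b,
                "n_a": len(A),
                "n_b": len(B),
                "n_intersection": inter,
                "jaccard_pct": 100.0 * inter / uni if uni else np.nan,
                "maintained_forward_pct": 100.0 * inter / len(A) if A else np.nan,
            }
        )
    pairwise = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "timepoint_a", "timepoint_b", "n_a", "n_b",
            "n_intersection", "jaccard_pct", "maintained_forward_pct",
        ],
    )
    return SharingSummary(
        patient_id=partition.patient_id, n_union=n_union, shared_ge=shared_ge, pairwise=pairwise
    )


def patient_sharing(
    sets_by_patient: dict[str, dict[str, set[str]]]
) -> tuple[dict[str, VennPartition], dict[str, SharingSummary]]:
    """Venn partition + sharing summary for every patient with >=2 timepoints."""
    partitions, summaries = {}, {}
    for patient, sets in sets_by_patient.items():
        part = venn_partition(sets, patient_id=patient)
        partitions[patient] = part
        summaries[patient] = sharing_summary(part)
    return partitions, summaries


def group_sharing(
    summaries: dict[str, SharingSummary],
    sets_by_patient: dict[str, dict[str, set[str]]],
    cells: pd.DataFrame,
) -> pd.DataFrame:
    """Per-response-group sharing statistics, per-patient mean AND pooled.

    The per-patient mean averages each patient's shared_ge_k / pairwise
    percentages within the group; the pooled variant merges all patients'
    unions and >= k members before dividing (clonotype keys namespaced per
    patient, since CDR3 identity across patients is not clonal identity).
    Both are emitted, labelled by the ``statistic`` column. Empty groups are
    omitted with a warning.
    """
    pat2resp = cells.drop_duplicates("patient_id").set_index("patient_id")["response"]
    rows = []
    for resp in pat2resp.unique():
        patients = [p for p in summaries if pat2resp.get(p) == resp]
        if not patients:
            logger.warning("group_sharing: group %s has no patients with sharing data", resp)
            continue
        ks = sorted({k for p in patients for k in summaries[p].shared_ge})
        # per-patient mean
        for k in ks:
            vals = [summaries[p].shared_ge[k] for p in patients if k in summaries[p].shared_ge]
            vals = [v for v in vals if np.isfinite(v)]
            rows.append(
                {
                    "response": resp, "statistic": "per_patient_mean", "metric": f"shared_ge_{k}",
                    "value_pct": float(np.mean(vals)) if vals else np.nan, "n_patients": len(patients),
                }
            )
        mf = [
            v
            for p in patients
            for v in summaries[p].pairwise["maintained_forward_pct"]
            if np.isfinite(v)
        ]
        rows.append(
            {
                "response": resp, "statistic": "per_patient_mean", "metric": "maintained_forward",
                "value_pct": float(np.mean(mf)) if mf else np.nan, "n_patients": len(patients),
            }
        )
        # pooled: namespace keys per patient, then treat the group as one repertoire
        pooled_counts: dict[int, int] = {}
        pooled_union = 0
        for p in patients:
            part = venn_partition(sets_by_patient[p], patient_id=p)
            pooled_union += part.n_union
            for pat, c in part.counts.items():
                pooled_counts[len(pat)] = pooled_counts.get(len(pat), 0) + c
        for k in ks:
            n_ge = sum(c for npts, c in pooled_counts.items() if npts >= k)
            rows.append(
                {
                    "response": resp, "statistic": "pooled", "metric": f"shared_ge_{k}",
                    "value_pct": 100.0 * n_ge / pooled_union if pooled_union else np.nan,
                    "n_patients": len(patients),
                }
            )
        inter = sum(
            summaries[p].pairwise["n_intersection"].sum() for p in patients
        )
        n_a = sum(summaries[p].pairwise["n_a"].sum() for p in patients)
        rows.append(
            {
                "response": resp, "statistic": "pooled", "metric": "maintained_forward",
                "value_pct": 100.0 * inter / n_a if n_a else np.nan, "n_patients": len(patients),
            }
        )
    return pd.DataFrame(rows, columns=["response", "statistic", "metric", "value_pct", "n_patients"])


def consecutive_maintenance(summaries: dict[str, SharingSummary]) -> pd.DataFrame:
    """Forward maintenance restricted to consecutive timepoint pairs.

    The natural estimator of a per-step clone persistence probability:
    |A∩B|/|A| for (baseline→post_chemo, post_chemo→post_ici,
    post_ici→endpoint), one row per patient and step.
    """
    order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    frames = []
    for s in summaries.values():
        pw = s.pairwise
        consec = pw[
            pw.apply(lambda r: order[r["timepoint_b"]] - order[r["timepoint_a"]] == 1, axis=1)
        ] if len(pw) else pw
        frames.append(consec)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
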