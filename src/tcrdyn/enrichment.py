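"""Pseudobulk aggregation, log-CPM normalisation and ssGSEA scoring.

ssGSEA (single-sample gene set enrichment analysis) scores one unit — a
pseudobulk sample or a single cell — at a time. Genes are ranked by
expression within the unit (average ranks on ties); walking the gene list
in descending-expression order, a running sum gains
``rank^alpha / sum_in_set(rank^alpha)`` at each in-set gene and loses
``1/(N - m)`` at each out-of-set gene (N genes total, m in the set); the
score is the sum of the running-sum values over all N steps (the integral
form). ``alpha`` defaults to 0.25 and the optional normalisation divides
the whole unit x set score matrix by its global max - min range, both
matching the common ssGSEA convention.

Because the score depends on expression only through within-unit ranks, it
is invariant to any strictly monotone per-unit transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io import CountsMatrix
from . import stats as _stats

logger = logging.getLogger(__name__)


@dataclass
class PseudobulkMatrix:
    """Gene x sample summed raw counts plus per-sample metadata.

    ``meta`` has one row per retained sample: ``sample_id, patient_id,
    timepoint, response, n_cells``.
    """

    genes: list[str]
    sample_ids: list[str]
    matrix: np.ndarray  # genes x samples, integer sums
    meta: pd.DataFrame


def aggregate_pseudobulk(
    counts: CountsMatrix,
    cells: pd.DataFrame,
    cell_filter: Callable[[pd.DataFrame], pd.Series] | str | None = None,
) -> PseudobulkMatrix:
    """Sum raw counts over cells within each sample (exact integer sums).

    ``cell_filter`` optionally restricts aggregation to a subset of cells
    before summing: either a cell-type name (shorthand for
    ``cell_type == name``) or a predicate mapping the cell table to a
    boolean mask. Samples left with zero passing cells are omitted with a
    warning. An empty barcode intersection between counts and cell table is
    an error.
    """
    key = counts.cells.merge(
        cells, on=["barcode", "sample_id"], how="left", indicator=True
    )
    matched = key["_merge"] == "both"
    if not matched.any():
        raise ValueError("no overlap between counts barcodes and cell table")
    if isinstance(cell_filter, str):
        name = cell_filter
        cell_filter = lambda df: df["cell_type"] == name  # noqa: E731
    keep = matched if cell_filter is None else (matched & cell_filter(key).fillna(False))

    key = key.loc[keep]
    col_idx = np.flatnonzero(keep.to_numpy())
    samples = sorted(key["sample_id"].unique())
    all_samples = sorted(cells["sample_id"].unique())
    dropped = set(all_samples) - set(samples)
    if dropped:
        logger.warning("aggregate_pseudobulk: sample(s) %s have 0 passing cells; omitted",
                       sorted(dropped))

    sample_pos = {s: i for i, s in enumerate(samples)}
    rows = col_idx
    cols = key["sample_id"].map(sample_pos).to_numpy()
    ind = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(counts.matrix.shape[1], len(samples))
    )
    pb = np.asarray((counts.matrix @ ind).todense()).astype(np.int64)

    meta = (
        key.groupby("sample_id")
        .agg(
            patient_id=("patient_id", "first"),
            timepoint=("timepoint", "first"),
            response=("response", "first"),
            n_cells=("barcode", "size"),
        )
        .reindex(samples)
        .reset_index()
    )
    return PseudobulkMatrix(genes=list(counts.genes), sample_ids=samples, matrix=pb, meta=meta)


def normalize_log_cpm(
    pb: PseudobulkMatrix | np.ndarray, pseudocount: float = 1.0
) -> pd.DataFrame | np.ndarray:
    """log2(1e6 * count / column_sum + pseudocount) per column.

    Accepts a :class:`PseudobulkMatrix` (returns a genes x samples
    DataFrame) or a raw 2-D array (returns an array). Zero column sums are
    an error — prevented upstream by sample omission.
    """
    if isinstance(pb, PseudobulkMatrix):
        mat = pb.matrix.astype(float)
    else:
        mat = np.asarray(pb, dtype=float)
    colsum = mat.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("normalize_log_cpm: zero column sum(s)")
    out = np.log2(1e6 * mat / colsum + pseudocount)
    if isinstance(pb, PseudobulkMatrix):
        return pd.DataFrame(out, index=pb.genes, columns=pb.sample_ids)
    return out


def normalize_log_cpm_cells(counts: CountsMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-cell log-CPM (dense genes x cells DataFrame) for per-cell ssGSEA."""
    mat = np.asarray(counts.matrix.todense(), dtype=float)
    colsum = mat.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("normalize_log_cpm_cells: cell(s) with zero total counts")
    out = np.log2(1e6 * mat / colsum + pseudocount)
    cols = counts.cells["barcode"] + "@" + counts.cells["sample_id"]
    return pd.DataFrame(out, index=counts.genes, columns=list(cols))


def ssgsea(
    expr: pd.DataFrame,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA scores for every unit (column of ``expr``) and gene set.

    ``expr`` is genes x units on any within-unit monotone scale (log-CPM,
    ranks, ...). Gene sets are intersected with the expression genes; empty
    intersections are skipped with a warning. With ``normalize`` the score
    matrix is rescaled by its global (max - min) range across all units and
    sets. Returns a units x sets DataFrame.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if expr.shape[0] < 2:
        raise ValueError("ssgsea needs >=2 genes")
    genes = list(expr.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)

    memberships = {}
    for name, gs in sets.items():
        idx = np.array([gene_pos[g] for g in gs if g in gene_pos], dtype=int)
        if idx.size == 0:
            logger.warning("ssgsea: set %s has no genes in the expression matrix; skipped", name)
            continue
        if idx.size == N:
            logger.warning("ssgsea: set %s covers every gene; out-of-set term vanishes", name)
        mask = np.zeros(N, dtype=bool)
        mask[idx] = True
        memberships[name] = mask
    if not memberships:
        raise ValueError("ssgsea: no gene set overlaps the expression matrix")

    X = expr.to_numpy(dtype=float)
    scores = np.zeros((X.shape[1], len(memberships)))
    for u in range(X.shape[1]):
        col = X[:, u]
        ranks = scipy.stats.rankdata(col)          # highest expression -> rank N
        order = np.argsort(-col, kind="stable")    # descending expression walk
        for s_i, (name, mask) in enumerate(memberships.items()):
            in_set = mask[order]
            w = ranks[order] ** alpha
            w[~in_set] = 0.0
            denom_in = w.sum()
            step = np.where(
                in_set,
                w / denom_in if denom_in > 0 else 0.0,
                -1.0 / (N - int(mask.sum())) if N > mask.sum() else 0.0,
            )
            scores[u, s_i] = np.cumsum(step).sum()
    out = pd.DataFrame(scores, index=list(expr.columns), columns=list(memberships))
    if normalize:
        rng = float(out.to_numpy().max() - out.to_numpy().min())
        if rng > 0:
            out = out / rng
    return out


def score_contrast(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    contrast_on: str = "timepoint",
    paired: bool = True,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Compare each gene set's scores between two conditions.

    ``scores`` is units x sets; ``meta`` maps each unit (matched on its
    index or a ``unit`` column equal to ``scores.index``) to ``patient_id``
    and the ``contrast_on`` column (``timepoint`` or ``response``).
    Paired contrasts pair within patient and drop patients missing either
    member (logged); fewer than 2 complete pairs skips the set with a
    warning. ``test`` is ``wilcoxon`` (signed-rank / rank-sum) or ``t``.
    Returns a tidy table (set, contrast, n, statistic, p, p_adj) with BH
    adjustment across sets.
    """
    if test not in {"wilcoxon", "t"}:
        raise ValueError(f"test must be 'wilcoxon' or 't', got {test!r}")
    a, b = contrast
    meta = meta.set_index("unit") if "unit" in meta.columns else meta
    meta = meta.reindex(scores.index)
    if meta[contrast_on].isna().all():
        raise ValueError(f"no unit has a {contrast_on!r} annotation")

    rows = []
    for set_name in scores.columns:
        vals = pd.DataFrame({"score": scores[set_name], **meta})
        if paired:
            va = vals[vals[contrast_on] == a].set_index("patient_id")["score"]
            vb = vals[vals[contrast_on] == b].set_index("patient_id")["score"]
            common = va.index.intersection(vb.index)
            missing = set(va.index).symmetric_difference(vb.index)
            if missing:
                logger.info("score_contrast(%s): patient(s) %s lack one member of %s; excluded",
                            set_name, sorted(missing), contrast)
            if len(common) < 2:
                logger.warning("score_contrast(%s): <2 complete pairs; skipped", set_name)
                continue
            x, y = va.loc[common].to_numpy(), vb.loc[common].to_numpy()
            res = paired_fn(x, y, test)
            rows.append({"set": set_name, "contrast": f"{a} vs {b}", "n": len(common),
                         "statistic": res.statistic, "p": res.p, "effect": res.effect})
        else:
            x = vals.loc[vals[contrast_on] == a, "score"].to_numpy()
            y = vals.loc[vals[contrast_on] == b, "score"].to_numpy()
            if len(x) < 2 or len(y) < 2:
                logger.warning("score_contrast(%s): <2 observations per arm; skipped", set_name)
                continue
            if test == "t":
                res = _stats.unpaired_t(x, y)
            else:
                u, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
                res = _stats.TestResult("rank_sum", n=len(x) + len(y), statistic=float(u),
                                        p=float(p), effect=float(np.median(x) - np.median(y)))
            rows.append({"set": set_name, "contrast": f"{a} vs {b}", "n": res.n,
                         "statistic": res.statistic, "p": res.p, "effect": res.effect})
    out = pd.DataFrame(rows, columns=["set", "contrast", "n", "statistic", "p", "effect"])
    if len(out):
        out["p_adj"] = _stats.bh_adjust(out["p"].to_numpy())
    else:
        out["p_adj"] = []
    return out


def paired_fn(x: np.ndarray, y: np.ndarray, test: str) -> _stats.TestResult:
    if test == "t":
        return _stats.paired_t(x, y)
    return _stats.paired_wilcoxon(x, y)
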