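"""Readers and writers for every external format the pipeline touches.

Formats
-------
* Cell annotation table (CSV/TSV): one row per cell with sample, patient,
  timepoint, response-group, cell-type and optional subcluster labels.
* Filtered contig table (CSV), following the 10x Cell Ranger VDJ
  ``filtered_contig_annotations.csv`` dialect: one row per assembled chain
  with CDR3 amino-acid/nucleotide sequences, productive flag and UMI count.
* Tumor clonotype export (TSV), following the MiXCR ``exportClones``
  dialect: one row per bulk-RNA-seq-derived clone with a clone count and
  CDR3 sequences. Column names are remappable because exports vary between
  MiXCR versions.
* Gene sets (GMT): ``name<TAB>description<TAB>gene1<TAB>...``.
* Gene x cell counts: MatrixMarket coordinate triplet plus ``genes.tsv``
  and ``barcodes.tsv`` sidecars (barcode TAB sample_id).

All validation is strict: closed enums for timepoint/response, integrity
checks on uniqueness and on MTX dimensions. Readers never mutate their
inputs; every dropped row is counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: The four sampling timepoints, in chronological order.
TIMEPOINTS = ("baseline", "post_chemo", "post_ici", "endpoint")

#: Response groups by residual cancer burden: RCB 0/I responders vs RCB II/III.
RESPONSES = ("RCB0_I", "RCB_II_III")

CHAINS = ("TRA", "TRB")

CELL_TABLE_COLUMNS = (
    "barcode",
    "sample_id",
    "patient_id",
    "timepoint",
    "response",
    "cell_type",
)


class FormatError(ValueError):
    """A file does not conform to its expected dialect (missing column, bad value)."""


class ValidationError(ValueError):
    """A parsed value falls outside a closed vocabulary or numeric domain."""


class IntegrityError(ValueError):
    """Internally inconsistent data (duplicates, dimension mismatches)."""


def _read_delim(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, **kwargs)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-cell annotation table.

    Returns a DataFrame with columns ``barcode, sample_id, patient_id,
    timepoint, response, cell_type, subcluster`` (``subcluster`` filled with
    NA when the file lacks it). Raises :class:`FormatError` for a missing
    required column, :class:`ValidationError` for out-of-vocabulary
    timepoint/response values, and :class:`IntegrityError` for duplicate
    ``(barcode, sample_id)`` pairs or a ``sample_id`` mapped to more than one
    ``(patient_id, timepoint)``.
    """
    df = _read_delim(path)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table {path}: missing required column(s) {missing}")
    if "subcluster" not in df.columns:
        df["subcluster"] = pd.NA
    df = df.loc[:, list(CELL_TABLE_COLUMNS) + ["subcluster"]].copy()
    df["subcluster"] = df["subcluster"].replace("", pd.NA)

    bad_tp = sorted(set(df["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise ValidationError(
            f"cell table {path}: unknown timepoint value(s) {bad_tp}; "
            f"allowed: {list(TIMEPOINTS)}"
        )
    bad_resp = sorted(set(df["response"]) - set(RESPONSES))
    if bad_resp:
        raise ValidationError(
            f"cell table {path}: unknown response value(s) {bad_resp}; "
            f"allowed: {list(RESPONSES)}"
        )
    dup = df.duplicated(subset=["barcode", "sample_id"])
    if dup.any():
        raise IntegrityError(
            f"cell table {path}: {int(dup.sum())} duplicate (barcode, sample_id) pair(s)"
        )
    samp = df.drop_duplicates(subset=["sample_id", "patient_id", "timepoint"])
    multi = samp["sample_id"].duplicated()
    if multi.any():
        bad = sorted(samp.loc[multi, "sample_id"])
        raise IntegrityError(
            f"cell table {path}: sample_id(s) {bad} map to more than one "
            "(patient_id, timepoint)"
        )
    return df.reset_index(drop=True)


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    cols = list(CELL_TABLE_COLUMNS) + ["subcluster"]
    df.loc[:, cols].to_csv(path, sep=sep, index=False)


CONTIG_COLUMNS = ("barcode", "sample_id", "chain", "cdr3_aa", "cdr3_nt", "productive", "umis")

_TRUE = {"true", "t", "1", "yes"}
_FALSE = {"false", "f", "0", "no", "none", ""}


def read_contigs(path: str | Path) -> pd.DataFrame:
    """Read a VDJ contig table; keep only TRA/TRB rows.

    Rows whose ``chain`` is outside {TRA, TRB} (e.g. IGH/IGK from ambient
    B cells, or "Multi") are dropped and the drop count is logged. Booleans
    accept True/true/TRUE. An unparseable ``umis`` value raises
    :class:`FormatError` naming the offending line (1-based, header = line 1).
    """
    df = _read_delim(path)
    missing = [c for c in CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contig table {path}: missing required column(s) {missing}")
    df = df.loc[:, list(CONTIG_COLUMNS)].copy()

    umis = pd.to_numeric(df["umis"], errors="coerce")
    bad = umis.isna() | (umis % 1 != 0)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +header +1-based
        raise FormatError(f"contig table {path}: unparseable umis value at line {line}")
    if (umis < 0).any():
        line = int(np.flatnonzero((umis < 0).to_numpy())[0]) + 2
        raise FormatError(f"contig table {path}: negative umis value at line {line}")
    df["umis"] = umis.astype(int)

    prod_norm = df["productive"].str.strip().str.lower()
    unknown = ~(prod_norm.isin(_TRUE) | prod_norm.isin(_FALSE))
    if unknown.any():
        line = int(np.flatnonzero(unknown.to_numpy())[0]) + 2
        raise FormatError(f"contig table {path}: unparseable productive flag at line {line}")
    df["productive"] = prod_norm.isin(_TRUE)

    keep = df["chain"].isin(CHAINS)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("read_contigs(%s): dropped %d non-TRA/TRB row(s)", path, n_drop)
    df = df.loc[keep].copy()
    # CDR3 comparisons are string equality downstream: normalise once, here.
    df["cdr3_aa"] = df["cdr3_aa"].str.strip().str.upper()
    df["cdr3_nt"] = df["cdr3_nt"].str.strip().str.upper()
    empty_prod = df["productive"] & (df["cdr3_aa"] == "")
    if empty_prod.any():
        raise ValidationError(
            f"contig table {path}: {int(empty_prod.sum())} productive row(s) with empty cdr3_aa"
        )
    return df.reset_index(drop=True)


def write_contigs(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(CONTIG_COLUMNS)].to_csv(path, index=False)


#: Default column-name aliases for MiXCR-style clone exports, by MiXCR vintage.
TUMOR_CLONE_ALIASES = {
    "clone_id": ("clone_id", "cloneId", "Clone ID"),
    "clone_count": ("clone_count", "cloneCount", "Clone count", "readCount"),
    "cdr3_aa": ("cdr3_aa", "aaSeqCDR3", "AA. Seq. CDR3", "aaSeqImputedCDR3"),
    "cdr3_nt": ("cdr3_nt", "nSeqCDR3", "N. Seq. CDR3", "targetSequences"),
}


def read_tumor_clones(
    path: str | Path, aliases: dict[str, tuple[str, ...]] | None = None
) -> pd.DataFrame:
    """Read a MiXCR-style tab-delimited tumor clonotype export.

    Requires (possibly aliased) clone-count and CDR3 amino-acid columns;
    clone id and CDR3 nucleotide columns are optional. CDR3s are uppercased
    and stripped. Duplicate CDR3s across clones are kept (collapse happens in
    :func:`tcrdyn.tumormatch.build_tumor_repertoire`). Zero usable rows is a
    warning, not an error: an empty tumor repertoire is a legal outcome.
    """
    aliases = {**TUMOR_CLONE_ALIASES, **(aliases or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def find(field: str) -> str | None:
        for cand in aliases[field]:
            if cand in df.columns:
                return cand
        return None

    count_col = find("clone_count")
    aa_col = find("cdr3_aa")
    if count_col is None or aa_col is None:
        need = [f for f, c in (("clone_count", count_col), ("cdr3_aa", aa_col)) if c is None]
        raise FormatError(
            f"tumor clone table {path}: no column found for {need} "
            f"(known aliases: {({f: aliases[f] for f in need})})"
        )
    out = pd.DataFrame(
        {
            "clone_count": pd.to_numeric(df[count_col], errors="coerce"),
            "cdr3_aa": df[aa_col].str.strip().str.upper(),
        }
    )
    id_col = find("clone_id")
    out["clone_id"] = (
        pd.to_numeric(df[id_col], errors="coerce").astype("Int64")
        if id_col is not None
        else pd.array(np.arange(len(df)), dtype="Int64")
    )
    nt_col = find("cdr3_nt")
    out["cdr3_nt"] = df[nt_col].str.strip().str.upper() if nt_col is not None else ""

    usable = out["clone_count"].notna() & (out["clone_count"] > 0) & (out["cdr3_aa"] != "")
    n_drop = int((~usable).sum())
    if n_drop:
        logger.info("read_tumor_clones(%s): dropped %d unusable row(s)", path, n_drop)
    out = out.loc[usable, ["clone_id", "clone_count", "cdr3_aa", "cdr3_nt"]].reset_index(drop=True)
    if out.empty:
        logger.warning("read_tumor_clones(%s): empty tumor repertoire", path)
    return out


def write_tumor_clones(df: pd.DataFrame, path: str | Path) -> None:
    out = df.rename(
        columns={
            "clone_id": "cloneId",
            "clone_count": "cloneCount",
            "cdr3_aa": "aaSeqCDR3",
            "cdr3_nt": "nSeqCDR3",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into ``{set name: [gene, ...]}``.

    Duplicate genes within a set are dropped (first kept) with a warning;
    a set with fewer than 2 distinct genes raises :class:`ValidationError`.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT {path}: line {ln} has fewer than 3 fields")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                logger.warning(
                    "read_gmt(%s): set %s: dropped %d duplicate gene(s)",
                    path, name, len(genes) - len(uniq),
                )
            if len(uniq) < 2:
                raise ValidationError(f"GMT {path}: set {name} has fewer than 2 genes")
            if name in sets:
                raise IntegrityError(f"GMT {path}: duplicate set name {name}")
            sets[name] = uniq
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


@dataclass
class CountsMatrix:
    """Sparse gene x cell raw counts with gene symbols and cell identities.

    ``cells`` has columns ``barcode, sample_id`` aligned to matrix columns.
    """

    genes: list[str]
    cells: pd.DataFrame
    matrix: sp.csc_matrix

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.genes), len(self.cells)):
            raise IntegrityError(
                f"counts matrix shape {self.matrix.shape} disagrees with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValidationError("counts matrix contains negative values")


def read_counts_mtx(directory: str | Path) -> CountsMatrix:
    """Read ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` from a directory.

    ``barcodes.tsv`` rows are ``barcode<TAB>sample_id``. The MTX dimension
    header must agree with the sidecar lengths (:class:`IntegrityError`
    otherwise).
    """
    directory = Path(directory)
    genes = [l.split("\t")[0] for l in (directory / "genes.tsv").read_text().splitlines() if l]
    rows = [l.split("\t") for l in (directory / "barcodes.tsv").read_text().splitlines() if l]
    for r in rows:
        if len(r) != 2:
            raise FormatError(f"{directory}/barcodes.tsv: expected 'barcode<TAB>sample_id' rows")
    cells = pd.DataFrame(rows, columns=["barcode", "sample_id"])
    mat = scipy.io.mmread(directory / "matrix.mtx")
    if mat.shape != (len(genes), len(cells)):
        raise IntegrityError(
            f"{directory}/matrix.mtx declares {mat.shape} but sidecars have "
            f"{len(genes)} genes and {len(cells)} barcodes"
        )
    mat = sp.csc_matrix(mat)
    if not np.issubdtype(mat.dtype, np.integer):
        if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
            raise ValidationError(f"{directory}/matrix.mtx: non-integer count values")
        mat = mat.astype(np.int64)
    return CountsMatrix(genes=genes, cells=cells, matrix=mat)


def write_counts_mtx(cm: CountsMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "genes.tsv").write_text("\n".join(cm.genes) + "\n")
    (directory / "barcodes.tsv").write_text(
        "\n".join(f"{b}\t{s}" for b, s in zip(cm.cells["barcode"], cm.cells["sample_id"])) + "\n"
    )
    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(cm.matrix))
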