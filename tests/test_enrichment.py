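import numpy as np
import pandas as pd
import pytest
import scipy.stats

from tcrdyn.enrichment import (
    aggregate_pseudobulk,
    normalize_log_cpm,
    normalize_log_cpm_cells,
    score_contrast,
    ssgsea,
)
from tcrdyn.io import CountsMatrix

import scipy.sparse as sp


def ssgsea_oracle(values: np.ndarray, genes: list, gene_set: set, alpha: float) -> float:
    """Direct loop computation of the ssGSEA running-sum integral."""
    ranks = scipy.stats.rankdata(values)
    order = sorted(range(len(genes)), key=lambda i: (-values[i], i))
    in_set = [genes[i] in gene_set for i in order]
    m = sum(in_set)
    N = len(genes)
    denom_in = sum(ranks[i] ** alpha for i in order if genes[i] in gene_set)
    running, total = 0.0, 0.0
    for pos, i in enumerate(order):
        if in_set[pos]:
            running += ranks[i] ** alpha / denom_in
        else:
            running -= 1.0 / (N - m)
        total += running
    return total


def toy_counts(matrix, genes=None, samples=("s1",), cells_per_sample=None):
    matrix = np.asarray(matrix)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    n = matrix.shape[1]
    barcodes = [f"b{i}" for i in range(n)]
    per = cells_per_sample or {s: n // len(samples) for s in samples}
    sample_ids = [s for s in samples for _ in range(per[s])]
    cells = pd.DataFrame({"barcode": barcodes, "sample_id": sample_ids})
    return CountsMatrix(genes=genes, cells=cells, matrix=sp.csc_matrix(matrix))


def cell_meta(cm, **cols):
    df = cm.cells.copy()
    for k, v in cols.items():
        df[k] = v
    return df


class TestPseudobulk:
    def test_exact_integer_sums(self):
        cm = toy_counts([[3, 4], [0, 2]])
        cells = cell_meta(cm, patient_id="P1", timepoint="baseline",
                          response="RCB0_I", cell_type="B")
        pb = aggregate_pseudobulk(cm, cells)
        assert pb.matrix[:, 0].tolist() == [7, 2]

    def test_cell_type_filter(self):
        cm = toy_counts([[3, 4]])
        cells = cell_meta(cm, patient_id="P1", timepoint="baseline", response="RCB0_I")
        cells["cell_type"] = ["B", "CD8_T"]
        pb = aggregate_pseudobulk(cm, cells, cell_filter="B")
        assert pb.matrix[0, 0] == 3
        assert pb.meta["n_cells"].iloc[0] == 1

    def test_empty_barcode_intersection_errors(self):
        cm = toy_counts([[1, 2]])
        cells = pd.DataFrame(
            {"barcode": ["zz"], "sample_id": ["s1"], "patient_id": ["P1"],
             "timepoint": ["baseline"], "response": ["RCB0_I"], "cell_type": ["B"]}
        )
        with pytest.raises(ValueError, match="no overlap"):
            aggregate_pseudobulk(cm, cells)

    def test_conserves_total_counts(self, small_cohort):
        pb = aggregate_pseudobulk(small_cohort.counts, small_cohort.cells)
        assert pb.matrix.sum() == small_cohort.counts.matrix.sum()

    def test_sample_with_no_passing_cells_omitted(self, caplog):
        cm = toy_counts([[1, 2]], samples=("s1", "s2"), cells_per_sample={"s1": 1, "s2": 1})
        cells = cell_meta(cm, patient_id="P1", response="RCB0_I")
        cells["timepoint"] = ["baseline", "post_chemo"]
        cells["cell_type"] = ["B", "CD8_T"]
        with caplog.at_level("WARNING"):
            pb = aggregate_pseudobulk(cm, cells, cell_filter="B")
        assert pb.sample_ids == ["s1"]
        assert "omitted" in caplog.text


class TestLogCpm:
    def test_closed_form_single_gene(self):
        out = normalize_log_cpm(np.array([[10.0]]))
        assert out[0, 0] == pytest.approx(np.log2(1e6 + 1))

    def test_all_zero_gene_maps_to_zero(self):
        out = normalize_log_cpm(np.array([[5.0], [0.0]]))
        assert out[1, 0] == 0.0

    def test_scale_invariance(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert normalize_log_cpm(2 * x) == pytest.approx(normalize_log_cpm(x))

    def test_zero_column_sum_errors(self):
        with pytest.raises(ValueError):
            normalize_log_cpm(np.array([[0.0], [0.0]]))


class TestSsgsea:
    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_direct_oracle(self, alpha):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n_genes = int(rng.integers(4, 11))
            genes = [f"g{i}" for i in range(n_genes)]
            expr = pd.DataFrame(
                rng.normal(size=(n_genes, 3)), index=genes,
                columns=["u1", "u2", "u3"],
            )
            m = int(rng.integers(1, n_genes))
            gene_set = set(rng.choice(genes, size=m, replace=False))
            scores = ssgsea(expr, {"S": sorted(gene_set)}, alpha=alpha, normalize=False)
            for u in expr.columns:
                exp = ssgsea_oracle(expr[u].to_numpy(), genes, gene_set, alpha)
                assert scores.loc[u, "S"] == pytest.approx(exp, abs=1e-12)

    def test_top2_alpha0_hand_value(self):
        # 4 genes, set = top-2 expressed, alpha=0: steps +1/2, +1/2, -1/2, -1/2
        # running sums 0.5, 1.0, 0.5, 0.0 -> integral 2.0
        expr = pd.DataFrame({"u": [4.0, 3.0, 2.0, 1.0]}, index=["a", "b", "c", "d"])
        s = ssgsea(expr, {"TOP2": ["a", "b"]}, alpha=0.0, normalize=False)
        assert s.loc["u", "TOP2"] == pytest.approx(2.0)

    def test_set_of_all_genes_closed_form(self):
        expr = pd.DataFrame({"u": [3.0, 2.0, 1.0]}, index=["a", "b", "c"])
        s = ssgsea(expr, {"ALL": ["a", "b", "c"]}, alpha=0.0, normalize=False)
        # steps of 1/3 each: running sums 1/3, 2/3, 1 -> 2.0
        assert s.loc["u", "ALL"] == pytest.approx(2.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            expr = pd.DataFrame(
                rng.normal(size=(15, 4)), index=[f"g{i}" for i in range(15)],
                columns=list("wxyz"),
            )
            sets = {"S1": ["g0", "g3", "g7"], "S2": ["g1", "g2", "g10", "g14"]}
            base = ssgsea(expr, sets, normalize=False)
            transformed = ssgsea(np.exp(expr * 2.0) + 5.0, sets, normalize=False)
            assert np.allclose(base.to_numpy(), transformed.to_numpy())

    def test_minmax_normalization_matrix_wide(self):
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(
            rng.normal(size=(12, 5)), index=[f"g{i}" for i in range(12)],
            columns=[f"u{i}" for i in range(5)],
        )
        sets = {"A": ["g0", "g1", "g2"], "B": ["g9", "g10", "g11"]}
        raw = ssgsea(expr, sets, normalize=False).to_numpy()
        norm = ssgsea(expr, sets, normalize=True).to_numpy()
        assert norm == pytest.approx(raw / (raw.max() - raw.min()))

    def test_empty_intersection_skipped_with_warning(self, caplog):
        expr = pd.DataFrame({"u": [1.0, 2.0]}, index=["a", "b"])
        with caplog.at_level("WARNING"):
            s = ssgsea(expr, {"GOOD": ["a", "b"], "GONE": ["zz", "ww"]}, normalize=False)
        assert list(s.columns) == ["GOOD"]
        assert "skipped" in caplog.text

    def test_negative_alpha_rejected(self):
        expr = pd.DataFrame({"u": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            ssgsea(expr, {"S": ["a", "b"]}, alpha=-0.5)


class TestScoreContrast:
    def _scores_meta(self, n_patients=6, delta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        units, rows, scores = [], [], []
        for i in range(n_patients):
            base = rng.normal()
            for tp, shift in (("baseline", 0.0), ("post_chemo", delta)):
                unit = f"P{i}_{tp}"
                units.append(unit)
                rows.append({"unit": unit, "patient_id": f"P{i}", "timepoint": tp})
                scores.append(base + shift + rng.normal(0, 1e-6))
        return (
            pd.DataFrame({"S": scores}, index=units),
            pd.DataFrame(rows),
        )

    def test_identical_scores_p_one(self):
        scores, meta = self._scores_meta(delta=0.0, seed=1)
        scores["S"] = 1.0
        res = score_contrast(scores, meta, ("baseline", "post_chemo"))
        assert res["p"].iloc[0] == 1.0

    def test_constant_shift_hits_exact_signed_rank_bound(self):
        scores, meta = self._scores_meta(n_patients=6, delta=0.7, seed=2)
        res = score_contrast(scores, meta, ("baseline", "post_chemo"))
        assert res["p"].iloc[0] == pytest.approx(2 / 2**6)

    def test_missing_member_excludes_patient(self, caplog):
        scores, meta = self._scores_meta(n_patients=5, delta=0.7, seed=3)
        scores = scores.drop(index="P0_post_chemo")
        meta = meta[meta["unit"] != "P0_post_chemo"]
        with caplog.at_level("INFO"):
            res = score_contrast(scores, meta, ("baseline", "post_chemo"))
        assert res["n"].iloc[0] == 4
        assert "excluded" in caplog.text

    def test_too_few_pairs_skipped(self, caplog):
        scores, meta = self._scores_meta(n_patients=1)
        with caplog.at_level("WARNING"):
            res = score_contrast(scores, meta, ("baseline", "post_chemo"))
        assert res.empty
        assert "skipped" in caplog.text

    def test_unpaired_t_mode(self):
        rng = np.random.default_rng(4)
        units = [f"c{i}" for i in range(40)]
        meta = pd.DataFrame(
            {"unit": units, "patient_id": "P1",
             "response": ["RCB0_I"] * 20 + ["RCB_II_III"] * 20}
        )
        scores = pd.DataFrame(
            {"S": np.concatenate([rng.normal(2, 0.1, 20), rng.normal(0, 0.1, 20)])},
            index=units,
        )
        res = score_contrast(scores, meta, ("RCB0_I", "RCB_II_III"),
                             contrast_on="response", paired=False, test="t")
        assert res["p"].iloc[0] < 1e-10
        assert res["effect"].iloc[0] == pytest.approx(2.0, abs=0.1)


def test_per_cell_log_cpm_shapes(small_cohort):
    sub_cells = small_cohort.counts.cells.iloc[:50]
    cm = CountsMatrix(
        genes=small_cohort.counts.genes,
        cells=sub_cells.reset_index(drop=True),
        matrix=small_cohort.counts.matrix[:, :50],
    )
    expr = normalize_log_cpm_cells(cm)
    assert expr.shape == (len(cm.genes), 50)
    assert np.isfinite(expr.to_numpy()).all()
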