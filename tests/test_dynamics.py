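import itertools

import numpy as np
import pandas as pd
import pytest

from tcrdyn.clonotype import assign_clonotypes, is_clonal
from tcrdyn.dynamics import (
    clonal_sets_by_timepoint,
    group_sharing,
    patient_sharing,
    sharing_summary,
    venn_partition,
)
from tcrdyn.io import TIMEPOINTS

from conftest import make_contigs


def oracle_partition(sets: dict[str, set]) -> dict[frozenset, int]:
    """Independent set-algebra oracle: for each subset S of timepoints,
    |(intersection over S) minus (union over complement of S)|."""
    tps = list(sets)
    out = {}
    for r in range(1, len(tps) + 1):
        for S in itertools.combinations(tps, r):
            inter = set.intersection(*(sets[t] for t in S))
            rest = set().union(*(sets[t] for t in tps if t not in S), set())
            n = len(inter - rest)
            if n:
                out[frozenset(S)] = n
    return out


def oracle_shared_ge(sets: dict[str, set], k: int) -> float:
    union = set().union(*sets.values())
    if not union:
        return np.nan
    n = sum(1 for e in union if sum(e in s for s in sets.values()) >= k)
    return 100.0 * n / len(union)


class TestVennPartition:
    def test_worked_example(self):
        sets = {"t1": {"A", "B"}, "t2": {"B"}, "t3": set(), "t4": {"A"}}
        part = venn_partition(sets)
        assert part.counts == {frozenset({"t1", "t4"}): 1, frozenset({"t1", "t2"}): 1}

    def test_identical_sets_single_bucket(self):
        s = {f"C{i}" for i in range(7)}
        part = venn_partition({tp: set(s) for tp in TIMEPOINTS})
        assert part.counts == {frozenset(TIMEPOINTS): 7}

    def test_disjoint_sets_only_singleton_buckets(self):
        sets = {"t1": {"A"}, "t2": {"B"}, "t3": {"C"}}
        part = venn_partition(sets)
        assert all(len(pat) == 1 for pat in part.counts)

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            venn_partition({"t1": {"A"}})

    def test_conservation_and_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_tp = rng.integers(2, 5)
            universe = [f"C{i}" for i in range(rng.integers(1, 51))]
            sets = {
                f"t{j}": set(rng.choice(universe, size=rng.integers(0, len(universe) + 1),
                                        replace=False))
                for j in range(n_tp)
            }
            if not any(sets.values()):
                continue
            part = venn_partition(sets)
            assert part.n_union == len(set().union(*sets.values()))
            assert part.counts == oracle_partition(sets)

    def test_pattern_table_bitstrings(self):
        sets = {"baseline": {"A"}, "post_chemo": {"A", "B"}, "post_ici": set(), "endpoint": {"A"}}
        tab = venn_partition(sets, "P1").pattern_table()
        assert set(tab["pattern"]) == {"1101", "0100"}


class TestSharingSummary:
    def test_worked_example(self):
        part = venn_partition({"t1": {"A", "B"}, "t2": {"B"}, "t3": set(), "t4": {"A"}})
        s = sharing_summary(part)
        assert s.n_union == 2
        assert s.shared_ge[2] == pytest.approx(100.0)
        assert s.shared_ge[3] == pytest.approx(0.0)

    def test_disjoint_gives_zero_sharing(self):
        s = sharing_summary(venn_partition({"t1": {"A"}, "t2": {"B"}}))
        assert s.shared_ge[2] == 0.0

    def test_jaccard_identity(self):
        s = sharing_summary(venn_partition({"t1": {"X", "Y"}, "t2": {"Y", "Z"}}))
        assert s.pairwise["jaccard_pct"].iloc[0] == pytest.approx(100 / 3)
        assert s.pairwise["maintained_forward_pct"].iloc[0] == pytest.approx(50.0)

    def test_empty_union_gives_na(self):
        s = sharing_summary(venn_partition({"t1": set(), "t2": set()}))
        assert all(np.isnan(v) for v in s.shared_ge.values())

    def test_shared_ge_non_increasing_in_k(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            universe = [f"C{i}" for i in range(30)]
            sets = {
                tp: set(rng.choice(universe, size=rng.integers(1, 31), replace=False))
                for tp in TIMEPOINTS
            }
            s = sharing_summary(venn_partition(sets))
            ks = sorted(s.shared_ge)
            for a, b in zip(ks[:-1], ks[1:]):
                assert s.shared_ge[b] <= s.shared_ge[a] + 1e-9

    def test_matches_per_element_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            universe = [f"C{i}" for i in range(rng.integers(1, 40))]
            sets = {
                tp: set(rng.choice(universe, size=rng.integers(0, len(universe) + 1),
                                   replace=False))
                for tp in TIMEPOINTS
            }
            if not any(sets.values()):
                continue
            s = sharing_summary(venn_partition(sets))
            for k in s.shared_ge:
                expected = oracle_shared_ge(sets, k)
                assert s.shared_ge[k] == pytest.approx(expected, nan_ok=True)

    def test_timepoint_label_equivariance(self):
        rng = np.random.default_rng(5)
        universe = [f"C{i}" for i in range(20)]
        base = {
            tp: set(rng.choice(universe, size=10, replace=False)) for tp in TIMEPOINTS
        }
        s1 = sharing_summary(venn_partition(base))
        # permute which label holds which set; pairwise metrics must follow
        perm = {TIMEPOINTS[i]: TIMEPOINTS[(i + 1) % 4] for i in range(4)}
        permuted = {perm[tp]: base[tp] for tp in TIMEPOINTS}
        s2 = sharing_summary(venn_partition(permuted))
        for _, row in s1.pairwise.iterrows():
            a2, b2 = perm[row["timepoint_a"]], perm[row["timepoint_b"]]
            m = s2.pairwise
            hit = m[
                ((m["timepoint_a"] == a2) & (m["timepoint_b"] == b2))
                | ((m["timepoint_a"] == b2) & (m["timepoint_b"] == a2))
            ]
            assert hit["jaccard_pct"].iloc[0] == pytest.approx(row["jaccard_pct"], nan_ok=True)
        assert s1.shared_ge == s2.shared_ge


class TestClonalSets:
    def _cohort(self):
        rows, contigs = [], []
        i = 0

        def add(tp, key, n):
            nonlocal i
            for _ in range(n):
                b = f"BC{i}"
                rows.append((b, f"P1_{tp}", "P1", tp, "RCB0_I", "CD8_T", "s"))
                contigs.append((b, f"P1_{tp}", "TRB", key, "TGT", True, 1))
                i += 1

        add("baseline", "CASSA", 3)
        add("post_ici", "CASSA", 2)   # pooled size 5 -> clonal
        add("baseline", "CASSB", 3)   # pooled size 3 -> not clonal
        cells = pd.DataFrame(
            rows,
            columns=["barcode", "sample_id", "patient_id", "timepoint", "response",
                     "cell_type", "subcluster"],
        )
        return cells, make_contigs(contigs)

    def test_pooled_clonal_clone_enters_both_timepoints(self):
        cells, contigs = self._cohort()
        a = assign_clonotypes(cells, contigs)
        sets = clonal_sets_by_timepoint(cells, a, is_clonal(a))
        assert sets["P1"]["baseline"] == {"CASSA"}
        assert sets["P1"]["post_ici"] == {"CASSA"}

    def test_single_timepoint_patient_excluded(self, caplog):
        rows = [("B0", "P2_baseline", "P2", "baseline", "RCB0_I", "CD8_T", "s")]
        cells = pd.DataFrame(
            rows,
            columns=["barcode", "sample_id", "patient_id", "timepoint", "response",
                     "cell_type", "subcluster"],
        )
        contigs = make_contigs([("B0", "P2_baseline", "TRB", "CASSA", "TGT", True, 1)])
        a = assign_clonotypes(cells, contigs)
        with caplog.at_level("WARNING"):
            sets = clonal_sets_by_timepoint(cells, a, is_clonal(a))
        assert "P2" not in sets
        assert "excluded" in caplog.text


class TestGroupSharing:
    def test_single_patient_group_pooled_equals_per_patient(self, small_cohort):
        cells = small_cohort.cells
        one = cells[cells["patient_id"] == "PT05"]  # first non-responder
        cd8 = one[one["cell_type"] == "CD8_T"]
        a = assign_clonotypes(cd8, small_cohort.contigs)
        sets = clonal_sets_by_timepoint(cd8, a, is_clonal(a))
        _, summaries = patient_sharing(sets)
        gs = group_sharing(summaries, sets, one)
        ge2 = gs[gs["metric"] == "shared_ge_2"].set_index("statistic")["value_pct"]
        assert ge2["pooled"] == pytest.approx(ge2["per_patient_mean"])

    def test_per_patient_mean_arithmetic(self):
        from tcrdyn.dynamics import SharingSummary

        pw = pd.DataFrame(
            columns=["patient_id", "timepoint_a", "timepoint_b", "n_a", "n_b",
                     "n_intersection", "jaccard_pct", "maintained_forward_pct"]
        )
        summaries = {
            "P1": SharingSummary("P1", 10, {2: 10.0}, pw),
            "P2": SharingSummary("P2", 10, {2: 20.0}, pw),
        }
        sets = {
            "P1": {"t1": {"A"}, "t2": {"A"}},
            "P2": {"t1": {"B"}, "t2": {"B"}},
        }
        cells = pd.DataFrame(
            {"patient_id": ["P1", "P2"], "response": ["RCB0_I", "RCB0_I"]}
        )
        gs = group_sharing(summaries, sets, cells)
        row = gs[(gs["metric"] == "shared_ge_2") & (gs["statistic"] == "per_patient_mean")]
        assert row["value_pct"].iloc[0] == pytest.approx(15.0)

    def test_configured_persistence_ordering_recovered(self, small_cohort):
        cells = small_cohort.cells
        cd8 = cells[cells["cell_type"] == "CD8_T"]
        a = assign_clonotypes(cd8, small_cohort.contigs)
        sets = clonal_sets_by_timepoint(cd8, a, is_clonal(a))
        _, summaries = patient_sharing(sets)
        gs = group_sharing(summaries, sets, cells)
        ge2 = gs[(gs["metric"] == "shared_ge_2") & (gs["statistic"] == "per_patient_mean")]
        vals = dict(zip(ge2["response"], ge2["value_pct"]))
        assert vals["RCB_II_III"] > vals["RCB0_I"]
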