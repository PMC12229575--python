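"""Statistical toolbox: exact paired Wilcoxon signed-rank, t tests,
ANOVA + Tukey HSD, Kruskal-Wallis + Dunn, BH adjustment, and per-gene
rank-sum differential expression with log-fold-change / adjusted-p
thresholds.

The paired signed-rank test computes its null distribution exactly (by
dynamic programming over the signed-rank sum, ties included) for up to 25
informative pairs, switching to the continuity-corrected normal
approximation with tie correction above. Zero differences are dropped
before ranking (the classic Wilcoxon convention); Pratt's
zeros-included ranking is available via ``zero_method="pratt"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXACT_MAX_PAIRS = 25


@dataclass
class TestResult:
    test_name: str
    n: int
    statistic: float
    p: float
    effect: float = np.nan
    adjusted_p: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "test": self.test_name,
            "n": self.n,
            "statistic": self.statistic,
            "p": self.p,
            "effect": self.effect,
            "p_adj": self.adjusted_p,
            "flags": ";".join(self.flags),
        }


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Exact PMF of the positive-rank sum over all 2^n sign assignments.

    Ranks are passed doubled so that average ranks from ties become
    integers; index i of the returned array is P(2*W+ == i).
    """
    total = int(doubled_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def paired_wilcoxon(
    x: np.ndarray,
    y: np.ndarray | None = None,
    zero_method: str = "wilcox",
) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    ``x`` may be the vector of paired differences, or the first member with
    ``y`` the second (differences ``x - y``). Exact enumeration (DP) for up
    to 25 informative pairs, continuity-corrected normal approximation with
    tie correction above. All-zero differences give p = 1 with a
    ``degenerate`` flag; a single informative pair is an error.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if zero_method not in {"wilcox", "pratt"}:
        raise ValueError(f"zero_method must be 'wilcox' or 'pratt', got {zero_method!r}")

    nonzero = d != 0
    if not nonzero.any():
        return TestResult("paired_wilcoxon", n=0, statistic=np.nan, p=1.0,
                          effect=0.0, flags=["degenerate"])
    if zero_method == "wilcox":
        d_used = d[nonzero]
    else:
        d_used = d
    n = int(np.count_nonzero(d_used))
    if n < 2:
        raise ValueError("paired_wilcoxon needs >=2 non-zero differences")

    ranks = scipy.stats.rankdata(np.abs(d_used))
    if zero_method == "pratt":
        # zeros are ranked but contribute to neither sum
        keep = d_used != 0
        ranks, d_used = ranks[keep], d_used[keep]
    w_plus = float(ranks[d_used > 0].sum())
    effect = float(np.median(d[nonzero]))

    if n <= EXACT_MAX_PAIRS:
        doubled = np.rint(2 * ranks).astype(int)
        pmf = _signed_rank_distribution(doubled)
        w2 = int(round(2 * w_plus))
        p_low = float(pmf[: w2 + 1].sum())
        p_high = float(pmf[w2:].sum())
        p = min(1.0, 2.0 * min(p_low, p_high))
        flags = ["exact"]
    else:
        mu = n * (n + 1) / 4.0
        tie_term = 0.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts**3 - counts).sum())) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        # continuity correction toward the mean
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
        p = float(2 * scipy.stats.norm.sf(abs(z)))
        flags = ["normal_approx"]
    return TestResult("paired_wilcoxon", n=n, statistic=w_plus, p=p, effect=effect, flags=flags)


def paired_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided paired t test; degenerate zero-variance cases flagged."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired_t requires equal-length vectors")
    if len(x) < 2:
        raise ValueError("paired_t needs >=2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d.mean(), 0):
            return TestResult("paired_t", n=len(d), statistic=np.nan, p=1.0,
                              effect=0.0, flags=["degenerate"])
        return TestResult("paired_t", n=len(d), statistic=np.inf * np.sign(d.mean()),
                          p=0.0, effect=float(d.mean()), flags=["zero_variance"])
    res = scipy.stats.ttest_rel(x, y)
    return TestResult("paired_t", n=len(d), statistic=float(res.statistic),
                      p=float(res.pvalue), effect=float(d.mean()))


def unpaired_t(x: np.ndarray, y: np.ndarray, equal_var: bool = False) -> TestResult:
    """Two-sided two-sample t test (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("unpaired_t needs >=2 observations per arm")
    eff = float(x.mean() - y.mean())
    if np.allclose(x.std(ddof=1), 0) and np.allclose(y.std(ddof=1), 0):
        if np.allclose(eff, 0):
            return TestResult("unpaired_t", n=len(x) + len(y), statistic=np.nan,
                              p=1.0, effect=0.0, flags=["degenerate"])
        return TestResult("unpaired_t", n=len(x) + len(y),
                          statistic=np.inf * np.sign(eff), p=0.0, effect=eff,
                          flags=["zero_variance"])
    res = scipy.stats.ttest_ind(x, y, equal_var=equal_var)
    return TestResult("unpaired_t", n=len(x) + len(y), statistic=float(res.statistic),
                      p=float(res.pvalue), effect=eff)


def _usable_groups(groups: dict[str, np.ndarray], min_n: int = 2) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < min_n:
            logger.warning("group %s has <%d observations; excluded", name, min_n)
            continue
        out[name] = vals
    if len(out) < 2:
        raise ValueError("need >=2 usable groups")
    return out


def anova_tukey(groups: dict[str, np.ndarray]) -> tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA omnibus plus Tukey HSD pairwise comparisons.

    Returns the omnibus F test and a table with one row per group pair and
    the studentized-range-adjusted p value. Groups with fewer than 2
    observations are excluded with a warning.
    """
    groups = _usable_groups(groups)
    names = list(groups)
    arrays = [groups[n] for n in names]
    n_total = sum(len(a) for a in arrays)
    if all(np.allclose(a.std(ddof=1), 0) for a in arrays) and np.allclose(
        np.std([a.mean() for a in arrays]), 0
    ):
        omni = TestResult("anova", n=n_total, statistic=0.0, p=1.0, flags=["degenerate"])
        rows = [
            {"group_a": a, "group_b": b, "mean_diff": 0.0, "p_adj": 1.0}
            for a, b in combinations(names, 2)
        ]
        return omni, pd.DataFrame(rows)
    f, p = scipy.stats.f_oneway(*arrays)
    omni = TestResult("anova", n=n_total, statistic=float(f), p=float(p))
    hsd = scipy.stats.tukey_hsd(*arrays)
    rows = []
    for i, j in combinations(range(len(names)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(hsd.pvalue[i, j]),
            }
        )
    return omni, pd.DataFrame(rows)


def kruskal_dunn(groups: dict[str, np.ndarray]) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis omnibus plus Dunn's post hoc z tests (tie-corrected),
    with BH adjustment across the pairwise family."""
    groups = _usable_groups(groups)
    names = list(groups)
    arrays = [groups[n] for n in names]
    n_total = sum(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        omni = TestResult("kruskal", n=n_total, statistic=0.0, p=1.0, flags=["degenerate"])
        rows = [
            {"group_a": a, "group_b": b, "z": 0.0, "p": 1.0, "p_adj": 1.0}
            for a, b in combinations(names, 2)
        ]
        return omni, pd.DataFrame(rows)
    h, p = scipy.stats.kruskal(*arrays)
    omni = TestResult("kruskal", n=n_total, statistic=float(h), p=float(p))

    ranks = scipy.stats.rankdata(pooled)
    N = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float((counts**3 - counts).sum())
    # Dunn's pooled variance term with tie correction
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + len(a)].mean())
        sizes.append(len(a))
        start += len(a)
    rows = []
    for i, j in combinations(range(len(names)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append(
            {"group_a": names[i], "group_b": names[j], "z": float(z),
             "p": float(2 * scipy.stats.norm.sf(abs(z)))}
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return omni, table


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, capped at 1."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def de_rank_sum(
    expr_by_cell: pd.DataFrame,
    group_labels: np.ndarray,
    lfc_threshold: float = 0.5,
    padj_threshold: float = 1e-5,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum differential expression.

    ``expr_by_cell`` is a genes x cells DataFrame of normalised expression;
    ``group_labels`` holds exactly two labels over the cell axis. The
    log2 fold change is ``log2((mean_a + c)/(mean_b + c))`` with a tiny
    pseudocount ``c``; genes are pre-filtered to ``|log2FC| >=
    lfc_threshold`` before testing (the convention of marker-finding tools:
    the threshold gates which genes are tested, and BH adjustment runs over
    the tested family only). ``passes`` requires both ``|log2FC| >=
    lfc_threshold`` and ``p_adj <= padj_threshold``. Untested genes carry NA
    p values.
    """
    labels = pd.unique(np.asarray(group_labels))
    if len(labels) != 2:
        raise ValueError(f"de_rank_sum requires exactly 2 groups, got {list(labels)}")
    mask_a = np.asarray(group_labels) == labels[0]
    mask_b = np.asarray(group_labels) == labels[1]
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must contain at least one cell")

    X = expr_by_cell.to_numpy(dtype=float)
    mean_a = X[:, mask_a].mean(axis=1)
    mean_b = X[:, mask_b].mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    tested = np.abs(lfc) >= lfc_threshold
    pvals = np.full(len(lfc), np.nan)
    if tested.any():
        res = scipy.stats.mannwhitneyu(
            X[np.ix_(tested, mask_a)], X[np.ix_(tested, mask_b)],
            alternative="two-sided", axis=1,
        )
        pvals[tested] = res.pvalue
    padj = np.full(len(lfc), np.nan)
    if tested.any():
        padj[tested] = bh_adjust(pvals[tested])

    out = pd.DataFrame(
        {
            "gene": expr_by_cell.index,
            "log2_fold_change": lfc,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "tested": tested,
            "p": pvals,
            "p_adj": padj,
        }
    ).set_index("gene")
    out["passes"] = tested & (out["p_adj"] <= padj_threshold)
    return out
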