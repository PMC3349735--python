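"""Association statistics shared across the binding-mode pipeline.

2x2 contingency tests (Pearson chi-square without continuity correction, and
Fisher's exact test), the Monte-Carlo gene-list overlap z-score computed
against 10,000 random background lists, and hypergeometric gene-set
enrichment over user-supplied GMT gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyResult",
    "OverlapZResult",
    "chisq_2x2",
    "fisher_exact_2x2",
    "test_2x2",
    "list_overlap_z",
    "hypergeom_enrichment",
    "cluster_category_enrichment",
    "read_gmt",
    "write_gmt",
]

Table2x2 = tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class ContingencyResult:
    """Outcome of a 2x2 test: ((a,b),(c,d)) with rows = groups, cols = feature."""

    table: Table2x2
    statistic: float | None
    p: float
    test_used: str
    odds_ratio: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class OverlapZResult:
    """Monte-Carlo z-score for the overlap of two gene lists within a universe."""

    observed: int
    bg_mean: float
    bg_sd: float
    z: float
    n_background: int
    universe_size: int
    size_a: int
    size_b: int
    degenerate: bool = False


def _check_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValueError("table entries must be non-negative integers")
        arr = arr.astype(int)
    if arr.sum() == 0:
        raise ValueError("table has no observations")
    return arr


def _odds_ratio(arr: np.ndarray) -> float:
    a, b = arr[0]
    c, d = arr[1]
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def chisq_2x2(table, continuity_correction: bool = False) -> ContingencyResult:
    """Pearson chi-square test (df = 1) on a 2x2 table.

    No continuity correction by default. Raises if any row or column margin is
    zero (the test is undefined there — use Fisher's exact test instead).
    """
    arr = _check_table(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-square undefined for zero row/column margin")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=continuity_correction)
    return ContingencyResult(
        table=tuple(map(tuple, arr.tolist())),
        statistic=float(stat),
        p=float(p),
        test_used="chisq",
        odds_ratio=_odds_ratio(arr),
    )


def fisher_exact_2x2(table) -> ContingencyResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums all hypergeometric outcomes (at fixed margins) whose
    probability does not exceed that of the observed table. Zero cells and
    zero margins are allowed (a degenerate table gives p = 1).
    """
    arr = _check_table(table)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return ContingencyResult(
        table=tuple(map(tuple, arr.tolist())),
        statistic=None,
        p=float(p),
        test_used="fisher",
        odds_ratio=_odds_ratio(arr),
    )


def test_2x2(table, expected_min: float = 5.0) -> ContingencyResult:
    """Chi-square test, falling back to Fisher's exact when counts are small.

    Fisher is used when any expected cell count is below ``expected_min`` or
    when a margin is zero; the choice is recorded in ``test_used``.
    """
    arr = _check_table(table)
    rows = arr.sum(axis=1, keepdims=True)
    cols = arr.sum(axis=0, keepdims=True)
    if np.any(rows == 0) or np.any(cols == 0):
        return fisher_exact_2x2(arr)
    expected = rows * cols / arr.sum()
    if np.any(expected < expected_min):
        return fisher_exact_2x2(arr)
    return chisq_2x2(arr)


def list_overlap_z(
    list_a, list_b, universe, n_background: int = 10_000, seed: int = 0
) -> OverlapZResult:
    """Monte-Carlo z-score for |A ∩ B| against random same-size background lists.

    ``n_background`` lists of size |B| are sampled uniformly without
    replacement from the universe; the z-score is (observed − mean) / sd of
    their overlaps with A. If the background sd is zero (e.g. B equals the
    universe) the result is flagged degenerate and z is NaN.
    """
    universe = sorted(set(universe))
    set_a, set_b = set(list_a), set(list_b)
    if not set_a <= set(universe) or not set_b <= set(universe):
        raise ValueError("both lists must be subsets of the universe")
    n = len(universe)
    size_b = len(set_b)
    observed = len(set_a & set_b)

    in_a = np.array([g in set_a for g in universe])
    rng = np.random.default_rng(seed)
    overlaps = np.empty(n_background, dtype=int)
    for k in range(n_background):
        idx = rng.choice(n, size=size_b, replace=False)
        overlaps[k] = int(in_a[idx].sum())
    mean = float(overlaps.mean())
    sd = float(overlaps.std(ddof=1))
    degenerate = sd == 0.0
    z = float("nan") if degenerate else (observed - mean) / sd
    if degenerate:
        log.warning("overlap z degenerate: background sd is zero")
    return OverlapZResult(
        observed=observed, bg_mean=mean, bg_sd=sd, z=z,
        n_background=n_background, universe_size=n,
        size_a=len(set_a), size_b=size_b, degenerate=degenerate,
    )


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (term, description, member genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")


def hypergeom_enrichment(gene_list, gene_sets: dict[str, set[str]], universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list in each gene set.

    Per term: P(overlap >= observed) under random draws of |list| genes from
    the universe. Terms entirely outside the universe are skipped. Returns a
    DataFrame sorted by p, with raw p, -log10 p, and a BH-adjusted column.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if not gene_list <= universe:
        raise ValueError("gene list must be a subset of the universe")
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    n_univ = len(universe)
    n_list = len(gene_list)
    rows = []
    for term, members in gene_sets.items():
        members_in = members & universe
        if not members_in:
            log.info("term %s entirely outside universe, skipped", term)
            continue
        k = len(gene_list & members_in)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members_in), n_list))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append({
            "term": term,
            "overlap": k,
            "term_size": len(members_in),
            "list_size": n_list,
            "universe_size": n_univ,
            "p": p,
            "neg_log10_p": -np.log10(p),
        })
    df = pd.DataFrame(rows).sort_values(["p", "term"]).reset_index(drop=True)
    df["q_bh"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def cluster_category_enrichment(
    assignment: dict[str, int], category_sets: dict[str, set[str]],
    ratio_threshold: float = 1.0, small_category: int = 5,
) -> pd.DataFrame:
    """Per-category test of uneven spread across expression clusters.

    For each category: compute each cluster's enrichment ratio
    observed/expected for category members, partition clusters at ratio >
    ``ratio_threshold``, and test category membership against that partition
    in a 2x2 (chi-square, or Fisher for categories smaller than
    ``small_category`` genes).
    """
    genes = list(assignment)
    clusters = sorted(set(assignment.values()))
    cluster_sizes = {c: sum(1 for g in genes if assignment[g] == c) for c in clusters}
    n_total = len(genes)
    rows = []
    for cat, members in category_sets.items():
        members_in = members & set(genes)
        n_cat = len(members_in)
        if n_cat == 0:
            continue
        ratios = {}
        for c in clusters:
            obs = sum(1 for g in members_in if assignment[g] == c)
            expected = cluster_sizes[c] * n_cat / n_total
            ratios[c] = obs / expected if expected > 0 else float("nan")
        enriched = {c for c, r in ratios.items() if r > ratio_threshold}
        in_enriched_cat = sum(1 for g in members_in if assignment[g] in enriched)
        in_enriched_not = sum(
            1 for g in genes if assignment[g] in enriched and g not in members_in
        )
        table = (
            (in_enriched_cat, n_cat - in_enriched_cat),
            (in_enriched_not, (n_total - n_cat) - in_enriched_not),
        )
        if n_cat < small_category:
            res = fisher_exact_2x2(table)
        else:
            res = test_2x2(table)
        rows.append({
            "category": cat,
            "n_genes": n_cat,
            "enriched_clusters": sorted(enriched),
            "ratios": ratios,
            "p": res.p,
            "test_used": res.test_used,
        })
    return pd.DataFrame(rows)
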