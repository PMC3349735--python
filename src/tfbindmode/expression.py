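"""Probeset-to-gene expression analysis for the 2x2 knockdown-by-stimulus design.

The design crosses siRNA treatment (control vs knockdown of the focal factor)
with growth-factor stimulus (0 vs 30 min), with replicate batches pairing
samples across conditions. The stages here mirror the analysis conventions of
two-colour-era microarray work on log10-scale signals:

* probeset filtering/collapsing to one probeset per gene,
* batch-paired t-tests per contrast with Benjamini-Hochberg adjustment
  (a transparent stand-in for moderated-t/empirical-Bayes pipelines,
  recorded as such in output metadata),
* z-transformation of the four condition means per gene,
* k-means clustering (k = 8) with hierarchical display ordering,
* contingency tests linking clusters and regulation direction to the
  unique/redundant binding mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .assoc import ContingencyResult, test_2x2

log = logging.getLogger(__name__)

__all__ = [
    "CONDITIONS",
    "CONTRASTS",
    "ClusterAssignment",
    "collapse_probesets",
    "differential_response",
    "filter_regulated",
    "z_transform_profiles",
    "kmeans_cluster",
    "cluster_mode_association",
    "direction_mode_split",
]

#: The four experimental conditions in canonical display order.
CONDITIONS = [
    ("control_kd", 0),
    ("control_kd", 30),
    ("focal_kd", 0),
    ("focal_kd", 30),
]
CONDITION_LABELS = [f"{t}_{s}min" for t, s in CONDITIONS]

#: Supported contrasts: knockdown effect at each stimulus time, and the
#: stimulus effect itself in control cells. Each is (minuend, subtrahend).
CONTRASTS = {
    "kd_0": (("focal_kd", 0), ("control_kd", 0)),
    "kd_30": (("focal_kd", 30), ("control_kd", 30)),
    "egf": (("control_kd", 30), ("control_kd", 0)),
}


def _check_design(design: pd.DataFrame) -> pd.DataFrame:
    required = {"treatment", "stimulus", "batch"}
    if not required <= set(design.columns):
        raise ValueError(f"design must have columns {sorted(required)}")
    counts = design.groupby(["treatment", "stimulus"]).size()
    if (counts < 2).any():
        raise ValueError("every (treatment, stimulus) cell needs >= 2 replicates")
    return design


def _cell_means(matrix: pd.DataFrame, design: pd.DataFrame,
                treatment: str, stimulus: int) -> pd.DataFrame:
    """Per-batch means of all samples in one (treatment, stimulus) cell."""
    mask = (design["treatment"] == treatment) & (design["stimulus"] == stimulus)
    sub = design.loc[mask]
    cols = {}
    for batch, rows in sub.groupby("batch"):
        cols[batch] = matrix[rows.index.tolist()].mean(axis=1)
    return pd.DataFrame(cols).sort_index(axis=1)


#: Contrast vectors over the four conditions in CONDITIONS order.
CONTRAST_VECTORS = {
    "kd_0": np.array([-1.0, 0.0, 1.0, 0.0]),
    "kd_30": np.array([0.0, -1.0, 0.0, 1.0]),
    "egf": np.array([-1.0, 1.0, 0.0, 0.0]),
    "kd_pooled": np.array([-0.5, -0.5, 0.5, 0.5]),
}


def _condition_cube(matrix: pd.DataFrame, design: pd.DataFrame) -> np.ndarray:
    """genes x conditions x batches array of batch/cell means."""
    frames = [_cell_means(matrix, design, t, s) for (t, s) in CONDITIONS]
    batches = frames[0].columns
    for f in frames[1:]:
        batches = batches.intersection(f.columns)
    if len(batches) < 2:
        raise ValueError("need >= 2 batches shared by all four conditions")
    return np.stack([f[batches].to_numpy() for f in frames], axis=1)


def _anova_contrast_stats(matrix: pd.DataFrame, design: pd.DataFrame,
                          contrast: np.ndarray) -> pd.DataFrame:
    """Per-gene contrast t-test from the two-factor model with batch pairing.

    Fits, per gene, the additive condition + batch model on the cell/batch
    means; the residual mean square (df = (conditions-1)(batches-1) = 6 for
    three batches) is the error term for every contrast. Genes with zero
    residual variance get p = NaN and are flagged downstream.
    """
    X = _condition_cube(matrix, design)          # genes x 4 x B
    n_genes, n_cond, n_batch = X.shape
    cond_mean = X.mean(axis=2, keepdims=True)
    batch_mean = X.mean(axis=1, keepdims=True)
    grand = X.mean(axis=(1, 2), keepdims=True)
    resid = X - cond_mean - batch_mean + grand
    df = (n_cond - 1) * (n_batch - 1)
    ss = (resid ** 2).sum(axis=(1, 2))
    effect = (cond_mean[:, :, 0] * contrast).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ss / df * (contrast ** 2).sum() / n_batch)
        t = effect / se
    p = 2 * stats.t.sf(np.abs(t), df=df)
    p = np.where(ss == 0, np.nan, p)
    return pd.DataFrame(
        {"effect": effect, "t": np.where(ss == 0, np.nan, t), "p": p,
         "n_batches": n_batch, "df": df},
        index=matrix.index,
    )


def collapse_probesets(
    matrix: pd.DataFrame,
    probe_map: dict[str, str],
    design: pd.DataFrame,
    background_level: float | None = None,
    p_changed: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse a probeset-level matrix to one probeset per gene.

    Three rules, in order:

    1. probesets whose mean signal in the stimulated control samples is at or
       below ``background_level`` are discarded (default level: the 2.5th
       percentile of all signals in the matrix);
    2. genes whose significantly changed probesets (knockdown contrast pooled
       over stimulus, paired p < ``p_changed``) disagree in direction are
       excluded entirely;
    3. of a gene's remaining probesets, only the one with the largest
       absolute knockdown effect is retained.

    Returns the gene-level matrix (indexed by gene, same sample columns) and
    an exclusion log recording the rule applied to every dropped probeset.
    """
    design = _check_design(design)
    missing = set(matrix.index) - set(probe_map)
    if missing:
        raise ValueError(f"probe_map missing {len(missing)} probesets, e.g. {sorted(missing)[:3]}")
    if background_level is None:
        background_level = float(np.percentile(matrix.to_numpy(), 2.5))
        log.info("background level defaulted to 2.5th percentile = %.4f", background_level)

    exclusions = []

    ctrl_egf = design[(design["treatment"] == "control_kd") & (design["stimulus"] == 30)]
    ctrl_mean = matrix[ctrl_egf.index.tolist()].mean(axis=1)
    below = ctrl_mean <= background_level
    for ps in matrix.index[below]:
        exclusions.append({"probeset": ps, "gene": probe_map[ps], "rule": "below_background"})
    kept = matrix.loc[~below]

    ps_stats = _anova_contrast_stats(kept, design, CONTRAST_VECTORS["kd_pooled"])

    by_gene: dict[str, list[str]] = {}
    for ps in kept.index:
        by_gene.setdefault(probe_map[ps], []).append(ps)

    chosen = {}
    for gene, probesets in by_gene.items():
        sub = ps_stats.loc[probesets]
        changed = sub[(sub["p"] < p_changed) & sub["p"].notna()]
        signs = set(np.sign(changed["effect"]).astype(int)) - {0}
        if len(signs) > 1:
            for ps in probesets:
                exclusions.append({"probeset": ps, "gene": gene, "rule": "opposite_directions"})
            continue
        best = sub["effect"].abs().sort_values(ascending=False, kind="stable")
        # tie-break deterministically on probeset id
        top = sorted(best[best == best.iloc[0]].index)[0]
        for ps in probesets:
            if ps != top:
                exclusions.append({"probeset": ps, "gene": gene, "rule": "not_largest_change"})
        chosen[gene] = top

    gene_matrix = kept.loc[[chosen[g] for g in sorted(chosen)]].copy()
    gene_matrix.index = pd.Index(sorted(chosen), name="gene")
    log_df = pd.DataFrame(exclusions, columns=["probeset", "gene", "rule"])
    return gene_matrix, log_df


def differential_response(
    gene_matrix: pd.DataFrame, design: pd.DataFrame, contrast: str
) -> pd.DataFrame:
    """Batch-paired differential response per gene for one contrast.

    Effect is the mean paired log10 difference for the requested contrast; p
    from the contrast t-test of a two-factor (condition + batch) model fitted
    per gene, whose residual mean square is the shared error term
    (df = 6 with three batches). q by Benjamini-Hochberg across genes
    (stand-in for a q-value procedure). Genes with undefined p (zero residual
    variance) are flagged ``excluded`` and ignored by the BH adjustment.
    """
    if contrast not in CONTRASTS:
        raise KeyError(f"unknown contrast {contrast!r}; expected one of {sorted(CONTRASTS)}")
    design = _check_design(design)
    res = _anova_contrast_stats(gene_matrix, design, CONTRAST_VECTORS[contrast])
    out = pd.DataFrame({
        "gene": gene_matrix.index,
        "contrast": contrast,
        "effect": res["effect"].to_numpy(),
        "p": res["p"].to_numpy(),
    })
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
    out["direction"] = np.where(out["effect"] > 0, "up",
                                np.where(out["effect"] < 0, "down", "none"))
    out["excluded"] = ~ok | (out["direction"] == "none")
    return out


def filter_regulated(
    results: pd.DataFrame, p_max: float = 0.05, q_max: float = 0.1
) -> dict[str, list[str]]:
    """Regulated genes per direction: p < p_max and q < q_max, split up/down."""
    sig = results[
        (results["p"] < p_max) & (results["q"] < q_max) & (~results["excluded"])
    ]
    return {
        "up": sorted(sig.loc[sig["direction"] == "up", "gene"]),
        "down": sorted(sig.loc[sig["direction"] == "down", "gene"]),
    }


def z_transform_profiles(gene_matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores of the four condition means.

    Each gene's four condition means (replicates averaged) are centred on
    their mean and scaled by their sample (n-1) standard deviation, so the
    displayed profile is relative to the gene's average level across all
    conditions. Genes with identical means in all four conditions are
    excluded (zero sd) and logged.
    """
    design = _check_design(design)
    cols = {}
    for (t, s), label in zip(CONDITIONS, CONDITION_LABELS):
        mask = (design["treatment"] == t) & (design["stimulus"] == s)
        cols[label] = gene_matrix[design.index[mask].tolist()].mean(axis=1)
    means = pd.DataFrame(cols)
    sd = means.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        log.info("excluding %d flat profiles from z-transform", int(flat.sum()))
    means = means.loc[~flat]
    z = means.sub(means.mean(axis=1), axis=0).div(sd[~flat], axis=0)
    z.index.name = "gene"
    return z


@dataclass
class ClusterAssignment:
    """k-means result with display-ordered cluster labels (1..k)."""

    labels: dict[str, int]
    means: pd.DataFrame
    inertia: float
    k: int = field(default=8)

    def members(self, cluster: int) -> list[str]:
        return sorted(g for g, c in self.labels.items() if c == cluster)

    def sizes(self) -> dict[int, int]:
        out = {c: 0 for c in range(1, self.k + 1)}
        for c in self.labels.values():
            out[c] += 1
        return out


def kmeans_cluster(
    profiles: pd.DataFrame, k: int = 8, seed: int = 0, n_restarts: int = 20
) -> ClusterAssignment:
    """Euclidean k-means on z-profiles, display-ordered by hierarchical clustering.

    Best of ``n_restarts`` k-means++ initialisations by within-cluster sum of
    squares (seeded, deterministic). Cluster display order 1..k comes from
    average-linkage hierarchical clustering of the k cluster mean profiles,
    so related response shapes sit next to each other. k-means++ with
    reassignment guarantees no returned cluster is empty.
    """
    if len(profiles) < k:
        raise ValueError(f"need >= {k} profiles, got {len(profiles)}")
    X = profiles.to_numpy()
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2**32 - 1))
    raw = km.fit_predict(X)
    centres = km.cluster_centers_
    if k > 2:
        order = leaves_list(linkage(centres, method="average"))
    else:
        order = np.arange(k)
    display = {int(orig): rank + 1 for rank, orig in enumerate(order)}
    labels = {g: display[int(c)] for g, c in zip(profiles.index, raw)}
    means = pd.DataFrame(
        centres[order], index=pd.Index(range(1, k + 1), name="cluster"),
        columns=profiles.columns,
    )
    return ClusterAssignment(labels=labels, means=means, inertia=float(km.inertia_), k=k)


def cluster_mode_association(
    assignment: ClusterAssignment, mode_by_gene: dict[str, str]
) -> pd.DataFrame:
    """Per-cluster 2x2 test of binding mode vs cluster membership.

    Genes without a binding-mode label are excluded (and counted in the log).
    For each cluster the table is (in cluster / not in cluster) x
    (unique / redundant); chi-square is used unless an expected cell drops
    below 5, in which case Fisher's exact test is reported.
    """
    labelled = {g: c for g, c in assignment.labels.items() if g in mode_by_gene}
    dropped = len(assignment.labels) - len(labelled)
    if dropped:
        log.info("%d clustered genes lack a binding-mode label, excluded", dropped)
    if not labelled:
        raise ValueError("no clustered genes carry a binding-mode label")
    rows = []
    for c in range(1, assignment.k + 1):
        in_u = sum(1 for g, cl in labelled.items() if cl == c and mode_by_gene[g] == "unique")
        in_r = sum(1 for g, cl in labelled.items() if cl == c and mode_by_gene[g] == "redundant")
        out_u = sum(1 for g, cl in labelled.items() if cl != c and mode_by_gene[g] == "unique")
        out_r = sum(1 for g, cl in labelled.items() if cl != c and mode_by_gene[g] == "redundant")
        res = test_2x2(((in_u, in_r), (out_u, out_r)))
        rows.append({
            "cluster": c, "n_unique": in_u, "n_redundant": in_r,
            "n": in_u + in_r, "p": res.p, "test_used": res.test_used,
            "odds_ratio": res.odds_ratio,
        })
    return pd.DataFrame(rows)


def direction_mode_split(
    regulated: dict[str, list[str]], mode_by_gene: dict[str, str]
) -> tuple[pd.DataFrame, ContingencyResult]:
    """Up/down x unique/redundant counts for one contrast, with a 2x2 test."""
    counts = {}
    for direction in ("up", "down"):
        genes = [g for g in regulated[direction] if g in mode_by_gene]
        counts[direction] = {
            "unique": sum(1 for g in genes if mode_by_gene[g] == "unique"),
            "redundant": sum(1 for g in genes if mode_by_gene[g] == "redundant"),
        }
    table = (
        (counts["up"]["unique"], counts["up"]["redundant"]),
        (counts["down"]["unique"], counts["down"]["redundant"]),
    )
    df = pd.DataFrame(counts).T
    df.index.name = "direction"
    res = test_2x2(table)
    return df, res
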