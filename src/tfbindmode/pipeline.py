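"""End-to-end orchestration of the binding-mode analysis.

Stage order: simulate (or load) the data bundle, call confident peaks from the
two replicates, classify regions as uniquely vs redundantly bound against the
comparator set, characterise the two classes (TSS geometry, hexamer-site
distributions, SRF/AP1 rates, composite modules), run the expression chain
(collapse, differential response, z-profiles, k-means), and compute the
association statistics tying binding mode to regulation and function.

A single global seed fans out to independent per-stage streams via stable
hashing, so any stage can be reproduced in isolation. The report is plain
JSON; every number in it is the direct output of a stage function.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, expression, intervals, motifs, synthgen
from ._util import derive_seed

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "write_report"]


@dataclass
class PipelineConfig:
    """Run parameters: a simulation config plus all stage thresholds.

    Defaults mirror the analysis conventions: FDR < 10%, the 2 kb proximal
    window and 10 kb promoter/downstream windows, the 100 bp / 50 bp module
    rule, p < 0.05 & q < 0.1 regulated-gene thresholds, k = 8 clusters, and
    10,000 background lists for the overlap z-score.
    """

    sim: synthgen.SimConfig = field(default_factory=synthgen.SimConfig)
    seed: int = 0
    fdr_max_pct: float = 10.0
    min_overlap_bp: int = 1
    proximal_window_bp: int = 2_000
    promoter_bp: int = 10_000
    downstream_bp: int = 10_000
    module_summit_window_bp: float = 100.0
    module_pair_max_bp: float = 50.0
    p_max: float = 0.05
    q_max: float = 0.1
    k_clusters: int = 8
    kmeans_restarts: int = 20
    n_background: int = 10_000
    n_perm: int = 1_000

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = synthgen.SimConfig(**self.sim)
        # the pipeline seed drives the simulation unless one was set explicitly
        self.sim.seed = self.sim.seed or self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.blake2s(blob.encode(), digest_size=8).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage on the configured synthetic bundle; return the report."""
    report: dict = {"provenance": {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package": "tfbindmode",
    }}
    stage = "simulate"
    try:
        bundle = synthgen.generate_bundle(config.sim)
        truth = bundle.truth

        stage = "confidence"
        high, low = intervals.intersect_confidence(
            bundle.rep1, bundle.rep2, config.fdr_max_pct, config.min_overlap_bp)
        report["confidence"] = {
            "n_rep1": len(bundle.rep1), "n_rep2": len(bundle.rep2),
            "n_high": len(high), "n_low": len(low),
        }

        stage = "classify"
        mode_table = intervals.classify_by_overlap(high, bundle.comparator,
                                                   config.min_overlap_bp)
        n_unique = sum(1 for v in mode_table.values() if v == "unique")
        n_redundant = len(mode_table) - n_unique
        agree = sum(
            1 for rid, m in mode_table.items() if truth.region_class.get(rid) == m)
        report["classification"] = {
            "n_unique": n_unique, "n_redundant": n_redundant,
            "truth_agreement": agree / len(mode_table) if mode_table else None,
            "pct_redundant": 100.0 * n_redundant / len(mode_table) if mode_table else None,
        }

        stage = "tss_geometry"
        assignments = intervals.assign_nearest_tss(high, bundle.tss)
        by_class = {"unique": [], "redundant": []}
        for a in assignments:
            by_class[mode_table[a.region_id]].append(a)
        geometry = {}
        for cls, asn in by_class.items():
            h = intervals.tss_distance_histogram(asn, window_bp=config.proximal_window_bp)
            geometry[cls] = {
                "fraction_within_window": h["fraction_within"],
                "n": h["n_total"],
            }
        report["tss_geometry"] = geometry
        report["genomic_distribution"] = intervals.genomic_distribution(
            high, bundle.tss, bundle.genome.chrom_sizes,
            config.promoter_bp, config.downstream_bp,
            seed=derive_seed(config.seed, "genomic_distribution"))

        stage = "region_overlap_test"
        overlap_res = intervals.region_overlap_permutation_test(
            high, bundle.comparator, bundle.genome.chrom_sizes,
            n_perm=config.n_perm, seed=derive_seed(config.seed, "region_overlap"))
        report["region_overlap_test"] = dataclasses.asdict(overlap_res)

        stage = "motifs"
        seqs = bundle.region_sequences(high)
        seq_by_class = {
            cls: {rid: s for rid, s in seqs.items() if mode_table[rid] == cls}
            for cls in ("unique", "redundant")
        }
        motif_section: dict = {}
        for octamer, label in ((config.sim.ets_strong_octamer, "strong"),
                               (config.sim.ets_variant_octamer, "variant")):
            per_class = {}
            for cls, class_seqs in seq_by_class.items():
                summary = motifs.per_region_count_distribution(class_seqs, octamer)
                bg = motifs.per_region_count_distribution(class_seqs, octamer, invert=True)
                hist = summary.histogram()
                per_class[cls] = {
                    "histogram": {int(k): int(v) for k, v in sorted(hist.items())},
                    "total_sites": summary.total_sites,
                    "total_regions": summary.total_regions,
                    "modal_count": max(hist, key=lambda k: (hist[k], -k)),
                    "background_total_sites": bg.total_sites,
                }
            motif_section[f"ets_{label}"] = per_class

        def rate_and_compare(feature_fn, name):
            counts = {}
            for cls, class_seqs in seq_by_class.items():
                n_with = sum(1 for rid in class_seqs if feature_fn(rid, class_seqs[rid]))
                counts[cls] = (n_with, len(class_seqs))
            res = motifs.motif_class_compare(
                counts["unique"][0], counts["unique"][1],
                counts["redundant"][0], counts["redundant"][1])
            motif_section[name] = {
                "rate_unique": counts["unique"][0] / counts["unique"][1],
                "rate_redundant": counts["redundant"][0] / counts["redundant"][1],
                "p": res.p, "test_used": res.test_used,
            }

        rate_and_compare(
            lambda rid, s: bool(motifs.count_iupac(s, motifs.SRF_CARG_PATTERN)), "srf")
        rate_and_compare(
            lambda rid, s: bool(motifs.count_iupac(s, motifs.AP1_PATTERN)), "ap1")
        high_by_id = {r.name: r for r in high}
        rate_and_compare(
            lambda rid, s: bool(motifs.call_ets_srf_modules(
                s, high_by_id[rid].summit - high_by_id[rid].start, region_id=rid,
                summit_window=config.module_summit_window_bp,
                pair_max=config.module_pair_max_bp)),
            "module")
        report["motifs"] = motif_section

        stage = "expression"
        gene_matrix, excl = expression.collapse_probesets(
            bundle.expression, bundle.probe_map, bundle.design)
        de = {c: expression.differential_response(gene_matrix, bundle.design, c)
              for c in ("kd_0", "kd_30", "egf")}
        regulated = {c: expression.filter_regulated(d, config.p_max, config.q_max)
                     for c, d in de.items()}
        mode_by_gene = {truth.region_gene[rid]: m for rid, m in mode_table.items()}
        bound_genes = sorted(mode_by_gene)
        regulated_any = sorted(
            set().union(*[set(r["up"]) | set(r["down"])
                          for c, r in regulated.items() if c != "egf"]))
        target_genes = sorted(set(bound_genes) & set(regulated_any))
        report["expression"] = {
            "n_probesets": int(bundle.expression.shape[0]),
            "n_genes_collapsed": int(gene_matrix.shape[0]),
            "exclusions_by_rule": excl["rule"].value_counts().to_dict(),
            "n_regulated": {c: {d: len(g) for d, g in r.items()}
                            for c, r in regulated.items()},
            "n_bound_genes": len(bound_genes),
            "n_target_genes": len(target_genes),
            "de_method": "batch-paired t-test + Benjamini-Hochberg",
        }

        stage = "overlap_z"
        universe = sorted({t.gene for t in bundle.tss})
        z_section = {}
        for c in ("kd_0", "kd_30"):
            reg = sorted(set(regulated[c]["up"]) | set(regulated[c]["down"]))
            res = assoc.list_overlap_z(
                bound_genes, reg, universe, n_background=config.n_background,
                seed=derive_seed(config.seed, "overlap_z", c))
            z_section[c] = dataclasses.asdict(res)
        report["gene_overlap_z"] = z_section

        stage = "clustering"
        profiles = expression.z_transform_profiles(
            gene_matrix.loc[gene_matrix.index.intersection(target_genes)],
            bundle.design)
        assignment = expression.kmeans_cluster(
            profiles, k=config.k_clusters,
            seed=derive_seed(config.seed, "kmeans"),
            n_restarts=config.kmeans_restarts)
        cm = expression.cluster_mode_association(assignment, mode_by_gene)
        with_truth = [g for g in assignment.labels if g in truth.gene_cluster]
        ari = None
        if with_truth:
            from sklearn.metrics import adjusted_rand_score
            ari = float(adjusted_rand_score(
                [truth.gene_cluster[g] for g in with_truth],
                [assignment.labels[g] for g in with_truth]))
        report["clustering"] = {
            "n_clustered": len(assignment.labels),
            "cluster_sizes": {int(k): int(v) for k, v in assignment.sizes().items()},
            "inertia": assignment.inertia,
            "ari_vs_planted": ari,
            "cluster_mode_association": cm.to_dict(orient="records"),
        }

        stage = "direction_mode"
        dm_section = {}
        for c in ("kd_0", "kd_30"):
            counts, res = expression.direction_mode_split(regulated[c], mode_by_gene)
            dm_section[c] = {
                "counts": counts.to_dict(orient="index"),
                "p": res.p, "test_used": res.test_used,
            }
        report["direction_mode"] = dm_section

        stage = "enrichment"
        if bundle.gene_sets:
            enr = assoc.hypergeom_enrichment(
                sorted(set(regulated["kd_0"]["down"]) & set(bound_genes)),
                bundle.gene_sets, universe)
            cat = assoc.cluster_category_enrichment(assignment.labels, bundle.gene_sets)
            report["enrichment"] = {
                "downregulated_bound_genes": enr.to_dict(orient="records"),
                "cluster_category": cat.drop(columns=["ratios"]).to_dict(orient="records"),
            }
        else:
            log.info("no gene sets supplied; enrichment section skipped")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return _jsonable(report)


def write_report(report: dict, out_dir) -> Path:
    """Write report.json (sorted keys, stable formatting) and per-table TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(json.dumps(report, sort_keys=True, indent=1) + "\n")
    for section in ("clustering", "enrichment"):
        data = report.get(section, {})
        for key, value in data.items():
            if isinstance(value, list) and value and isinstance(value[0], dict):
                pd.DataFrame(value).to_csv(out_dir / f"{section}_{key}.tsv",
                                           sep="\t", index=False)
    return path
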