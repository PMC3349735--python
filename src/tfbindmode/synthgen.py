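"""Self-contained synthetic data generator for the binding-mode pipeline.

Generates a miniature genome, two replicate peak sets for a focal
transcription factor, a comparator factor's peaks, region sequences with
planted ETS / SRF (CArG) / AP1 words, a TSS annotation, and a probeset-level
expression matrix for the 2x2 knockdown-by-stimulus design — together with
ground-truth labels for every planted structure, so each downstream stage can
be tested for parameter recovery without any external download.

The planted structure emulates the statistical signatures of a two-class
binding-mode dataset: redundant-class regions sit close to TSSs, carry
multiple strong ETS octamers and are fully covered by comparator peaks;
unique-class regions sit in a broad distribution around TSSs, carry fewer
(often variant-only) ETS words plus SRF/AP1 sites and composite ETS-SRF
modules, and are never touched by the comparator. Bound genes receive
archetype expression responses whose cluster membership is coupled to the
binding class. Background sequence is i.i.d. uniform and spurious word
occurrences are deliberately not suppressed; tests needing exact counts read
sequences from the planted-site ledger.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import derive_rng, revcomp
from .intervals import PeakRegion, PeakSet, TSSRecord, write_narrowpeak, write_tss_table
from .assoc import write_gmt

log = logging.getLogger(__name__)

__all__ = ["SimConfig", "TruthLabels", "SynthGenome", "Bundle",
           "simulate_genome", "simulate_peaks", "plant_motifs",
           "simulate_expression", "make_gene_sets", "generate_bundle",
           "write_bundle", "DEFAULT_ARCHETYPES"]

#: Default archetype mean profiles over (control 0', control 30', kd 0', kd 30'),
#: in relative log10 units before amplitude scaling. Shapes are chosen to be
#: well separated after per-gene z-transformation and to cover the canonical
#: response classes: stimulus-responsive (1-3), knockdown-down (2, 4-6) and
#: knockdown-up (7, 8).
DEFAULT_ARCHETYPES = (
    (0.0, 1.0, 0.0, 1.0),   # 1: stimulus-up, knockdown-neutral
    (0.0, 1.0, 0.0, 0.0),   # 2: stimulus-up, response lost on knockdown
    (1.0, 0.0, 1.0, 0.0),   # 3: stimulus-down, knockdown-neutral
    (1.0, 1.0, 0.0, 0.0),   # 4: down on knockdown, stimulus-neutral
    (1.0, 0.0, 0.0, 0.0),   # 5: down on stimulus and knockdown
    (1.0, 1.0, 1.0, 0.0),   # 6: down only on stimulated knockdown
    (0.0, 0.0, 1.0, 1.0),   # 7: up on knockdown, stimulus-neutral
    (0.0, 0.0, 1.0, 0.0),   # 8: up only on unstimulated knockdown
)


@dataclass
class SimConfig:
    """All knobs of the synthetic dataset; defaults encode the study conditions.

    Class sizes default to 303 unique / 226 redundant regions; proximal
    fractions to 26% / 93% within the 2 kb window; SRF CArG rates to 54% /
    27%; site-count distributions peak at 1 (unique) and 3 (redundant)
    non-overlapping strong-hexamer sites per region.
    """

    seed: int = 0
    # genome / annotation
    n_chrom: int = 4
    chrom_length: int = 2_000_000
    n_genes_universe: int = 800
    gene_length_range: tuple[int, int] = (1_000, 5_000)
    # peaks
    n_unique: int = 303
    n_redundant: int = 226
    region_length: int = 400
    frac_redundant_proximal: float = 0.93
    frac_unique_proximal: float = 0.26
    proximal_window: int = 2_000
    replicate_jitter_sd: float = 20.0
    replicate_dropout: float = 0.10
    fdr_exceed_frac: float = 0.05
    fdr_max_pct: float = 10.0
    comparator_margin: int = 100
    # motifs
    ets_strong_octamer: str = "CCGGAAGT"
    ets_variant_octamer: str = "CAGGATGT"
    redundant_site_count_dist: dict[int, float] = field(
        default_factory=lambda: {2: 0.15, 3: 0.70, 4: 0.15})
    unique_site_count_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.80, 2: 0.20})
    variant_site_count_dist: dict[int, float] = field(
        default_factory=lambda: {0: 0.50, 1: 0.40, 2: 0.10})
    variant_only_frac_unique: float = 0.30
    srf_rate_unique: float = 0.54
    srf_rate_redundant: float = 0.27
    module_rate_unique: float = 0.25
    module_rate_redundant: float = 0.04
    ap1_rate_unique: float = 0.40
    ap1_rate_redundant: float = 0.10
    # expression
    cluster_archetypes: tuple = DEFAULT_ARCHETYPES
    archetype_amplitude: float = 0.30
    noise_sd: float = 0.10
    n_reps: int = 3
    baseline_range: tuple[float, float] = (1.5, 3.5)
    probe_offset_sd: float = 0.10
    probeset_count_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.20, 3: 0.10})
    low_probe_frac: float = 0.05
    opposite_pair_frac: float = 0.02
    enrichment_odds: float = 7.0
    unique_archetypes: tuple[int, ...] = (2, 4)
    redundant_archetypes: tuple[int, ...] = (7, 8)

    def __post_init__(self):
        props = [
            self.frac_redundant_proximal, self.frac_unique_proximal,
            self.replicate_dropout, self.fdr_exceed_frac,
            self.variant_only_frac_unique, self.srf_rate_unique,
            self.srf_rate_redundant, self.module_rate_unique,
            self.module_rate_redundant, self.ap1_rate_unique,
            self.ap1_rate_redundant, self.low_probe_frac, self.opposite_pair_frac,
        ]
        if any(not 0.0 <= p <= 1.0 for p in props):
            raise ValueError("all proportions must lie in [0, 1]")
        if min(self.n_chrom, self.n_unique, self.n_redundant,
               self.n_genes_universe, self.n_reps) < 0:
            raise ValueError("counts must be non-negative")
        if len(self.cluster_archetypes) != 8 or any(
                len(a) != 4 for a in self.cluster_archetypes):
            raise ValueError("cluster_archetypes must be 8 profiles of length 4")
        if self.region_length >= self.chrom_length:
            raise ValueError("region_length must be smaller than chrom_length")
        if (self.module_rate_unique > self.srf_rate_unique
                or self.module_rate_redundant > self.srf_rate_redundant):
            raise ValueError("module rates cannot exceed SRF rates (modules need a CArG)")
        for dist in (self.redundant_site_count_dist, self.unique_site_count_dist,
                     self.variant_site_count_dist, self.probeset_count_dist):
            total = sum(dist.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"site/probeset count distribution must sum to 1, got {total}")


@dataclass
class TruthLabels:
    """Ground truth for every generated region and gene."""

    region_class: dict[str, str] = field(default_factory=dict)
    region_gene: dict[str, str] = field(default_factory=dict)
    region_proximal: dict[str, bool] = field(default_factory=dict)
    site_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    has_srf: dict[str, bool] = field(default_factory=dict)
    has_ap1: dict[str, bool] = field(default_factory=dict)
    has_module: dict[str, bool] = field(default_factory=dict)
    gene_cluster: dict[str, int] = field(default_factory=dict)
    gene_direction: dict[str, str] = field(default_factory=dict)

    def mode_by_gene(self) -> dict[str, str]:
        return {self.region_gene[r]: c for r, c in self.region_class.items()}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)


@dataclass
class SynthGenome:
    """Mutable synthetic genome: per-chromosome base arrays."""

    sequences: dict[str, np.ndarray]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return "".join(self.sequences[chrom][start:end])

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq("".join(seq)), id=chrom, description="")
            for chrom, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def plant(self, chrom: str, start: int, word: str) -> None:
        arr = self.sequences[chrom]
        if start < 0 or start + len(word) > len(arr):
            raise ValueError("planted word outside chromosome")
        arr[start:start + len(word)] = list(word)


def _gene_spacing(config: SimConfig) -> int:
    per_chrom = -(-config.n_genes_universe // config.n_chrom)  # ceil
    return config.chrom_length // (per_chrom + 1)


def simulate_genome(config: SimConfig) -> tuple[SynthGenome, list[TSSRecord]]:
    """Uniform-random genome plus a tiled TSS annotation.

    Genes are tiled at fixed spacing so that both proximal and distal peak
    placement relative to any gene's TSS is always geometrically possible;
    gene lengths and strands are random. Deterministic for a given seed.
    """
    spacing = _gene_spacing(config)
    min_spacing = 2 * config.proximal_window + 2 * config.region_length + 1_000
    if spacing < min_spacing:
        raise ValueError(
            f"chrom_length too small: gene spacing {spacing} bp < required "
            f"{min_spacing} bp for distal placement"
        )
    rng = derive_rng(config.seed, "genome")
    sequences = {}
    for i in range(config.n_chrom):
        chrom = f"chr{i + 1}"
        sequences[chrom] = rng.choice(np.array(list("ACGT")), size=config.chrom_length)
    genome = SynthGenome(sequences)

    tss_records = []
    per_chrom = -(-config.n_genes_universe // config.n_chrom)
    gene_no = 0
    lo, hi = config.gene_length_range
    for i in range(config.n_chrom):
        chrom = f"chr{i + 1}"
        for j in range(per_chrom):
            if gene_no >= config.n_genes_universe:
                break
            gene_no += 1
            tss = spacing * (j + 1)
            length = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            tts = tss + length if strand == "+" else tss - length
            tss_records.append(TSSRecord(f"g{gene_no:04d}", chrom, tss, tts, strand))
    return genome, tss_records


def _sample_count(rng: np.random.Generator, dist: dict[int, float]) -> int:
    ks = sorted(dist)
    return int(rng.choice(ks, p=[dist[k] for k in ks]))


def simulate_peaks(
    genome: SynthGenome, tss: list[TSSRecord], config: SimConfig
) -> tuple[PeakSet, PeakSet, PeakSet, TruthLabels]:
    """Two replicate focal peak sets, one comparator set, and truth labels.

    Each region is hosted by a distinct gene. Redundant-class regions are
    proximal (summit within the 2 kb window of their gene's TSS) with
    probability ``frac_redundant_proximal``, unique-class regions with
    ``frac_unique_proximal``. Comparator peaks cover the interior of every
    redundant region and never touch a unique region, making the two classes
    perfectly separable by overlap. Replicate 2 is replicate 1 jittered by
    N(0, jitter_sd); a ``replicate_dropout`` fraction of regions appears in
    one replicate only, and a ``fdr_exceed_frac`` fraction draws an FDR above
    the cut-off, exercising the confidence-calling logic.
    """
    n_total = config.n_unique + config.n_redundant
    if n_total > len(tss):
        raise ValueError(
            f"requested {n_total} regions but only {len(tss)} genes available")
    rng = derive_rng(config.seed, "peaks")
    spacing = _gene_spacing(config)
    half = config.region_length // 2
    hosts = list(rng.choice(len(tss), size=n_total, replace=False))
    classes = ["unique"] * config.n_unique + ["redundant"] * config.n_redundant

    truth = TruthLabels()
    rep1, rep2, comparator = [], [], []
    max_distal = min(int(2.25 * config.proximal_window),
                     spacing // 2 - config.region_length - 200)
    min_distal = config.proximal_window + 500

    placements = []
    for host_idx, cls in zip(hosts, classes):
        t = tss[host_idx]
        prox_rate = (config.frac_redundant_proximal if cls == "redundant"
                     else config.frac_unique_proximal)
        proximal = bool(rng.random() < prox_rate)
        if proximal:
            offset = int(rng.integers(-int(0.9 * config.proximal_window),
                                      int(0.9 * config.proximal_window) + 1))
        else:
            mag = int(rng.integers(min_distal, max_distal + 1))
            offset = mag if rng.random() < 0.5 else -mag
        summit = t.tss + offset
        placements.append((t, cls, proximal, summit))

    # name regions in genomic order so ids carry no class information
    placements.sort(key=lambda p: (p[0].chrom, p[3]))
    for k, (t, cls, proximal, summit) in enumerate(placements):
        rid = f"peak_{k + 1:04d}"
        start, end = summit - half, summit - half + config.region_length
        score = int(rng.integers(20, 200))
        if rng.random() < config.fdr_exceed_frac:
            fdr = float(rng.uniform(config.fdr_max_pct, config.fdr_max_pct * 2))
        else:
            fdr = float(rng.uniform(0, config.fdr_max_pct * 0.99))
        r1 = PeakRegion(t.chrom, start, end, rid, score, summit, fdr)
        shift = int(round(rng.normal(0, config.replicate_jitter_sd)))
        r2 = PeakRegion(t.chrom, start + shift, end + shift, rid, score, summit + shift, fdr)
        # dropout regions appear in replicate 2 only, so they exercise the
        # low-confidence branch of the intersection logic
        if rng.random() < config.replicate_dropout:
            rep2.append(r2)
        else:
            rep1.append(r1)
            rep2.append(r2)
        truth.region_class[rid] = cls
        truth.region_gene[rid] = t.gene
        truth.region_proximal[rid] = proximal
        if cls == "redundant":
            # margin shrinks for short regions so the comparator stays inside
            m = min(config.comparator_margin, (config.region_length - 20) // 2)
            comparator.append(PeakRegion(
                t.chrom, start + m, end - m, f"comp_{len(comparator) + 1:04d}",
                int(rng.integers(20, 200)), summit, float(rng.uniform(0, 5)),
            ))

    sizes = genome.chrom_sizes
    return (
        PeakSet("focal_rep1", rep1, sizes),
        PeakSet("focal_rep2", rep2, sizes),
        PeakSet("comparator", comparator, sizes),
        truth,
    )


_PLANT_GAP = 6          # min bp between planted footprints (keeps sites countable)
_PLANT_HALF_WINDOW = 140  # planting window around the replicate-1 summit


def _make_carg(rng: np.random.Generator) -> str:
    return "CC" + "".join(rng.choice(["A", "T"], size=6)) + "GG"


def _make_ap1(rng: np.random.Generator) -> str:
    return "TGA" + str(rng.choice(list("ACGT"))) + "TCA"


class _SlotAllocator:
    """Non-overlapping word placement inside a region window."""

    def __init__(self, rng, lo: int, hi: int):
        self.rng = rng
        self.lo, self.hi = lo, hi
        self.occupied: list[tuple[int, int]] = []

    def reserve(self, start: int, length: int) -> bool:
        iv = (start - _PLANT_GAP, start + length + _PLANT_GAP)
        if start < self.lo or start + length > self.hi:
            return False
        for (s, e) in self.occupied:
            if iv[0] < e and s < iv[1]:
                return False
        self.occupied.append((start, start + length))
        return True

    def place(self, length: int, tries: int = 200) -> int:
        for _ in range(tries):
            start = int(self.rng.integers(self.lo, self.hi - length + 1))
            if self.reserve(start, length):
                return start
        raise RuntimeError(
            f"could not place a {length} bp word in [{self.lo},{self.hi}) "
            f"after {tries} tries (window too crowded)")


def plant_motifs(
    genome: SynthGenome, rep1: PeakSet, truth: TruthLabels, config: SimConfig
) -> pd.DataFrame:
    """Mutate the genome to plant motif words in every labelled region.

    Redundant regions receive k strong ETS octamers (k from the redundant
    count distribution); unique regions receive k sites from the unique
    distribution, a configurable fraction drawn from the variant octamer
    only. Both classes additionally receive variant-octamer sites at a shared
    rate, SRF CArG words and AP1 sites at class-specific rates, and
    module-flagged regions get an ETS word and a CArG word both within 100 bp
    of the summit and < 50 bp apart. Every planted word is recorded in the
    returned ledger (region, family, word, absolute position, strand).
    """
    rng = derive_rng(config.seed, "motifs")
    ledger = []
    regions_by_id = {r.name: r for r in rep1}

    for rid, cls in truth.region_class.items():
        region = regions_by_id.get(rid)
        if region is None:      # region dropped from replicate 1
            truth.site_counts[rid] = {"strong": 0, "variant": 0}
            truth.has_srf[rid] = truth.has_ap1[rid] = truth.has_module[rid] = False
            continue
        lo = max(region.start, region.summit - _PLANT_HALF_WINDOW)
        hi = min(region.end, region.summit + _PLANT_HALF_WINDOW)
        alloc = _SlotAllocator(rng, lo, hi)
        planted = {"strong": 0, "variant": 0}
        has_ap1 = False
        has_module = False

        def record(family: str, word: str, start: int):
            strand = "+" if rng.random() < 0.5 else "-"
            written = word if strand == "+" else revcomp(word)
            genome.plant(region.chrom, start, written)
            ledger.append({
                "region_id": rid, "family": family, "word": word,
                "chrom": region.chrom, "start": start, "strand": strand,
            })

        variant_only = (cls == "unique" and rng.random() < config.variant_only_frac_unique)

        # SRF presence is drawn at the class rate; module-flagged regions are a
        # subset of the SRF-positive ones, so the marginal CArG rate stays at
        # the configured value while the marginal module rate is module_rate
        srf_rate = config.srf_rate_unique if cls == "unique" else config.srf_rate_redundant
        module_rate = (config.module_rate_unique if cls == "unique"
                       else config.module_rate_redundant)
        has_srf = rng.random() < srf_rate
        module_flag = has_srf and srf_rate > 0 and rng.random() < module_rate / srf_rate

        # composite ETS-SRF module, planted tight around the summit so the
        # 100 bp / 50 bp rule survives replicate jitter
        if module_flag:
            ets_word = (config.ets_variant_octamer if variant_only
                        else config.ets_strong_octamer)
            for _ in range(50):
                centre_e = region.summit + int(rng.integers(-35, 36))
                d = int(rng.integers(20, 46)) * (1 if rng.random() < 0.5 else -1)
                centre_s = centre_e + d
                if abs(centre_s - region.summit) > 55:
                    continue
                e_start, s_start = centre_e - 4, centre_s - 5
                if alloc.reserve(e_start, 8) and alloc.reserve(s_start, 10):
                    record("ets_variant" if variant_only else "ets_strong",
                           ets_word, e_start)
                    record("srf", _make_carg(rng), s_start)
                    planted["variant" if variant_only else "strong"] += 1
                    has_module = True
                    break
            else:
                raise RuntimeError(f"{rid}: failed to place ETS-SRF module")

        # main ETS sites; a module's ETS word counts toward the target k
        if cls == "redundant":
            need = {"strong": _sample_count(rng, config.redundant_site_count_dist),
                    "variant": 0}
        else:
            k = _sample_count(rng, config.unique_site_count_dist)
            need = ({"strong": 0, "variant": k} if variant_only
                    else {"strong": k, "variant": 0})
        # both classes share the same extra variant-site distribution
        if not variant_only:
            need["variant"] += _sample_count(rng, config.variant_site_count_dist)
        for fam in ("strong", "variant"):
            word = (config.ets_strong_octamer if fam == "strong"
                    else config.ets_variant_octamer)
            while planted[fam] < need[fam]:
                start = alloc.place(8)
                record(f"ets_{fam}", word, start)
                planted[fam] += 1

        if has_srf and not has_module:
            # standalone CArG goes far from the summit so it cannot form an
            # accidental module (its centre stays outside the 100 bp summit
            # window even under replicate jitter); fall back to anywhere free
            placed = False
            for _ in range(100):
                off = int(rng.integers(125, 136)) * (1 if rng.random() < 0.5 else -1)
                start = region.summit + off - 5
                if alloc.reserve(start, 10):
                    record("srf", _make_carg(rng), start)
                    placed = True
                    break
            if not placed:
                record("srf", _make_carg(rng), alloc.place(10))

        ap1_rate = config.ap1_rate_unique if cls == "unique" else config.ap1_rate_redundant
        if rng.random() < ap1_rate:
            start = alloc.place(7)
            record("ap1", _make_ap1(rng), start)
            has_ap1 = True

        truth.site_counts[rid] = planted
        truth.has_srf[rid] = has_srf
        truth.has_ap1[rid] = has_ap1
        truth.has_module[rid] = has_module

    return pd.DataFrame(ledger, columns=["region_id", "family", "word", "chrom", "start", "strand"])


def simulate_expression(
    tss: list[TSSRecord], truth: TruthLabels, config: SimConfig
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Probeset-level expression matrix for the 2x2 design, with truth labels.

    Genes hosting unique-class regions draw their response archetype with
    enriched odds on the unique-preferred archetypes (default 2 and 4, the
    knockdown-down shapes); redundant-class genes on archetypes 7 and 8 (the
    knockdown-up shapes). Unbound genes are flat (null). Signals are log10
    scale: gene baseline + probe offset + amplitude-scaled centred archetype
    + N(0, noise_sd) per replicate. Multi-probeset genes, dead probesets
    below background, and opposite-direction probeset pairs are planted to
    exercise every collapsing rule.
    """
    rng = derive_rng(config.seed, "expression")
    archetypes = np.array(config.cluster_archetypes, dtype=float)
    centred = archetypes - archetypes.mean(axis=1, keepdims=True)
    mode_by_gene = truth.mode_by_gene()
    if not mode_by_gene:
        raise ValueError("no bound genes: run simulate_peaks first")

    def pick_archetype(mode: str) -> int:
        preferred = (config.unique_archetypes if mode == "unique"
                     else config.redundant_archetypes)
        weights = np.array([
            config.enrichment_odds if (i + 1) in preferred else 1.0
            for i in range(8)
        ])
        return int(rng.choice(8, p=weights / weights.sum())) + 1

    conditions = [(t, s) for t in ("control_kd", "focal_kd") for s in (0, 30)]
    samples = []
    design_rows = []
    for t, s in conditions:
        for b in range(1, config.n_reps + 1):
            sid = f"{t}_{s}min_b{b}"
            samples.append(sid)
            design_rows.append({"sample": sid, "treatment": t, "stimulus": s, "batch": b})
    design = pd.DataFrame(design_rows).set_index("sample")

    lo_b, hi_b = config.baseline_range
    probe_map: dict[str, str] = {}
    rows = []
    index = []
    for t in tss:
        gene = t.gene
        mode = mode_by_gene.get(gene)
        if mode is None:
            arch = 0
            deviation = np.zeros(4)
        else:
            arch = pick_archetype(mode)
            deviation = centred[arch - 1] * config.archetype_amplitude
            truth.gene_cluster[gene] = arch
        kd_effect = deviation[2:].mean() - deviation[:2].mean()
        if abs(kd_effect) < 1e-12:
            truth.gene_direction[gene] = "none"
        else:
            truth.gene_direction[gene] = "up" if kd_effect > 0 else "down"

        baseline = float(rng.uniform(lo_b, hi_b))
        n_ps = _sample_count(rng, config.probeset_count_dist)
        dev_list = [deviation] * n_ps
        if mode is not None and rng.random() < config.opposite_pair_frac:
            dev_list.append(-deviation)     # opposite-direction probeset pair
        for pi, dev in enumerate(dev_list, start=1):
            ps = f"{gene}_ps{pi}"
            probe_map[ps] = gene
            if rng.random() < config.low_probe_frac:
                base = float(rng.uniform(0.2, 0.8))   # dead probe, below background
                dev = np.zeros(4)
            else:
                base = baseline + float(rng.normal(0, config.probe_offset_sd))
            signal = []
            for (trt, stim) in conditions:
                ci = conditions.index((trt, stim))
                for _ in range(config.n_reps):
                    signal.append(base + dev[ci] + float(rng.normal(0, config.noise_sd)))
            rows.append(signal)
            index.append(ps)

    matrix = pd.DataFrame(rows, index=pd.Index(index, name="probeset"), columns=samples)
    return matrix, probe_map, design


def make_gene_sets(
    tss: list[TSSRecord], truth: TruthLabels, config: SimConfig
) -> dict[str, set[str]]:
    """Planted functional categories coupled to binding mode, plus decoys.

    Unique-bound genes preferentially populate "cytoskeleton_migration",
    redundant-bound genes "gene_expression_machinery"; "cell_survival" draws
    from both; two decoy categories are uniform over the universe.
    """
    rng = derive_rng(config.seed, "gene_sets")
    mode_by_gene = truth.mode_by_gene()
    universe = [t.gene for t in tss]
    sets: dict[str, set[str]] = {
        "cytoskeleton_migration": set(),
        "gene_expression_machinery": set(),
        "cell_survival": set(),
    }
    for gene, mode in mode_by_gene.items():
        u = rng.random()
        if mode == "unique":
            if u < 0.55:
                sets["cytoskeleton_migration"].add(gene)
            elif u < 0.70:
                sets["cell_survival"].add(gene)
        else:
            if u < 0.55:
                sets["gene_expression_machinery"].add(gene)
            elif u < 0.65:
                sets["cell_survival"].add(gene)
    for name in ("decoy_metabolism", "decoy_transport"):
        size = max(10, len(universe) // 20)
        sets[name] = set(rng.choice(universe, size=size, replace=False))
    return sets


@dataclass
class Bundle:
    """The full in-memory synthetic dataset."""

    config: SimConfig
    genome: SynthGenome
    tss: list[TSSRecord]
    rep1: PeakSet
    rep2: PeakSet
    comparator: PeakSet
    truth: TruthLabels
    ledger: pd.DataFrame
    expression: pd.DataFrame
    probe_map: dict[str, str]
    design: pd.DataFrame
    gene_sets: dict[str, set[str]]

    def region_sequences(self, peaks: PeakSet | None = None) -> dict[str, str]:
        peaks = peaks if peaks is not None else self.rep2
        return {r.name: self.genome.fetch(r.chrom, r.start, r.end) for r in peaks}


def generate_bundle(config: SimConfig) -> Bundle:
    """Run the full generator chain for one configuration (deterministic)."""
    genome, tss = simulate_genome(config)
    rep1, rep2, comparator, truth = simulate_peaks(genome, tss, config)
    ledger = plant_motifs(genome, rep1, truth, config)
    expression, probe_map, design = simulate_expression(tss, truth, config)
    gene_sets = make_gene_sets(tss, truth, config)
    return Bundle(config, genome, tss, rep1, rep2, comparator, truth, ledger,
                  expression, probe_map, design, gene_sets)


def write_bundle(bundle: Bundle, outdir) -> None:
    """Write every bundle component as plain-text files (FASTA/narrowPeak/TSV/JSON/GMT)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.genome.write_fasta(outdir / "genome.fa")
    write_narrowpeak(bundle.rep1, outdir / "focal_rep1.narrowPeak")
    write_narrowpeak(bundle.rep2, outdir / "focal_rep2.narrowPeak")
    write_narrowpeak(bundle.comparator, outdir / "comparator.narrowPeak")
    write_tss_table(bundle.tss, outdir / "tss.tsv")
    pd.DataFrame(
        sorted(bundle.genome.chrom_sizes.items()), columns=["chrom", "size"]
    ).to_csv(outdir / "chrom.sizes", sep="\t", header=False, index=False)
    bundle.expression.to_csv(outdir / "expression.tsv", sep="\t")
    bundle.design.to_csv(outdir / "design.tsv", sep="\t")
    pd.DataFrame(
        sorted(bundle.probe_map.items()), columns=["probeset", "gene"]
    ).to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
    bundle.ledger.to_csv(outdir / "planted_sites.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(bundle.truth.to_json())
    write_gmt(bundle.gene_sets, outdir / "gene_sets.gmt")
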