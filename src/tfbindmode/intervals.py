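"""Interval algebra over ChIP peak sets.

Implements the genomic-interval side of the binding-mode analysis:

* narrowPeak (BED6+4) reading/writing with summit-offset semantics,
* replicate-based confidence calling with an FDR filter,
* summit-based nearest-TSS assignment,
* unique/redundant classification of a focal factor's regions against a
  comparator factor's regions,
* TSS-distance histograms and coarse genomic-distribution categories,
* a per-chromosome permutation test for region-set overlap.

Coordinates are 0-based half-open throughout; the narrowPeak summit field is a
0-based offset from the region start.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "PeakRegion",
    "PeakSet",
    "TSSRecord",
    "NearestGeneAssignment",
    "RegionOverlapTestResult",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_tss_table",
    "write_tss_table",
    "intersect_confidence",
    "assign_nearest_tss",
    "classify_by_overlap",
    "tss_distance_histogram",
    "genomic_distribution",
    "region_overlap_permutation_test",
]


@dataclass(frozen=True)
class PeakRegion:
    """A called ChIP peak: half-open interval with a summit inside it.

    ``score`` is a pseudo tag-count; ``fdr_pct`` is the peak caller's FDR as a
    percentage in [0, 100].
    """

    chrom: str
    start: int
    end: int
    name: str
    score: int = 0
    summit: int = -1
    fdr_pct: float = 0.0

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.name}: start {self.start} !< end {self.end}")
        if self.summit < 0:
            object.__setattr__(self, "summit", (self.start + self.end) // 2)
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"{self.name}: summit {self.summit} outside [{self.start},{self.end})")
        if not (0.0 <= self.fdr_pct <= 100.0):
            raise ValueError(f"{self.name}: fdr_pct {self.fdr_pct} outside [0,100]")

    def overlaps(self, other: "PeakRegion", min_bp: int = 1) -> bool:
        return (
            self.chrom == other.chrom
            and min(self.end, other.end) - max(self.start, other.start) >= min_bp
        )


@dataclass
class PeakSet:
    """A named, coordinate-sorted collection of peaks.

    ``chrom_sizes`` (optional) bounds coordinates; regions beyond a declared
    chromosome end are rejected at construction.
    """

    name: str
    regions: list[PeakRegion] = field(default_factory=list)
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self):
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end))
        if self.chrom_sizes is not None:
            for r in self.regions:
                size = self.chrom_sizes.get(r.chrom)
                if size is not None and r.end > size:
                    raise ValueError(f"{r.name}: end {r.end} beyond {r.chrom} size {size}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def by_chrom(self) -> dict[str, list[PeakRegion]]:
        out: dict[str, list[PeakRegion]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out

    def filter_fdr(self, fdr_max_pct: float) -> "PeakSet":
        """Regions with FDR strictly below the cut-off (percent)."""
        kept = [r for r in self.regions if r.fdr_pct < fdr_max_pct]
        return PeakSet(self.name, kept, self.chrom_sizes)


@dataclass(frozen=True)
class TSSRecord:
    """Gene anchor: transcription start and termination sites with strand."""

    gene: str
    chrom: str
    tss: int
    tts: int
    strand: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene}: strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and self.tss > self.tts:
            raise ValueError(f"{self.gene}: + strand requires tss <= tts")
        if self.strand == "-" and self.tss < self.tts:
            raise ValueError(f"{self.gene}: - strand requires tss >= tts")


@dataclass(frozen=True)
class NearestGeneAssignment:
    """Nearest gene for a region's summit.

    ``signed_distance`` is negative when the summit lies 5' (upstream) of the
    TSS in the gene's orientation. ``gene`` is None for regions on
    chromosomes that carry no annotated gene.
    """

    region_id: str
    gene: str | None
    signed_distance: int | None


@dataclass(frozen=True)
class RegionOverlapTestResult:
    """Permutation test for overlap of two region sets (per-chromosome shuffling)."""

    observed_overlap: int
    perm_mean: float
    perm_sd: float
    z: float
    empirical_p: float
    n_perm: int


# ---------------------------------------------------------------------------
# I/O

_NP_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal", "pvalue", "qvalue", "summit_offset",
]


def read_narrowpeak(path, chrom_sizes: dict[str, int] | None = None, name: str | None = None) -> PeakSet:
    """Parse a narrowPeak (BED6+4) file into a :class:`PeakSet`.

    Field 9 (``qvalue``) is interpreted as the FDR in percent; field 10 is the
    summit offset from ``start``. Malformed lines raise with their line number;
    regions on chromosomes absent from ``chrom_sizes`` are skipped with a
    warning.
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(f"{path}:{lineno}: expected 10 narrowPeak fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                offset = int(fields[9])
                region = PeakRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    name=fields[3],
                    score=int(fields[4]),
                    summit=start + offset,
                    fdr_pct=float(fields[8]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if chrom_sizes is not None and chrom not in chrom_sizes:
                log.warning("%s:%d: unknown chromosome %s, skipping", path, lineno, chrom)
                continue
            regions.append(region)
    return PeakSet(name or str(path), regions, chrom_sizes)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    rows = []
    for r in peaks:
        rows.append([
            r.chrom, r.start, r.end, r.name, r.score, ".",
            float(r.score), 0.0, float(r.fdr_pct), r.summit - r.start,
        ])
    pd.DataFrame(rows, columns=_NP_COLS).to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path) -> list[TSSRecord]:
    """Read a refGene-like TSV: gene, chrom, tss, tts, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    return [
        TSSRecord(row.gene, row.chrom, int(row.tss), int(row.tts), row.strand)
        for row in df.itertuples()
    ]


def write_tss_table(records: list[TSSRecord], path) -> None:
    pd.DataFrame(
        [(t.gene, t.chrom, t.tss, t.tts, t.strand) for t in records],
        columns=["gene", "chrom", "tss", "tts", "strand"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Core interval operations


def _overlaps_any(region: PeakRegion, sorted_others: list[PeakRegion], min_bp: int = 1) -> bool:
    """True if region shares >= min_bp with any of a start-sorted same-chrom list."""
    starts = [o.start for o in sorted_others]
    # candidates: others with start < region.end; scan back while they might reach region.start
    idx = bisect.bisect_left(starts, region.end)
    for o in reversed(sorted_others[:idx]):
        if o.end - region.start >= min_bp and min(region.end, o.end) - max(region.start, o.start) >= min_bp:
            return True
        # sorted by start only: an earlier region may still be long enough, so
        # bail out conservatively once starts are far left of region.start
        if region.start - o.start > _max_len(sorted_others):
            break
    return False


def _max_len(regions: list[PeakRegion]) -> int:
    return max((r.end - r.start for r in regions), default=0)


def intersect_confidence(
    rep1: PeakSet, rep2: PeakSet, fdr_max_pct: float = 10.0, min_overlap_bp: int = 1
) -> tuple[PeakSet, PeakSet]:
    """Split replicate-2 peaks into high- and low-confidence sets.

    Both replicates are first filtered to FDR < ``fdr_max_pct``. A replicate-2
    region overlapping (>= ``min_overlap_bp``) any replicate-1 region is high
    confidence and keeps its own replicate-2 coordinates; the rest are low
    confidence.
    """
    rep1_f = rep1.filter_fdr(fdr_max_pct)
    rep2_f = rep2.filter_fdr(fdr_max_pct)
    n_dropped = (len(rep1) - len(rep1_f)) + (len(rep2) - len(rep2_f))
    if n_dropped:
        log.info("FDR filter (<%g%%) dropped %d regions", fdr_max_pct, n_dropped)
    rep1_by_chrom = rep1_f.by_chrom()
    high, low = [], []
    for r in rep2_f:
        others = rep1_by_chrom.get(r.chrom, [])
        (high if _overlaps_any(r, others, min_overlap_bp) else low).append(r)
    sizes = rep2.chrom_sizes or rep1.chrom_sizes
    return (
        PeakSet(f"{rep2_f.name}.high_confidence", high, sizes),
        PeakSet(f"{rep2_f.name}.low_confidence", low, sizes),
    )


def assign_nearest_tss(peaks: PeakSet, tss: list[TSSRecord]) -> list[NearestGeneAssignment]:
    """Assign each peak to the gene with the nearest TSS on its chromosome.

    Distance is summit-to-TSS. Ties (equidistant TSSs) go to the gene with the
    smaller TSS coordinate. Peaks on chromosomes without genes are returned
    with ``gene=None`` rather than dropped.
    """
    by_chrom: dict[str, list[TSSRecord]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    for recs in by_chrom.values():
        recs.sort(key=lambda t: (t.tss, t.gene))

    out = []
    n_unassigned = 0
    for r in peaks:
        recs = by_chrom.get(r.chrom)
        if not recs:
            out.append(NearestGeneAssignment(r.name, None, None))
            n_unassigned += 1
            continue
        positions = [t.tss for t in recs]
        i = bisect.bisect_left(positions, r.summit)
        # candidates around the insertion point; scan both neighbours, prefer
        # smaller coordinate on exact distance ties
        best = None
        best_key = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(recs):
                t = recs[j]
                key = (abs(r.summit - t.tss), t.tss, t.gene)
                if best_key is None or key < best_key:
                    best_key = key
                    best = t
        signed = r.summit - best.tss if best.strand == "+" else best.tss - r.summit
        out.append(NearestGeneAssignment(r.name, best.gene, signed))
    if n_unassigned:
        log.info("%d peaks on chromosomes without genes left unassigned", n_unassigned)
    return out


def classify_by_overlap(
    focal_high: PeakSet, comparator: PeakSet, min_overlap_bp: int = 1
) -> dict[str, str]:
    """Label each focal region ``redundant`` if it overlaps the comparator set.

    Returns the binding-mode table region_id -> {"unique", "redundant"}: a
    region is redundant iff it shares >= ``min_overlap_bp`` with at least one
    comparator region, unique otherwise.
    """
    comp_by_chrom = comparator.by_chrom()
    table = {}
    for r in focal_high:
        others = comp_by_chrom.get(r.chrom, [])
        table[r.name] = "redundant" if _overlaps_any(r, others, min_overlap_bp) else "unique"
    return table


def tss_distance_histogram(
    assignments: list[NearestGeneAssignment], window_bp: int = 2000, bin_bp: int = 100
) -> dict:
    """Histogram of signed summit-to-TSS distances within +/- ``window_bp``.

    Returns bin edges/counts plus the fraction of all (assigned) regions whose
    distance magnitude is within the window.
    """
    dists = np.array(
        [a.signed_distance for a in assignments if a.signed_distance is not None], dtype=float
    )
    if dists.size == 0:
        raise ValueError("no assigned regions to histogram")
    edges = np.arange(-window_bp, window_bp + bin_bp, bin_bp)
    inside = dists[np.abs(dists) <= window_bp]
    counts, edges = np.histogram(np.clip(inside, -window_bp, window_bp - 1e-9), bins=edges)
    return {
        "bin_edges": edges,
        "counts": counts,
        "n_total": int(dists.size),
        "n_within": int(inside.size),
        "fraction_within": float(inside.size / dists.size),
    }


def _categorise_summit(summit: int, chrom: str, tss: list[TSSRecord],
                       promoter_bp: int, downstream_bp: int) -> str:
    """Category with precedence promoter > gene body > downstream > intergenic."""
    in_promoter = in_body = in_downstream = False
    for t in tss:
        if t.chrom != chrom:
            continue
        lo, hi = (t.tss, t.tts) if t.strand == "+" else (t.tts, t.tss)
        if t.strand == "+":
            prom = (t.tss - promoter_bp, t.tss)
            down = (t.tts, t.tts + downstream_bp)
        else:
            prom = (t.tss, t.tss + promoter_bp)
            down = (t.tts - downstream_bp, t.tts)
        if prom[0] <= summit < prom[1]:
            in_promoter = True
        if lo <= summit <= hi:
            in_body = True
        if down[0] <= summit < down[1]:
            in_downstream = True
    if in_promoter:
        return "promoter"
    if in_body:
        return "gene_body"
    if in_downstream:
        return "downstream"
    return "intergenic"


def genomic_distribution(
    peaks: PeakSet,
    tss_records: list[TSSRecord],
    chrom_sizes: dict[str, int],
    promoter_bp: int = 10_000,
    downstream_bp: int = 10_000,
    seed: int = 0,
) -> dict:
    """Categorise peak summits as promoter / gene body / downstream / intergenic.

    The promoter covers up to ``promoter_bp`` upstream of the TSS (strand
    aware) and the downstream region up to ``downstream_bp`` past the TTS.
    A matched random baseline (uniform summits on the same chromosomes,
    seeded) is returned alongside the observed counts.
    """
    by_chrom: dict[str, list[TSSRecord]] = {}
    for t in tss_records:
        by_chrom.setdefault(t.chrom, []).append(t)

    def tally(items: list[tuple[str, int]]) -> dict[str, int]:
        counts = {"promoter": 0, "gene_body": 0, "downstream": 0, "intergenic": 0}
        for chrom, summit in items:
            counts[_categorise_summit(summit, chrom, by_chrom.get(chrom, []),
                                      promoter_bp, downstream_bp)] += 1
        return counts

    observed = tally([(r.chrom, r.summit) for r in peaks])
    rng = np.random.default_rng(seed)
    chroms = [r.chrom for r in peaks]
    baseline = tally([(c, int(rng.integers(0, chrom_sizes[c]))) for c in chroms])
    return {"observed": observed, "baseline": baseline, "n": len(peaks)}


def region_overlap_permutation_test(
    set_a: PeakSet,
    set_b: PeakSet,
    chrom_sizes: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap_bp: int = 1,
) -> RegionOverlapTestResult:
    """Permutation test: does set B overlap set A more than expected?

    Set A stays fixed. Each permutation re-places every B region uniformly at
    random within its own chromosome, preserving region lengths and
    per-chromosome counts. The statistic is the number of A regions overlapped
    by at least one B region; the one-sided empirical p-value is
    ``(1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    for r in set_b:
        if r.end - r.start > chrom_sizes[r.chrom]:
            raise ValueError(f"{r.name} longer than chromosome {r.chrom}")

    rng = np.random.default_rng(seed)
    a_by_chrom = {
        c: (np.array([r.start for r in rs]), np.array([r.end for r in rs]))
        for c, rs in set_a.by_chrom().items()
    }
    b_lengths = {c: np.array([r.end - r.start for r in rs])
                 for c, rs in set_b.by_chrom().items()}

    def count_overlapped(b_intervals: dict[str, np.ndarray]) -> int:
        total = 0
        for chrom, (a_starts, a_ends) in a_by_chrom.items():
            b = b_intervals.get(chrom)
            if b is None or len(b) == 0:
                continue
            order = np.argsort(b[:, 0], kind="stable")
            b_starts = b[order, 0]
            # running max of ends lets a single bisect decide overlap
            run_max_end = np.maximum.accumulate(b[order, 1])
            idx = np.searchsorted(b_starts, a_ends - (min_overlap_bp - 1), side="left")
            hit = idx > 0
            hit[hit] &= run_max_end[idx[hit] - 1] - a_starts[hit] >= min_overlap_bp
            total += int(hit.sum())
        return total

    observed = count_overlapped(
        {c: np.array([(r.start, r.end) for r in rs]) for c, rs in set_b.by_chrom().items()}
    )

    perm_counts = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        placed = {}
        for chrom, lengths in b_lengths.items():
            size = chrom_sizes[chrom]
            starts = rng.integers(0, size - lengths + 1)
            placed[chrom] = np.column_stack([starts, starts + lengths])
        perm_counts[k] = count_overlapped(placed)

    mean = float(perm_counts.mean())
    sd = float(perm_counts.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    p = (1 + int(np.sum(perm_counts >= observed))) / (n_perm + 1)
    return RegionOverlapTestResult(observed, mean, sd, z, p, n_perm)
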