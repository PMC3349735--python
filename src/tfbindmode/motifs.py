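"""Degenerate-word motif scanning and composite ETS-SRF module calling.

The word-based search deliberately works on exact IUPAC strings, not position
weight matrices: the binding-mode analysis counts exact matches to an octamer
consensus (e.g. the strong ETS consensus CCGGAAGT and the relaxed variant
CAGGATGT) via its three constituent hexamers, selected greedily so that
counted sites never overlap. Composite modules pair an ETS hit with an SRF
CArG-box hit near the peak summit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import IUPAC, revcomp
from .assoc import ContingencyResult, test_2x2

__all__ = [
    "MotifHit",
    "HexamerCountSummary",
    "ModuleCall",
    "count_iupac",
    "hexamer_derivatives",
    "count_hexamer_sites",
    "per_region_count_distribution",
    "call_ets_srf_modules",
    "motif_class_compare",
    "SRF_CARG_PATTERN",
    "AP1_PATTERN",
    "ETS_STRONG_OCTAMER",
    "ETS_VARIANT_OCTAMER",
]

#: CArG box consensus used for SRF sites (CC A/T-rich core GG).
SRF_CARG_PATTERN = "CCWWWWWWGG"
#: AP1 (FOS/JUN) recognition heptamer.
AP1_PATTERN = "TGANTCA"
#: Strong ETS octamer consensus.
ETS_STRONG_OCTAMER = "CCGGAAGT"
#: Relaxed/variant ETS octamer.
ETS_VARIANT_OCTAMER = "CAGGATGT"


@dataclass(frozen=True)
class MotifHit:
    """One match of a degenerate word.

    ``start``/``end`` are the 0-based half-open footprint on the forward
    strand of the scanned sequence, regardless of the strand of the match.
    """

    region_id: str
    motif_id: str
    strand: str
    start: int
    end: int

    @property
    def centre(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class HexamerCountSummary:
    """Per-region non-overlapping site counts for one octamer family."""

    octamer: str
    counts: dict[str, int]

    @property
    def total_sites(self) -> int:
        return sum(self.counts.values())

    @property
    def total_regions(self) -> int:
        return len(self.counts)

    def histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for c in self.counts.values():
            hist[c] = hist.get(c, 0) + 1
        return hist

    def rate_with_sites(self) -> float:
        if not self.counts:
            raise ValueError("empty summary")
        return sum(1 for c in self.counts.values() if c > 0) / len(self.counts)


@dataclass(frozen=True)
class ModuleCall:
    """An ETS-SRF composite module near a peak summit."""

    region_id: str
    ets_hit: MotifHit
    srf_hit: MotifHit
    summit_dist_ets: float
    summit_dist_srf: float
    pair_dist: float


def _validate_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC characters in pattern: {sorted(bad)}")
    if not pattern:
        raise ValueError("empty pattern")
    return pattern


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return seq


def _scan_forward(seq: str, pattern: str) -> list[int]:
    """Start positions of all (overlapping) matches of an IUPAC pattern.

    An N in the sequence matches nothing except a pattern N (an ambiguous
    base cannot be asserted to match a constrained code).
    """
    m = len(pattern)
    n = len(seq)
    if m > n:
        return []
    allowed = [IUPAC[c] for c in pattern]
    starts = []
    for i in range(n - m + 1):
        ok = True
        for j in range(m):
            base = seq[i + j]
            if base == "N":
                if pattern[j] != "N":
                    ok = False
                    break
            elif base not in allowed[j]:
                ok = False
                break
        if ok:
            starts.append(i)
    return starts


def count_iupac(
    seq: str, pattern: str, region_id: str = "", motif_id: str | None = None,
    strands: str = "both",
) -> list[MotifHit]:
    """All (possibly overlapping) matches of an IUPAC word in a sequence.

    With ``strands="both"`` the reverse complement of the pattern is also
    scanned on the forward sequence and matches reported on strand ``-`` with
    forward-strand footprints. A footprint matching on both strands (as every
    match of a palindromic pattern does) is collapsed to a single ``+`` hit.
    """
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    pattern = _validate_pattern(pattern)
    seq = _validate_seq(seq)
    motif_id = motif_id if motif_id is not None else pattern
    m = len(pattern)

    fwd = set(_scan_forward(seq, pattern))
    hits = [MotifHit(region_id, motif_id, "+", s, s + m) for s in sorted(fwd)]
    if strands == "both":
        rev = _scan_forward(seq, revcomp(pattern))
        hits += [
            MotifHit(region_id, motif_id, "-", s, s + m) for s in rev if s not in fwd
        ]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def hexamer_derivatives(octamer: str) -> list[str]:
    """The (deduplicated) three hexamer substrings of an octamer consensus."""
    octamer = octamer.upper()
    if len(octamer) != 8:
        raise ValueError(f"octamer must have length 8, got {len(octamer)}")
    seen = []
    for i in range(3):
        h = octamer[i : i + 6]
        if h not in seen:
            seen.append(h)
    return seen


def count_hexamer_sites(
    seq: str, octamer: str, region_id: str = "", strands: str = "both",
    invert: bool = False,
) -> tuple[int, list[MotifHit]]:
    """Count non-overlapping hexamer-derivative sites of an octamer consensus.

    All hits of the three derivative hexamers are collected (both strands by
    default), duplicate footprints collapsed, and sites selected greedily left
    to right by footprint start; a hit overlapping an already selected
    footprint — on either strand — is skipped. With ``invert=True`` the
    reversed octamer string is used instead (the background control, distinct
    from the reverse complement which both-strand scanning already covers).
    """
    if invert:
        octamer = octamer[::-1]
    hexamers = hexamer_derivatives(octamer)
    all_hits: list[MotifHit] = []
    for hx in hexamers:
        all_hits.extend(count_iupac(seq, hx, region_id=region_id, motif_id=hx, strands=strands))
    # collapse identical footprints across hexamers/strands (+ wins over -)
    by_fp: dict[tuple[int, int], MotifHit] = {}
    for h in sorted(all_hits, key=lambda h: (h.start, h.strand, h.motif_id)):
        by_fp.setdefault((h.start, h.end), h)
    ordered = [by_fp[k] for k in sorted(by_fp)]
    selected: list[MotifHit] = []
    last_end = -1
    for h in ordered:
        if h.start >= last_end:
            selected.append(h)
            last_end = h.end
    return len(selected), selected


def per_region_count_distribution(
    sequences: dict[str, str], octamer: str, strands: str = "both", invert: bool = False,
) -> HexamerCountSummary:
    """Apply :func:`count_hexamer_sites` to every region sequence.

    ``sequences`` maps region_id -> DNA string. Regions whose sequence fails
    validation are excluded (and reported via the returned summary's absence).
    """
    counts: dict[str, int] = {}
    for region_id, seq in sequences.items():
        n, _ = count_hexamer_sites(seq, octamer, region_id=region_id,
                                   strands=strands, invert=invert)
        counts[region_id] = n
    return HexamerCountSummary(octamer=octamer[::-1] if invert else octamer, counts=counts)


def call_ets_srf_modules(
    seq: str,
    summit_in_region: int,
    region_id: str = "",
    ets_patterns: list[str] | None = None,
    srf_pattern: str = SRF_CARG_PATTERN,
    summit_window: float = 100.0,
    pair_max: float = 50.0,
    strands: str = "both",
) -> list[ModuleCall]:
    """All ETS/SRF hit pairs forming a composite module around the summit.

    A module is an ETS site and an SRF site both with centre within
    ``summit_window`` bp of the peak summit, and with centre-to-centre
    distance strictly less than ``pair_max`` bp. ``ets_patterns`` defaults to
    the union of the derivative hexamers of the strong and variant ETS
    octamers.
    """
    if not (0 <= summit_in_region < len(seq)):
        raise ValueError("summit outside region sequence")
    if ets_patterns is None:
        ets_patterns = sorted(
            set(hexamer_derivatives(ETS_STRONG_OCTAMER))
            | set(hexamer_derivatives(ETS_VARIANT_OCTAMER))
        )
    ets_hits: list[MotifHit] = []
    for p in ets_patterns:
        ets_hits.extend(count_iupac(seq, p, region_id=region_id, motif_id=f"ETS:{p}", strands=strands))
    srf_hits = count_iupac(seq, srf_pattern, region_id=region_id,
                           motif_id=f"SRF:{srf_pattern}", strands=strands)
    modules = []
    for e in ets_hits:
        d_e = abs(e.centre - summit_in_region)
        if d_e > summit_window:
            continue
        for s in srf_hits:
            d_s = abs(s.centre - summit_in_region)
            if d_s > summit_window:
                continue
            pair = abs(e.centre - s.centre)
            if pair < pair_max:
                modules.append(ModuleCall(region_id, e, s, d_e, d_s, pair))
    return modules


def motif_class_compare(
    n_with_unique: int, n_unique: int, n_with_redundant: int, n_redundant: int,
) -> ContingencyResult:
    """2x2 class-vs-feature comparison (e.g. SRF-motif presence by binding mode).

    Rows are the two region classes; columns are feature-present vs absent.
    Delegates to the shared chi-square/Fisher machinery.
    """
    if n_unique == 0 or n_redundant == 0:
        raise ValueError("both region classes must be non-empty")
    table = (
        (n_with_unique, n_unique - n_with_unique),
        (n_with_redundant, n_redundant - n_with_redundant),
    )
    return test_2x2(table)
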