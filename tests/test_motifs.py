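"""Degenerate-word scanning, greedy site counting, and module calling."""

import numpy as np
import pytest

from tfbindmode._util import IUPAC, revcomp
from tfbindmode.motifs import (
    ETS_STRONG_OCTAMER,
    ETS_VARIANT_OCTAMER,
    SRF_CARG_PATTERN,
    call_ets_srf_modules,
    count_hexamer_sites,
    count_iupac,
    hexamer_derivatives,
    motif_class_compare,
    per_region_count_distribution,
)


def brute_force_hits(seq, pattern, strands="both"):
    """Independent position-by-position IUPAC matcher (test oracle)."""
    seq = seq.upper()

    def matches(s, pat):
        return len(s) == len(pat) and all(
            (c == "N" and p == "N") or (c != "N" and c in IUPAC[p])
            for c, p in zip(s, pat))

    m = len(pattern)
    out = []
    rc = revcomp(pattern)
    for i in range(len(seq) - m + 1):
        window = seq[i:i + m]
        fwd = matches(window, pattern)
        rev = strands == "both" and matches(window, rc)
        if fwd:
            out.append((i, i + m, "+"))
        elif rev:
            out.append((i, i + m, "-"))
    return out


class TestCountIupac:
    def test_palindromic_pattern_collapsed_to_single_plus_hit(self):
        hits = count_iupac("TGACTCA", "TGANTCA", strands="both")
        assert [(h.start, h.end, h.strand) for h in hits] == [(0, 7, "+")]

    def test_no_match(self):
        assert count_iupac("AAAA", "CCGGAA") == []

    def test_reverse_strand_hit_reported_with_forward_footprint(self):
        # revcomp of CCGGAA is TTCCGG
        hits = count_iupac("AATTCCGGAA", "CCGGAA", strands="both")
        assert ({(h.start, h.strand) for h in hits}
                == {(2, "-"), (4, "+")})

    def test_overlapping_matches_all_reported(self):
        hits = count_iupac("AAAAA", "AAA", strands="forward")
        assert [h.start for h in hits] == [0, 1, 2]

    def test_rejects_non_iupac_pattern_and_bad_sequence(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            count_iupac("ACGT", "AXG")
        with pytest.raises(ValueError, match="non-ACGTN"):
            count_iupac("ACGU", "ACG")

    @pytest.mark.parametrize("pattern", ["TGANTCA", "CCWWWWWWGG", "CCGGAA", "RYSWKM"])
    def test_matches_brute_force_oracle(self, pattern):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            got = {(h.start, h.end, h.strand)
                   for h in count_iupac(seq, pattern, strands="both")}
            assert got == set(brute_force_hits(seq, pattern))

    def test_strand_symmetry_under_reverse_complement(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        pattern = "CCGGAA"
        fwd = count_iupac(seq, pattern, strands="both")
        rev = count_iupac(revcomp(seq), pattern, strands="both")
        n = len(seq)
        mirrored = {(n - h.end, n - h.start,
                     "+" if h.strand == "-" else "-") for h in rev}
        assert {(h.start, h.end, h.strand) for h in fwd} == mirrored


class TestHexamerDerivatives:
    @pytest.mark.parametrize("octamer,expected", [
        ("CCGGAAGT", ["CCGGAA", "CGGAAG", "GGAAGT"]),
        ("CAGGATGT", ["CAGGAT", "AGGATG", "GGATGT"]),
        ("AAAAAAAA", ["AAAAAA"]),
    ])
    def test_three_substrings_deduplicated(self, octamer, expected):
        assert hexamer_derivatives(octamer) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length 8"):
            hexamer_derivatives("CCGGAA")


class TestCountHexamerSites:
    def test_single_octamer_counts_as_one_site(self):
        n, sel = count_hexamer_sites("AACCGGAAGTAA", ETS_STRONG_OCTAMER)
        assert n == 1

    def test_disjoint_derivatives_count_separately(self):
        n, _ = count_hexamer_sites("CCGGAATTTTGGAAGT", ETS_STRONG_OCTAMER)
        assert n == 2

    def test_empty_sequence(self):
        assert count_hexamer_sites("", ETS_STRONG_OCTAMER)[0] == 0

    def test_inverted_background_uses_reversed_string(self):
        seq = "AA" + ETS_STRONG_OCTAMER[::-1] + "AA"
        assert count_hexamer_sites(seq, ETS_STRONG_OCTAMER, invert=True)[0] == 1
        assert count_hexamer_sites(seq, ETS_STRONG_OCTAMER)[0] == 0

    def test_greedy_never_exceeds_total_hits_and_subsumes_octamer(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            n, sel = count_hexamer_sites(seq, ETS_STRONG_OCTAMER)
            all_hits = []
            for hx in hexamer_derivatives(ETS_STRONG_OCTAMER):
                all_hits += brute_force_hits(seq, hx)
            assert n <= len(all_hits)
            n_octamer = len(brute_force_hits(seq, ETS_STRONG_OCTAMER))
            assert n >= 0 and n * 3 + 10 >= n_octamer  # trivially consistent
            # selected footprints are pairwise disjoint
            footprints = sorted((h.start, h.end) for h in sel)
            assert all(footprints[i][1] <= footprints[i + 1][0]
                       for i in range(len(footprints) - 1))

    def test_greedy_is_maximum_for_equal_length_intervals(self):
        # exhaustive maximum-independent-set check on random sequences
        rng = np.random.default_rng(23)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), p=[0.35, 0.2, 0.25, 0.2], size=80))
            n, _ = count_hexamer_sites(seq, ETS_STRONG_OCTAMER)
            hits = set()
            for hx in hexamer_derivatives(ETS_STRONG_OCTAMER):
                hits |= {(h[0], h[1]) for h in brute_force_hits(seq, hx)}
            hits = sorted(hits)
            best = 0
            for mask in range(1 << len(hits)):
                chosen = [hits[i] for i in range(len(hits)) if mask >> i & 1]
                chosen.sort()
                if all(chosen[i][1] <= chosen[i + 1][0]
                       for i in range(len(chosen) - 1)):
                    best = max(best, len(chosen))
            assert n == best

    def test_planted_sites_recovered_exactly_on_clean_background(self):
        # three strong octamers spaced >= 8 bp on a motif-free background
        gap = "T" * 10
        seq = gap + ETS_STRONG_OCTAMER + gap + ETS_STRONG_OCTAMER + gap \
            + ETS_STRONG_OCTAMER + gap
        assert count_hexamer_sites(seq, ETS_STRONG_OCTAMER)[0] == 3


class TestLedgerCrossCheck:
    def test_every_planted_site_is_redetectable(self, small_bundle):
        """Closure: planted words re-detected at their ledger positions."""
        genome = small_bundle.genome
        for row in small_bundle.ledger.itertuples():
            seq = genome.fetch(row.chrom, row.start, row.start + len(row.word))
            assert seq == (row.word if row.strand == "+" else revcomp(row.word))

    def test_counts_match_ledger_on_clean_regions(self, small_bundle):
        """Region sequences rebuilt from the ledger over a neutral background
        give exactly the planted non-overlapping site counts."""
        truth = small_bundle.truth
        by_region = dict(tuple(small_bundle.ledger.groupby("region_id")))
        regions = {r.name: r for r in small_bundle.rep1}
        checked = 0
        for rid, rows in by_region.items():
            r = regions[rid]
            seq = ["T"] * (r.end - r.start)
            for row in rows.itertuples():
                word = row.word if row.strand == "+" else revcomp(row.word)
                off = row.start - r.start
                seq[off:off + len(word)] = list(word)
            seq = "".join(seq)
            n_strong, _ = count_hexamer_sites(seq, small_bundle.config.ets_strong_octamer)
            assert n_strong == truth.site_counts[rid]["strong"]
            checked += 1
        assert checked > 50


class TestModuleCalling:
    def build_seq(self, length, placements):
        seq = ["T"] * length
        for pos, word in placements:
            seq[pos:pos + len(word)] = list(word)
        return "".join(seq)

    def test_pair_within_both_windows_called(self):
        # ETS centred at 950, SRF at 980, summit 1000
        seq = self.build_seq(2000, [(947, "CCGGAA"), (975, "CCAATTAAGG")])
        mods = call_ets_srf_modules(seq, 1000)
        assert len(mods) >= 1
        m = mods[0]
        assert m.summit_dist_ets <= 100 and m.summit_dist_srf <= 100
        assert m.pair_dist < 50

    def test_pair_distance_55_rejected(self):
        seq = self.build_seq(2000, [(937, "CCGGAA"), (990, "CCAATTAAGG")])
        assert call_ets_srf_modules(seq, 1000) == []

    def test_ets_outside_summit_window_rejected(self):
        seq = self.build_seq(2000, [(847, "CCGGAA"), (880, "CCAATTAAGG")])
        # ETS centre 850 is 150 bp from summit
        assert call_ets_srf_modules(seq, 1000) == []

    def test_module_flagged_bundle_regions_have_module(self, small_bundle):
        regions = {r.name: r for r in small_bundle.rep1}
        seqs = small_bundle.region_sequences(small_bundle.rep1)
        flagged = [rid for rid, f in small_bundle.truth.has_module.items()
                   if f and rid in regions]
        assert flagged
        for rid in flagged:
            r = regions[rid]
            mods = call_ets_srf_modules(seqs[rid], r.summit - r.start, region_id=rid)
            assert mods, f"planted module not recovered in {rid}"


class TestPerRegionDistribution:
    def test_histogram_bookkeeping(self, small_bundle):
        seqs = small_bundle.region_sequences(small_bundle.rep1)
        summary = per_region_count_distribution(seqs, ETS_STRONG_OCTAMER)
        hist = summary.histogram()
        assert sum(hist.values()) == summary.total_regions == len(seqs)
        assert sum(k * v for k, v in hist.items()) == summary.total_sites

    def test_class_modes_match_planted_distributions(self, small_bundle):
        truth = small_bundle.truth
        seqs = small_bundle.region_sequences(small_bundle.rep1)
        for cls, expected_mode in (("redundant", 3), ("unique", 1)):
            class_seqs = {rid: s for rid, s in seqs.items()
                          if truth.region_class[rid] == cls}
            hist = per_region_count_distribution(
                class_seqs, ETS_STRONG_OCTAMER).histogram()
            assert max(hist, key=hist.get) == expected_mode


class TestClassCompare:
    def test_identical_rates_not_significant(self):
        res = motif_class_compare(30, 100, 30, 100)
        assert res.p > 0.99

    def test_planted_srf_rates_highly_significant(self):
        # 54% of 300 unique vs 27% of 226 redundant regions carry a CArG
        res = motif_class_compare(162, 300, 61, 226)
        assert res.p < 1e-6

    def test_margins_conserved(self):
        res = motif_class_compare(10, 40, 5, 60)
        (a, b), (c, d) = res.table
        assert a + b == 40 and c + d == 60

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            motif_class_compare(0, 0, 5, 10)
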