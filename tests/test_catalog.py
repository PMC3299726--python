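"""Catalog construction: parsers, the native detector, and exclusion filters."""

import io
import itertools

import pytest

from microsat import catalog as cat
from conftest import mk_locus, random_seq

# ---------------------------------------------------------------------------
# Brute-force oracle for the detector: exhaustively score every substring at
# one unit size and return the best interval (score, then length, leftmost).
# ---------------------------------------------------------------------------

def brute_score(seq: str, s: int, e: int, u: int) -> int:
    m = sum(1 for i in range(s + u, e) if seq[i] == seq[i - u])
    mm = (e - s - u) - m
    return 2 * (u + m) - 5 * mm


def brute_best_interval(seq: str, u: int, lo: int = 0, hi: int | None = None):
    hi = len(seq) if hi is None else hi
    best = None
    for s in range(lo, hi):
        for e in range(s + u + 1, hi + 1):
            sc = brute_score(seq, s, e, u)
            key = (sc, e - s, -s)
            if best is None or key > best[0]:
                best = (key, (s, e, sc))
    return best[1] if best else None


# ---------------------------------------------------------------------------
# TRF .dat parsing
# ---------------------------------------------------------------------------

TRF_RECORD = (
    "10 23 2 7.0 2 95 0 24 50 0 0 50 1.00 AC ACACACACACACAT A B\n"
)


class TestParseTrfDat:
    def test_empty_stream(self):
        assert cat.parse_trf_dat(io.StringIO("")) == []

    def test_single_record_coordinates_and_purity(self):
        body = "Sequence: chr1\n" + TRF_RECORD
        (locus,) = cat.parse_trf_dat(body)
        # TRF 1-based inclusive [10, 23] -> 0-based half-open [9, 23)
        assert (locus.chrom, locus.start, locus.end) == ("chr1", 9, 23)
        assert locus.unit_length == 2
        assert locus.unit == "AC"
        assert locus.purity == pytest.approx(0.95)
        assert locus.ref_length == 14

    def test_period_above_max_dropped(self):
        body = (
            "Sequence: chr1\n"
            "10 27 6 3.0 6 95 0 30 50 0 0 50 1.00 ACGTAG ACGTAGACGTAGACGTAG A B\n"
        )
        assert cat.parse_trf_dat(body) == []

    def test_malformed_record_names_line(self):
        body = "Sequence: chr1\n10 23 2\n"
        with pytest.raises(ValueError, match="line 2"):
            cat.parse_trf_dat(body)

    def test_unknown_header_with_naming_map(self):
        body = "Sequence: weird\n" + TRF_RECORD
        with pytest.raises(ValueError, match="weird"):
            cat.parse_trf_dat(body, chrom_names={"chr1": "2L"})

    def test_naming_map_applied(self):
        body = "Sequence: gi123\n" + TRF_RECORD
        (locus,) = cat.parse_trf_dat(body, chrom_names={"gi123": "2L"})
        assert locus.chrom == "2L"

    def test_preamble_lines_skipped(self):
        body = (
            "Tandem Repeats Finder Program\n\n"
            "Sequence: chr1\n"
            "Parameters: 2 5 5 80 10 14 5\n" + TRF_RECORD
        )
        assert len(cat.parse_trf_dat(body)) == 1


# ---------------------------------------------------------------------------
# Native detector
# ---------------------------------------------------------------------------

class TestFindTandemRepeats:
    def test_perfect_dinucleotide_in_random_flanks(self, rng):
        from conftest import reference_with_tract

        ref, locus = reference_with_tract(rng, unit="AC", tract_len=14)
        hits = cat.find_tandem_repeats(ref["chr1"], "chr1")
        match = [h for h in hits if (h.start, h.end) == (locus.start, locus.end)]
        assert len(match) == 1
        assert match[0].unit == "AC"
        assert match[0].ref_length == 14
        assert match[0].purity == 1.0

    def test_seven_base_mononucleotide_is_shortest_reported(self):
        # isolated runs: 6 bases score 12 (below threshold), 7 bases score 14
        flank = "GCGTCGTGCGTC"
        for n, expect in [(6, 0), (7, 1)]:
            seq = flank + "A" * n + flank[::-1]
            hits = [
                h
                for h in cat.find_tandem_repeats(seq, "c")
                if h.unit == "A" and h.start == len(flank)
            ]
            assert len(hits) == expect, f"run of {n}"

    def test_imperfect_purity_matches_oracle(self):
        seq = "ACGTACGGACGT"
        hits = cat.find_tandem_repeats(seq, "c", min_score=1, dedup=False)
        h4 = max((h for h in hits if h.unit_length == 4), key=lambda h: h.score)
        s, e, sc = brute_best_interval(seq, 4)
        assert (h4.start, h4.end) == (s, e)
        assert h4.score == sc
        m = sum(1 for i in range(s + 4, e) if seq[i] == seq[i - 4])
        assert h4.purity == pytest.approx(m / (e - s - 4))
        assert h4.purity < 1.0

    def test_matches_brute_force_on_random_sequences(self, rng):
        """On short random sequences with one planted repeat, the detector's
        hit for the planted unit equals the exhaustive argmax interval."""
        from conftest import reference_with_tract

        for trial in range(25):
            u = int(rng.integers(1, 6))
            unit = "".join(rng.choice(list("ACGT"), size=u))
            if len(set(unit)) == 1:
                unit = "A"
                u = 1
            L = int(rng.integers(max(7, u + 2), 30))
            ref, locus = reference_with_tract(
                rng, unit=unit, tract_len=L, left=40, right=40
            )
            seq = ref["chr1"]
            s, e, sc = brute_best_interval(seq, u, lo=20, hi=min(len(seq), 60 + L))
            hits = [
                h
                for h in cat.find_tandem_repeats(seq, "c", dedup=False)
                if h.unit_length == u and not (h.end <= s or h.start >= e)
            ]
            best = max(hits, key=lambda h: (h.score, h.end - h.start, -h.start))
            assert (best.start, best.end, best.score) == (s, e, sc)

    def test_n_bases_always_mismatch(self):
        seq = "GTCGA" + "ANAAAAAA" + "TCGTC"
        hits = [h for h in cat.find_tandem_repeats(seq, "c") if h.unit == "A"]
        # the N splits the run; only the 6 A's right of it come close, and
        # with the leading base they reach 7 aligned positions
        for h in hits:
            assert "N" not in seq[h.start : h.end] or h.purity < 1.0


class TestDeduplicateHits:
    def test_exact_duplicates_collapse(self):
        a = mk_locus(start=10, end=24, unit="AC")
        b = mk_locus(start=10, end=24, unit="AC")
        assert len(cat.deduplicate_hits([a, b])) == 1

    def test_nested_keeps_higher_score(self):
        inner = mk_locus(start=12, end=20, unit="AC", score=20)
        outer = mk_locus(start=10, end=30, unit="AG", score=40)
        kept = cat.deduplicate_hits([inner, outer])
        assert kept == [outer]

    def test_disjoint_same_unit_both_survive(self):
        a = mk_locus(start=10, end=24, unit="AC")
        b = mk_locus(start=100, end=114, unit="AC")
        assert len(cat.deduplicate_hits([a, b])) == 2

    def test_overlap_different_units_both_survive(self):
        a = mk_locus(start=10, end=24, unit="AC", score=28)
        b = mk_locus(start=20, end=30, unit="AAG", score=20)
        assert len(cat.deduplicate_hits([a, b])) == 2

    def test_equal_interval_tie_prefers_smaller_unit(self):
        a = mk_locus(start=10, end=24, unit="AC", score=28)
        b = mk_locus(start=10, end=24, unit="ACAC", score=28)
        kept = cat.deduplicate_hits([a, b])
        assert kept == [a]

    def test_output_sorted(self):
        a = mk_locus(start=100, end=114, unit="AC")
        b = mk_locus(start=10, end=24, unit="AG")
        assert [h.start for h in cat.deduplicate_hits([a, b])] == [10, 100]


# ---------------------------------------------------------------------------
# RepeatMasker / BED annotations
# ---------------------------------------------------------------------------

RM_HEADER = (
    "   SW  perc perc perc  query     position in query    matching repeat\n"
    "score  div. del. ins.  sequence  begin end    (left)  repeat   class/family\n"
    "\n"
)


class TestParseRepeatmasker:
    def test_empty_body(self):
        assert cat.parse_repeatmasker_out(RM_HEADER) == []

    def test_class_filter(self):
        body = RM_HEADER + (
            " 100 1.0 0.0 0.0 chr1 100 200 (500) + ALU Simple_repeat 1 100 (0) 1\n"
            " 200 1.0 0.0 0.0 chr1 300 400 (300) + GYP LTR/Gypsy 1 100 (0) 2\n"
        )
        (iv,) = cat.parse_repeatmasker_out(body)
        assert iv.repeat_class == "LTR/Gypsy"

    def test_coordinate_conversion(self):
        body = RM_HEADER + (
            " 200 1.0 0.0 0.0 chr1 100 200 (300) + GYP LTR/Gypsy 1 100 (0) 2\n"
        )
        (iv,) = cat.parse_repeatmasker_out(body)
        assert (iv.start, iv.end) == (99, 200)

    def test_low_complexity_removed(self):
        body = RM_HEADER + (
            " 50 1.0 0.0 0.0 chr1 10 60 (300) + AT_rich Low_complexity 1 50 (0) 3\n"
        )
        assert cat.parse_repeatmasker_out(body) == []

    def test_bed_dialect_is_zero_based(self):
        (iv,) = cat.parse_repeatmasker_out("chr1\t99\t200\tLTR/Gypsy\n")
        assert (iv.start, iv.end) == (99, 200)

    def test_malformed_row_raises(self):
        with pytest.raises(ValueError, match="line 1"):
            cat.parse_repeatmasker_out("chr1\t99\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

class TestProximityFilter:
    @pytest.mark.parametrize(
        "re_start,re_end,flagged",
        [
            (141, 200, False),  # gap 21 > 20
            (140, 200, True),  # gap 20, boundary case
            (110, 200, True),  # overlap
            (60, 80, True),  # gap 20 on the left
            (59, 79, False),  # gap 21 on the left
        ],
    )
    def test_edge_distance(self, re_start, re_end, flagged):
        locus = mk_locus(start=100, end=120)
        iv = cat.AnnotationInterval("chr1", re_start, re_end, "LTR/Gypsy")
        cat.filter_near_repetitive_elements([locus], [iv], 20)
        assert (cat.FLAG_RE_PROXIMAL in locus.flags) is flagged

    def test_other_chromosome_ignored(self):
        locus = mk_locus(start=100, end=120)
        iv = cat.AnnotationInterval("chr2", 100, 120, "LTR/Gypsy")
        cat.filter_near_repetitive_elements([locus], [iv], 20)
        assert not locus.flags


class TestHeterochromatinAndPurity:
    def test_het_chromosome_flagged(self):
        locus = mk_locus(chrom="2RHet")
        cat.exclude_heterochromatin([locus], {"2RHet", "U"})
        assert cat.FLAG_HETEROCHROMATIC in locus.flags

    def test_euchromatic_arm_unflagged(self):
        locus = mk_locus(chrom="2L")
        cat.exclude_heterochromatin([locus], {"2RHet", "U"})
        assert not locus.flags

    def test_empty_het_set(self):
        locus = mk_locus(chrom="2RHet")
        cat.exclude_heterochromatin([locus], set())
        assert not locus.flags

    def test_default_het_names(self):
        names = ["2L", "2LHet", "3R", "U", "X", "XHet"]
        assert cat.default_het_chroms(names) == {"2LHet", "U", "XHet"}

    @pytest.mark.parametrize(
        "purity,flagged", [(0.80, False), (0.79, True), (1.0, False)]
    )
    def test_purity_floor_inclusive(self, purity, flagged):
        locus = mk_locus(purity=purity)
        cat.apply_purity_floor([locus], 0.80)
        assert (cat.FLAG_LOW_PURITY in locus.flags) is flagged


def test_filter_composition_is_order_independent():
    """RE-proximity, heterochromatin and purity flags commute."""
    res = [cat.AnnotationInterval("chr1", 130, 200, "LTR/Gypsy")]

    def build():
        return [
            mk_locus(chrom="chr1", start=100, end=120, purity=0.85),
            mk_locus(chrom="chr1", start=300, end=320, purity=0.75),
            mk_locus(chrom="chr1Het", start=100, end=120, purity=1.0),
            mk_locus(chrom="chr2", start=50, end=64, purity=1.0),
        ]

    filters = {
        "re": lambda ls: cat.filter_near_repetitive_elements(ls, res, 20),
        "het": lambda ls: cat.exclude_heterochromatin(ls, {"chr1Het"}),
        "pur": lambda ls: cat.apply_purity_floor(ls, 0.80),
    }
    outcomes = set()
    for order in itertools.permutations(filters):
        loci = build()
        for name in order:
            filters[name](loci)
        outcomes.add(tuple(frozenset(l.flags) for l in loci))
    assert len(outcomes) == 1
    flags = [set(f) for f in next(iter(outcomes))]
    assert flags == [
        {cat.FLAG_RE_PROXIMAL},
        {cat.FLAG_LOW_PURITY},
        {cat.FLAG_HETEROCHROMATIC},
        set(),
    ]


# ---------------------------------------------------------------------------
# I/O round trips and bookkeeping
# ---------------------------------------------------------------------------

def test_catalog_tsv_round_trip(tmp_path, rng):
    seq = random_seq(rng, 300) + "ACACACACACACAC" + random_seq(rng, 300)
    loci = cat.find_tandem_repeats(seq, "chr1")
    cat.apply_purity_floor(loci, 0.95)
    path = tmp_path / "catalog.tsv"
    cat.write_catalog_tsv(loci, path)
    back = cat.read_catalog_tsv(path)
    assert len(back) == len(loci)
    for a, b in zip(loci, back):
        assert (a.locus_id, a.chrom, a.start, a.end, a.unit, a.flags) == (
            b.locus_id,
            b.chrom,
            b.start,
            b.end,
            b.unit,
            b.flags,
        )
        assert a.purity == pytest.approx(b.purity)
    # second round trip is the identity
    path2 = tmp_path / "catalog2.tsv"
    cat.write_catalog_tsv(back, path2)
    assert path.read_text() == path2.read_text()


def test_per_chromosome_totals_sum_to_genome_total():
    from microsat.simdata import SimConfig, simulate_reference

    cfg = SimConfig(seed=42, n_chromosomes=3, n_loci_per_unit=6, perfect_fraction=1.0)
    ref = simulate_reference(cfg)
    per_chrom = {
        chrom: len(cat.find_tandem_repeats(seq, chrom))
        for chrom, seq in ref.sequences.items()
    }
    all_hits = sum(
        len(cat.find_tandem_repeats(seq, chrom))
        for chrom, seq in ref.sequences.items()
    )
    assert sum(per_chrom.values()) == all_hits
    assert all_hits >= len(ref.loci)
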