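import random
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jittertag.barcode_model import (
    ExpectedPosition,
    MatchParams,
    MatchStatus,
    Whitelist,
)
from jittertag.matcher_set import (
    CapacityError,
    SetMatcher,
    build_mismatch_index,
    estimate_variant_count,
    extract_query_window,
    hamming,
    match_barcode_direct,
    match_barcode_set,
)

from conftest import hit_tuple, oracle_match, random_read, random_whitelist

_BASES = "ACGT"


def _all_kmers(n):
    return ["".join(p) for p in product(_BASES, repeat=n)]


class TestMismatchIndex:
    def test_m0_identity(self):
        wl = Whitelist("bc", ["ACGT"])
        idx = build_mismatch_index(wl, 0)
        assert len(idx) == 1
        assert idx.lookup("ACGT") == (0, ("ACGT",))
        assert idx.lookup("ACGA") is None

    def test_variant_count_m1(self):
        # {AA}, m=1 -> 1 + 2*3 = 7 variants (verified by brute force below)
        wl = Whitelist("bc", ["AA"])
        idx = build_mismatch_index(wl, 1)
        assert len(idx) == 7
        brute = [s for s in _all_kmers(2) if hamming(s, "AA") <= 1]
        assert len(brute) == 7
        for s in brute:
            d, bcs = idx.lookup(s)
            assert d == hamming(s, "AA") and bcs == ("AA",)

    def test_shared_variant_records_both_origins(self):
        # brute force over all 16 2-mers: "AC" is at distance 1 of both
        wl = Whitelist("bc", ["AA", "AT"])
        idx = build_mismatch_index(wl, 1)
        for s in _all_kmers(2):
            dists = {bc: hamming(s, bc) for bc in wl.barcodes}
            dmin = min(dists.values())
            expected = tuple(sorted(b for b, d in dists.items() if d == dmin))
            got = idx.lookup(s)
            if dmin > 1:
                assert got is None
            else:
                assert got == (dmin, expected)
        assert idx.lookup("AC") == (1, ("AA", "AT"))

    def test_insertion_order_independent(self):
        a = build_mismatch_index(Whitelist("bc", ["ACGT", "TTTT"]), 1)
        b = build_mismatch_index(Whitelist("bc", ["TTTT", "ACGT"]), 1)
        for s in _all_kmers(4):
            assert a.lookup(s) == b.lookup(s)

    def test_capacity_cap_recommends_trie(self):
        wl = Whitelist("bc", ["ACGTACGTACGTACGT"])
        with pytest.raises(CapacityError, match="trie"):
            build_mismatch_index(wl, 2, variant_cap=10)

    def test_estimate(self):
        assert estimate_variant_count(1, 2, 1) == 7
        assert estimate_variant_count(96, 8, 1) == 96 * (1 + 24)

    def test_m_at_least_n_rejected(self):
        with pytest.raises(ValueError):
            build_mismatch_index(Whitelist("bc", ["ACGT"]), 4)

    def test_lookup_rejects_n(self):
        idx = build_mismatch_index(Whitelist("bc", ["ACGT"]), 1)
        assert idx.lookup("ACGN") is None


class TestQueryWindow:
    def test_worked_example_start10_jitter2(self):
        win = extract_query_window("A" * 30, 10, 4, 2)
        assert [c.start for c in win.candidates] == [8, 9, 10, 11, 12]
        assert len(win.candidates) == 5

    def test_left_edge_padding(self):
        win = extract_query_window("ACGTACGTACGTACGTACGT", 1, 4, 1)
        first = win.candidates[0]
        assert first.start == 0
        assert first.seq == "N" + "ACG"
        assert first.pad_count == 1

    def test_right_edge_padding(self):
        win = extract_query_window("ACGTAC", 5, 4, 1)
        mid = win.at_offset(0)
        assert mid.seq == "AC" + "NN" and mid.pad_count == 2
        last = win.candidates[-1]
        assert last.seq == "C" + "NNN" and last.pad_count == 3

    def test_fully_outside_is_all_n(self):
        win = extract_query_window("ACGT", 20, 4, 1)
        assert all(c.seq == "NNNN" and c.pad_count == 4 for c in win.candidates)
        win = extract_query_window("ACGT", -10, 4, 1)
        assert all(c.seq == "NNNN" and c.pad_count == 4 for c in win.candidates)

    def test_degenerate_x0(self):
        win = extract_query_window("ACGTACGT", 3, 4, 0)
        assert len(win.candidates) == 1
        assert win.candidates[0].seq == "GTAC"

    def test_scan_order_upstream_first(self):
        win = extract_query_window("A" * 30, 10, 4, 2)
        assert [c.offset for c in win.scan_order()] == [0, -1, 1, -2, 2]

    @settings(max_examples=100, deadline=None)
    @given(
        st.integers(1, 12),
        st.integers(0, 4),
        st.integers(-5, 40),
        st.integers(1, 30),
    )
    def test_window_invariants(self, n, x, expected_start, read_len):
        read = "A" * read_len
        win = extract_query_window(read, expected_start, n, x)
        assert len(win.candidates) == 2 * x + 1
        assert [c.start for c in win.candidates] == list(
            range(expected_start - x, expected_start + x + 1)
        )
        for c in win.candidates:
            assert len(c.seq) == n
            assert c.pad_count == c.seq.count("N")


def _ep(start):
    return ExpectedPosition("wl", 1, max(start, 1), 1.0)


class TestMatchBarcodeSet:
    def setup_method(self):
        self.wl = Whitelist("wl", ["ACGTACGT", "TTTTCCCC", "GGGGAAAA"])
        self.params = MatchParams(jitter=1, max_mismatches=1)
        self.matcher = SetMatcher(self.wl, self.params)

    def test_exact_at_expected_start(self):
        read = "GG" + "ACGTACGT" + "GGGGG"
        hit = self.matcher.match(read, 3)
        assert hit.status is MatchStatus.EXACT
        assert (hit.barcode, hit.mismatches, hit.offset) == ("ACGTACGT", 0, 0)

    def test_perfect_match_beats_closer_mismatch(self):
        # offset 0 candidate "TACGTACG" is 1 mismatch from AACGTACG, while
        # the perfect ACGTACGT starts one base downstream (offset +1)
        wl = Whitelist("wl", ["AACGTACG", "ACGTACGT"])
        matcher = SetMatcher(wl, MatchParams(jitter=1, max_mismatches=1))
        read = "G" + "TACGTACGT" + "GG"
        hit = matcher.match(read, 2)
        assert hit.status is MatchStatus.EXACT
        assert hit.offset == 1 and hit.barcode == "ACGTACGT"
        assert hit_tuple(hit) == oracle_match(read, 2, wl.barcodes, 1, 1)

    def test_equal_rank_distinct_barcodes_is_ambiguous(self):
        # two distinct barcodes each at 1 mismatch, offsets -1 and +1
        wl = Whitelist("wl", ["AAAA", "TTTT"])
        matcher = SetMatcher(wl, MatchParams(jitter=1, max_mismatches=1))
        # expected start 2: offset -1 "AAAT" (1mm vs AAAA), offset +1 "ATTT"
        # (1mm vs TTTT), offset 0 "AATT" (2mm vs both) -> tie of distinct
        # barcodes at (1 mismatch, |offset| 1)
        read = "AAATTT"
        hit = matcher.match(read, 2)
        oracle = oracle_match(read, 2, wl.barcodes, 1, 1)
        assert hit_tuple(hit) == oracle
        assert oracle[0] == "ambiguous_null"

    def test_same_barcode_tie_prefers_upstream(self):
        wl = Whitelist("wl", ["AAAA"])
        matcher = SetMatcher(wl, MatchParams(jitter=1, max_mismatches=0))
        read = "AAAAA"  # exact at offsets -1 and +1 around start 2... and 0
        hit = matcher.match(read, 2)
        assert hit.status is MatchStatus.EXACT and hit.offset == 0
        read2 = "GAAAAG"
        # expected start 3: exact only at offset -1 (start 2)
        hit2 = matcher.match(read2, 3)
        assert hit2.offset == -1

    def test_no_match_null(self):
        hit = self.matcher.match("T" * 20, 3)
        assert hit.status is MatchStatus.NO_MATCH_NULL
        assert hit.barcode == "N" * 8
        assert hit.mismatches == -1 and hit.offset == 0

    def test_edge_truncation_recovered_iff_t_le_m(self):
        bc = "ACGTACGT"
        for t in (0, 1, 2):
            read = bc[t:] + "GGGGGGGG"
            for m in (0, 1, 2):
                matcher = SetMatcher(
                    self.wl, MatchParams(jitter=2, max_mismatches=m)
                )
                hit = matcher.match(read, 1)
                if t <= m:
                    assert not hit.is_null, (t, m)
                    assert hit.barcode == bc and hit.offset == -t
                    assert hit.mismatches == t
                else:
                    assert hit.is_null, (t, m)

    def test_function_form_matches_wrapper(self):
        read = "GGACGTACGTGG"
        hit_fn = match_barcode_set(
            read, _ep(3), self.wl, self.params, self.matcher.index
        )
        assert hit_fn == self.matcher.match(read, 3)


class TestMatchBarcodeDirect:
    def test_n_counts_as_mismatch(self):
        wl = Whitelist("wl", ["ACGT"])
        win = extract_query_window("NCGTAA", 1, 4, 0)
        ranked = match_barcode_direct(win, wl, 1)
        assert ranked == [("ACGT", 1, 0)]

    def test_two_pads_excluded_at_m1(self):
        wl = Whitelist("wl", ["ACGT"])
        win = extract_query_window("NNGTAA", 1, 4, 0)
        assert match_barcode_direct(win, wl, 1) == []

    def test_all_n_never_matches(self):
        wl = Whitelist("wl", ["ACGT"])
        win = extract_query_window("NNNN", 1, 4, 0)
        assert match_barcode_direct(win, wl, 3) == []


class TestOracleEquivalence:
    def test_randomized_against_oracle(self):
        """match_barcode_set equals the brute-force oracle on random small
        instances (including N-containing reads and edge windows)."""
        rng = random.Random(20240901)
        checked = 0
        for _ in range(150):
            n = rng.randint(2, 8)
            wl = random_whitelist(rng, rng.randint(1, 32), n)
            x = rng.randint(0, 3)
            m = rng.randint(0, min(2, n - 1))
            matcher = SetMatcher(wl, MatchParams(jitter=x, max_mismatches=m))
            for _ in range(20):
                read = random_read(
                    rng, rng.randint(n, n + 20), with_n=rng.random() < 0.3
                )
                es = rng.randint(1, len(read))
                got = hit_tuple(matcher.match(read, es))
                want = oracle_match(read, es, wl.barcodes, x, m)
                assert got == want, (read, es, wl.barcodes, x, m)
                checked += 1
        assert checked == 3000

    def test_monotonicity_in_x_and_m(self):
        """Valid-hit counts are non-decreasing in x and m on a fixed set of
        reads carrying shift-guarded barcodes."""
        from jittertag.fixtures import generate_whitelist

        rng = random.Random(7)
        wl = generate_whitelist(
            24, 8, 3, rng_seed=5, max_shift=2, shift_min_hamming=2
        )
        reads = []
        for _ in range(300):
            bc = rng.choice(wl.barcodes)
            off = rng.choice([-1, 0, 0, 1])
            prefix = "".join(rng.choice(_BASES) for _ in range(4 + off))
            suffix = "".join(rng.choice(_BASES) for _ in range(6))
            seq = prefix + bc + suffix
            if rng.random() < 0.3:
                pos = 4 + off + rng.randrange(8)
                seq = (
                    seq[:pos]
                    + rng.choice([b for b in _BASES if b != seq[pos]])
                    + seq[pos + 1 :]
                )
            reads.append(seq)

        def count_valid(x, m):
            matcher = SetMatcher(wl, MatchParams(jitter=x, max_mismatches=m))
            return sum(1 for r in reads if not matcher.match(r, 5).is_null)

        grid = {(x, m): count_valid(x, m) for x in (0, 1, 2) for m in (0, 1)}
        for m in (0, 1):
            assert grid[(0, m)] <= grid[(1, m)] <= grid[(2, m)]
        for x in (0, 1, 2):
            assert grid[(x, 0)] <= grid[(x, 1)]

    def test_degenerate_x0_m0_is_fixed_position_exact(self):
        rng = random.Random(3)
        wl = random_whitelist(rng, 16, 6)
        matcher = SetMatcher(wl, MatchParams(jitter=0, max_mismatches=0))
        for _ in range(300):
            read = random_read(rng, 20)
            es = rng.randint(1, 15)
            hit = matcher.match(read, es)
            sub = read[es - 1 : es - 1 + 6]
            if sub in wl:
                assert hit.status is MatchStatus.EXACT and hit.barcode == sub
            else:
                assert hit.status is MatchStatus.NO_MATCH_NULL

    def test_determinism(self):
        rng = random.Random(9)
        wl = random_whitelist(rng, 8, 6)
        matcher = SetMatcher(wl, MatchParams(jitter=2, max_mismatches=2))
        read = random_read(rng, 30)
        hits = {matcher.match(read, 10) for _ in range(5)}
        assert len(hits) == 1
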