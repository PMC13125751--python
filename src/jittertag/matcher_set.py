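"""Set-based jitter-aware approximate barcode matching.

This backend precomputes a "mismatches" index: every sequence within Hamming
distance <= m of any whitelist barcode, mapped back to its nearest origin
barcode(s).  At match time a query window of 2x+1 candidate substrings is
extracted around the expected start position (clipped candidates are N-padded)
and each candidate is looked up in the index.  Hits are ranked

    fewest mismatches  ->  smallest |offset|  ->  upstream before downstream

and a top rank shared by distinct barcodes yields an ambiguous null.

This module is the reference semantics; the trie backend must agree with it
on every input.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from math import comb
from typing import Sequence

from .barcode_model import (
    BarcodeHit,
    ExpectedPosition,
    MatchParams,
    MatchStatus,
    Whitelist,
    null_hit,
)

__all__ = [
    "CapacityError",
    "MismatchIndex",
    "WindowCandidate",
    "QueryWindow",
    "DEFAULT_VARIANT_CAP",
    "estimate_variant_count",
    "build_mismatch_index",
    "extract_query_window",
    "match_barcode_set",
    "match_barcode_direct",
    "hamming",
    "SetMatcher",
]

_BASES = "ACGT"
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_MASK = (1 << 32) - 1

#: Default cap on total enumerated variants across one whitelist's index.
DEFAULT_VARIANT_CAP = 50_000_000


class CapacityError(RuntimeError):
    """The mismatch index would exceed its variant cap."""


def hamming(query: str, barcode: str) -> int:
    """Hamming distance with non-ACGT query characters (e.g. N pads) counted
    as mismatches against every base.

    Whitelist barcodes are ACGT-only, so plain character inequality already
    implements the N-as-mismatch rule.
    """
    return sum(1 for q, b in zip(query, barcode) if q != b)


def estimate_variant_count(n_barcodes: int, n: int, m: int) -> int:
    """Upper bound |whitelist| * sum_{d=0..m} C(n,d)*3^d on index size."""
    per_barcode = sum(comb(n, d) * 3**d for d in range(m + 1))
    return n_barcodes * per_barcode


def _encode(seq: str) -> int | None:
    """2-bit encode an ACGT string; None if any other character occurs."""
    code = 0
    for ch in seq:
        v = _ENC.get(ch)
        if v is None:
            return None
        code = (code << 2) | v
    return code


class MismatchIndex:
    """All sequences within Hamming distance <= m of a whitelist, mapped to
    their minimal-distance origin barcode(s).

    Variants are stored as 2-bit-encoded integers.  The common case (one
    origin barcode at the minimal distance) lives in a packed int dict; the
    rare equal-distance ties live in a side dict so ambiguity is detectable.
    """

    __slots__ = ("whitelist_name", "n", "m", "_barcodes", "_single", "_multi")

    def __init__(self, wl: Whitelist, m: int):
        self.whitelist_name = wl.name
        self.n = wl.n
        self.m = m
        self._barcodes = wl.barcodes
        self._single: dict[int, int] = {}
        self._multi: dict[int, tuple[int, ...]] = {}

    def _add(self, variant: int, dist: int, idx: int) -> None:
        cur = self._single.get(variant)
        if cur is None:
            self._single[variant] = (dist << 32) | idx
            return
        cur_dist = cur >> 32
        if dist < cur_dist:
            self._single[variant] = (dist << 32) | idx
            self._multi.pop(variant, None)
        elif dist == cur_dist:
            cur_idx = cur & _IDX_MASK
            if cur_idx == idx:
                return
            tied = self._multi.get(variant)
            if tied is None:
                self._multi[variant] = (cur_idx, idx)
            elif idx not in tied:
                self._multi[variant] = tied + (idx,)

    def __len__(self) -> int:
        return len(self._single)

    def lookup(self, seq: str) -> tuple[int, tuple[str, ...]] | None:
        """Return (minimal distance, barcodes at that distance) or None.

        Returns None for sequences outside the index, including any sequence
        containing a non-ACGT character — callers must route those through
        the direct-scan fallback.
        """
        if len(seq) != self.n:
            return None
        code = _encode(seq)
        if code is None:
            return None
        packed = self._single.get(code)
        if packed is None:
            return None
        dist = packed >> 32
        tied = self._multi.get(code)
        if tied is None:
            return dist, (self._barcodes[packed & _IDX_MASK],)
        return dist, tuple(sorted(self._barcodes[i] for i in tied))


def build_mismatch_index(
    wl: Whitelist, m: int, variant_cap: int = DEFAULT_VARIANT_CAP
) -> MismatchIndex:
    """Enumerate every <=m-mismatch variant of every barcode in ``wl``.

    Deterministic: the index contents depend only on the set of barcodes,
    not their insertion order (ties are stored as sorted sequences).
    """
    if m >= wl.n:
        raise ValueError(f"m={m} must be < barcode length {wl.n}")
    est = estimate_variant_count(len(wl), wl.n, m)
    if est > variant_cap:
        raise CapacityError(
            f"whitelist {wl.name!r}: estimated {est:,} variants exceeds the "
            f"cap of {variant_cap:,}; use --backend trie for large whitelists"
        )
    idx = MismatchIndex(wl, m)
    n = wl.n
    shifts = [2 * (n - 1 - p) for p in range(n)]
    add = idx._add
    for bidx, bc in enumerate(wl.barcodes):
        code = _encode(bc)
        assert code is not None
        add(code, 0, bidx)
        # Per-position pre-shifted alternative base values.
        alt: list[tuple[int, ...]] = []
        masks: list[int] = []
        for p in range(n):
            sh = shifts[p]
            orig = (code >> sh) & 3
            alt.append(tuple(v << sh for v in range(4) if v != orig))
            masks.append(~(3 << sh))
        for d in range(1, m + 1):
            for pos in combinations(range(n), d):
                base = code
                for p in pos:
                    base &= masks[p]
                for repl in product(*(alt[p] for p in pos)):
                    variant = base
                    for v in repl:
                        variant |= v
                    add(variant, d, bidx)
    return idx


@dataclass(frozen=True)
class WindowCandidate:
    """One candidate substring of the query window."""

    start: int  # 1-based start within the read (may be < 1 off the edge)
    offset: int  # start - expected_start
    seq: str  # exactly n characters, N-padded where off-read
    pad_count: int


@dataclass(frozen=True)
class QueryWindow:
    """The 2x+1 candidate substrings around an expected start position."""

    expected_start: int
    n: int
    jitter: int
    candidates: tuple[WindowCandidate, ...]  # ascending start order

    def scan_order(self) -> list[WindowCandidate]:
        """Candidates by increasing |offset|, upstream before downstream."""
        return sorted(self.candidates, key=lambda c: (abs(c.offset), c.offset))

    def at_offset(self, offset: int) -> WindowCandidate:
        return self.candidates[offset + self.jitter]


def extract_query_window(
    read_seq: str, expected_start: int, n: int, x: int
) -> QueryWindow:
    """Extract the 2x+1 n-length candidates at starts expected_start +- x.

    Candidates that run off either read edge are trimmed there and padded
    with N on the out-of-range side; candidates fully outside the read are
    all-N with pad_count == n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if x < 0:
        raise ValueError("jitter must be >= 0")
    if not read_seq:
        raise ValueError("read_seq must be non-empty")
    length = len(read_seq)
    out: list[WindowCandidate] = []
    for offset in range(-x, x + 1):
        start = expected_start + offset
        s0 = start - 1
        e0 = s0 + n
        core = read_seq[max(s0, 0) : min(e0, length)] if e0 > 0 and s0 < length else ""
        left = min(max(0, -s0), n - len(core))
        right = n - len(core) - left
        seq = "N" * left + core + "N" * right
        out.append(WindowCandidate(start, offset, seq, left + right))
    return QueryWindow(expected_start, n, x, tuple(out))


def _has_non_acgt(seq: str) -> bool:
    for ch in seq:
        if ch not in _ENC:
            return True
    return False


def _direct_min(
    seq: str, wl: Whitelist, m: int
) -> tuple[int, tuple[str, ...]] | None:
    """Minimal Hamming distance <= m over the whitelist by direct scan."""
    best = m + 1
    hits: list[str] = []
    for bc in wl.barcodes:
        d = hamming(seq, bc)
        if d < best:
            best = d
            hits = [bc]
        elif d == best:
            hits.append(bc)
    if best > m:
        return None
    return best, tuple(sorted(hits))


def select_hit(
    matches: Sequence[tuple[int, WindowCandidate, tuple[str, ...]]],
    window: QueryWindow,
) -> BarcodeHit:
    """Apply the ranked-tie selection rule shared by both backends.

    ``matches`` holds, per surviving candidate, its minimal mismatch count
    (<= m), the candidate itself, and the barcode(s) achieving that minimum.
    """
    observed_at_zero = window.at_offset(0).seq
    if not matches:
        return null_hit(MatchStatus.NO_MATCH_NULL, window.n, observed_at_zero)
    best_d = min(d for d, _, _ in matches)
    pool = [(c, bcs) for d, c, bcs in matches if d == best_d]
    best_abs = min(abs(c.offset) for c, _ in pool)
    top = [(c, bcs) for c, bcs in pool if abs(c.offset) == best_abs]
    distinct = {b for _, bcs in top for b in bcs}
    if len(distinct) > 1:
        return null_hit(MatchStatus.AMBIGUOUS_NULL, window.n, observed_at_zero)
    barcode = distinct.pop()
    chosen = min((c for c, _ in top), key=lambda c: c.offset)
    status = MatchStatus.EXACT if best_d == 0 else MatchStatus.CORRECTED
    return BarcodeHit(status, barcode, best_d, chosen.offset, chosen.seq)


def match_barcode_set(
    read_seq: str,
    ep: ExpectedPosition,
    wl: Whitelist,
    params: MatchParams,
    idx: MismatchIndex,
) -> BarcodeHit:
    """Match one barcode element in one read via the mismatch index.

    Candidates containing N (edge pads or sequenced N's) bypass the
    ACGT-only index and are scored by the direct Hamming fallback.
    """
    window = extract_query_window(read_seq, ep.start, wl.n, params.jitter)
    m = params.max_mismatches
    matches: list[tuple[int, WindowCandidate, tuple[str, ...]]] = []
    for cand in window.candidates:
        if _has_non_acgt(cand.seq):
            res = _direct_min(cand.seq, wl, m)
        else:
            res = idx.lookup(cand.seq)
        if res is not None and res[0] <= m:
            matches.append((res[0], cand, res[1]))
    return select_hit(matches, window)


def match_barcode_direct(
    window: QueryWindow, wl: Whitelist, m: int
) -> list[tuple[str, int, int]]:
    """Rank every (barcode, mismatches, offset) with mismatches <= m by
    direct Hamming scan, N counting as a mismatch against every base.

    Ordering: mismatches ascending, |offset| ascending, upstream first.
    """
    out: list[tuple[str, int, int]] = []
    for cand in window.candidates:
        for bc in wl.barcodes:
            d = hamming(cand.seq, bc)
            if d <= m:
                out.append((bc, d, cand.offset))
    out.sort(key=lambda t: (t[1], abs(t[2]), t[2], t[0]))
    return out


class SetMatcher:
    """Convenience wrapper binding a whitelist, parameters and index."""

    def __init__(
        self,
        wl: Whitelist,
        params: MatchParams,
        variant_cap: int = DEFAULT_VARIANT_CAP,
    ):
        params.validate_for(wl)
        self.wl = wl
        self.params = params
        self.index = build_mismatch_index(
            wl, params.max_mismatches, variant_cap=variant_cap
        )

    def match(self, read_seq: str, expected_start: int) -> BarcodeHit:
        window = extract_query_window(
            read_seq, expected_start, self.wl.n, self.params.jitter
        )
        m = self.params.max_mismatches
        matches: list[tuple[int, WindowCandidate, tuple[str, ...]]] = []
        for cand in window.candidates:
            if _has_non_acgt(cand.seq):
                res = _direct_min(cand.seq, self.wl, m)
            else:
                res = self.index.lookup(cand.seq)
            if res is not None and res[0] <= m:
                matches.append((res[0], cand, res[1]))
        return select_hit(matches, window)
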