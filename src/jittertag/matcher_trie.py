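"""Hybrid trie + seed-index approximate matcher for large whitelists.

Exact matches are resolved by walking a 4-ary prefix trie; approximate
matches retrieve candidates through a pigeonhole seed index (each barcode
split into m+1 near-equal contiguous seeds, so any sequence within m
substitutions of a barcode shares at least one seed exactly) and are then
verified by full-length Hamming distance.  Selection follows the same
ranked-tie rule as the set backend, to which this backend is contractually
output-identical.
"""
from __future__ import annotations

from .barcode_model import (
    BarcodeHit,
    ExpectedPosition,
    MatchParams,
    Whitelist,
)
from .matcher_set import (
    WindowCandidate,
    _direct_min,
    _has_non_acgt,
    extract_query_window,
    hamming,
    select_hit,
)

__all__ = [
    "BarcodeTrie",
    "SeedIndex",
    "KmerIndex",
    "build_trie",
    "build_seed_index",
    "build_kmer_index",
    "match_barcode_trie",
    "TrieMatcher",
]


class BarcodeTrie:
    """4-ary prefix tree over {A,C,G,T}; terminal nodes carry barcode indices."""

    __slots__ = ("n", "_root")

    def __init__(self, n: int):
        self.n = n
        self._root: dict = {}

    def insert(self, barcode: str, index: int) -> None:
        if len(barcode) != self.n:
            raise ValueError(f"barcode {barcode!r} has length != {self.n}")
        node = self._root
        for ch in barcode:
            node = node.setdefault(ch, {})
        node["$"] = index

    def lookup(self, seq: str) -> int | None:
        """Barcode index if ``seq`` is a whitelist member, else None."""
        if len(seq) != self.n:
            return None
        node = self._root
        for ch in seq:
            node = node.get(ch)
            if node is None:
                return None
        return node.get("$")

    def __contains__(self, seq: object) -> bool:
        return isinstance(seq, str) and self.lookup(seq) is not None


def build_trie(wl: Whitelist) -> BarcodeTrie:
    trie = BarcodeTrie(wl.n)
    for i, bc in enumerate(wl.barcodes):
        trie.insert(bc, i)
    return trie


def _seed_slots(n: int, m: int) -> tuple[tuple[int, int], ...]:
    """Partition [0, n) into m+1 contiguous pieces with lengths differing by
    at most one (longer pieces first)."""
    parts = m + 1
    base, rem = divmod(n, parts)
    slots: list[tuple[int, int]] = []
    pos = 0
    for i in range(parts):
        size = base + (1 if i < rem else 0)
        slots.append((pos, pos + size))
        pos += size
    return tuple(slots)


class SeedIndex:
    """Pigeonhole index: (seed slot, seed sequence) -> barcode indices."""

    __slots__ = ("whitelist_name", "n", "m", "slots", "_map")

    def __init__(self, wl: Whitelist, m: int):
        if m + 1 > wl.n:
            raise ValueError(
                f"m+1 = {m + 1} seeds cannot partition barcodes of length {wl.n}"
            )
        self.whitelist_name = wl.name
        self.n = wl.n
        self.m = m
        self.slots = _seed_slots(wl.n, m)
        self._map: dict[tuple[int, str], tuple[int, ...]] = {}
        for idx, bc in enumerate(wl.barcodes):
            for slot_i, (s, e) in enumerate(self.slots):
                key = (slot_i, bc[s:e])
                cur = self._map.get(key)
                self._map[key] = (idx,) if cur is None else cur + (idx,)

    def candidates(self, seq: str) -> set[int]:
        """Indices of barcodes sharing at least one seed exactly with ``seq``."""
        found: set[int] = set()
        for slot_i, (s, e) in enumerate(self.slots):
            hit = self._map.get((slot_i, seq[s:e]))
            if hit:
                found.update(hit)
        return found


def build_seed_index(wl: Whitelist, m: int) -> SeedIndex:
    return SeedIndex(wl, m)


class KmerIndex:
    """Optional positional k-mer candidate filter (default off).

    Indexes every k-mer of every barcode at its position; retrieval unions
    barcodes sharing a same-position k-mer with the query.  Unlike the seed
    index this filter is not complete for every mismatch placement, so it is
    exposed only behind an explicit flag; verification (full Hamming) is
    identical either way.
    """

    __slots__ = ("whitelist_name", "n", "k", "_map")

    def __init__(self, wl: Whitelist, k: int):
        if not 1 <= k <= wl.n:
            raise ValueError(f"k={k} must be in [1, {wl.n}]")
        self.whitelist_name = wl.name
        self.n = wl.n
        self.k = k
        self._map: dict[tuple[int, str], tuple[int, ...]] = {}
        for idx, bc in enumerate(wl.barcodes):
            for pos in range(wl.n - k + 1):
                key = (pos, bc[pos : pos + k])
                cur = self._map.get(key)
                self._map[key] = (idx,) if cur is None else cur + (idx,)

    def candidates(self, seq: str) -> set[int]:
        found: set[int] = set()
        for pos in range(self.n - self.k + 1):
            hit = self._map.get((pos, seq[pos : pos + self.k]))
            if hit:
                found.update(hit)
        return found


def build_kmer_index(wl: Whitelist, m: int, k: int | None = None) -> KmerIndex:
    if k is None:
        k = max(1, wl.n // (m + 1))  # mirrors the pigeonhole bound
    return KmerIndex(wl, k)


def _approx_min(
    seq: str,
    wl: Whitelist,
    m: int,
    index: SeedIndex | KmerIndex,
) -> tuple[int, tuple[str, ...]] | None:
    """Minimal verified Hamming distance <= m among index candidates."""
    best = m + 1
    hits: list[str] = []
    for idx in index.candidates(seq):
        bc = wl.barcodes[idx]
        d = hamming(seq, bc)
        if d < best:
            best = d
            hits = [bc]
        elif d == best:
            hits.append(bc)
    if best > m:
        return None
    return best, tuple(sorted(hits))


def match_barcode_trie(
    read_seq: str,
    ep: ExpectedPosition,
    wl: Whitelist,
    params: MatchParams,
    trie: BarcodeTrie,
    index: SeedIndex | KmerIndex,
) -> BarcodeHit:
    """Trie-backend counterpart of ``match_barcode_set`` (identical output)."""
    window = extract_query_window(read_seq, ep.start, wl.n, params.jitter)
    m = params.max_mismatches
    matches: list[tuple[int, WindowCandidate, tuple[str, ...]]] = []
    for cand in window.candidates:
        if _has_non_acgt(cand.seq):
            res = _direct_min(cand.seq, wl, m)
        else:
            exact = trie.lookup(cand.seq)
            if exact is not None:
                res = (0, (cand.seq,))
            else:
                res = _approx_min(cand.seq, wl, m, index) if m > 0 else None
        if res is not None and res[0] <= m:
            matches.append((res[0], cand, res[1]))
    return select_hit(matches, window)


class TrieMatcher:
    """Convenience wrapper binding a whitelist, parameters, trie and index."""

    def __init__(self, wl: Whitelist, params: MatchParams, use_kmer: bool = False):
        params.validate_for(wl)
        self.wl = wl
        self.params = params
        self.trie = build_trie(wl)
        m = params.max_mismatches
        if use_kmer:
            self.index: SeedIndex | KmerIndex = build_kmer_index(
                wl, m, params.seed_kmer_length
            )
        else:
            self.index = build_seed_index(wl, m)

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
                exact = self.trie.lookup(cand.seq)
                if exact is not None:
                    res = (0, (cand.seq,))
                else:
                    res = _approx_min(cand.seq, self.wl, m, self.index) if m > 0 else None
            if res is not None and res[0] <= m:
                matches.append((res[0], cand, res[1]))
        return select_hit(matches, window)
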