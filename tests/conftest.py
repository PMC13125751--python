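"""Shared fixtures and the brute-force matching oracle.

The oracle deliberately re-derives the selection semantics from scratch —
every window candidate is compared against every whitelist barcode by plain
character comparison, then the ranked-tie rules are applied literally — so
it shares no code path with the matchers it checks.
"""
from __future__ import annotations

import random

import pytest

from jittertag.barcode_model import Whitelist
from jittertag.fixtures import (
    LayoutElement,
    LibraryDesign,
    generate_library,
    generate_whitelist,
)

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Brute-force oracle


def oracle_match(read_seq, expected_start, barcodes, x, m):
    """Literal implementation of the ranking contract.

    Returns (status, barcode, mismatches, offset, observed) where null
    statuses carry barcode N^n, mismatches -1 and offset 0.
    """
    n = len(barcodes[0])
    length = len(read_seq)
    cands = []
    for off in range(-x, x + 1):
        s0 = expected_start - 1 + off
        seq = "".join(
            read_seq[p] if 0 <= p < length else "N" for p in range(s0, s0 + n)
        )
        cands.append((off, seq))
    observed_at_zero = next(seq for off, seq in cands if off == 0)
    pairs = []
    for off, seq in cands:
        for bc in barcodes:
            d = sum(1 for a, b in zip(seq, bc) if a != b)
            if d <= m:
                pairs.append((d, abs(off), off, bc, seq))
    if not pairs:
        return ("no_match_null", "N" * n, -1, 0, observed_at_zero)
    best = min((d, ab) for d, ab, _, _, _ in pairs)
    top = [p for p in pairs if (p[0], p[1]) == best]
    distinct = {bc for _, _, _, bc, _ in top}
    if len(distinct) > 1:
        return ("ambiguous_null", "N" * n, -1, 0, observed_at_zero)
    chosen = min(top, key=lambda p: p[2])
    status = "exact" if chosen[0] == 0 else "corrected"
    return (status, chosen[3], chosen[0], chosen[2], chosen[4])


def hit_tuple(hit):
    """Flatten a BarcodeHit for comparison against the oracle."""
    return (hit.status.value, hit.barcode, hit.mismatches, hit.offset, hit.observed)


def random_whitelist(rng: random.Random, size: int, n: int) -> Whitelist:
    size = min(size, 4**n // 2 + 1)  # keep the draw loop finite for tiny n
    seqs: set[str] = set()
    while len(seqs) < size:
        seqs.add("".join(rng.choice(_BASES) for _ in range(n)))
    return Whitelist("wl", sorted(seqs))


def random_read(rng: random.Random, length: int, with_n: bool = False) -> str:
    alphabet = _BASES + ("N" if with_n else "")
    return "".join(rng.choice(alphabet) for _ in range(length))


# ---------------------------------------------------------------------------
# Shared synthetic library (used by reap/acceptance tests)

LINKER_A = "TCAGGA"
LINKER_B = "GGATCA"


def make_three_round_design(
    rng_seed: int = 11,
    jitter_probs=None,
    one_sub_prob: float = 0.0,
    truncate_probs=None,
) -> LibraryDesign:
    """3 x 96-barcode rounds (n=8, min pairwise Hamming 3, shift-guarded),
    two fixed linkers and an 8 nt UMI on read 1."""
    wls = [
        generate_whitelist(
            96, 8, 3, rng_seed=1000 + i, name=f"bc{i + 1}",
            max_shift=2, shift_min_hamming=2,
        )
        for i in range(3)
    ]
    elements = [
        LayoutElement("barcode", "bc1", whitelist=wls[0]),
        LayoutElement("linker", "lnk1", sequence=LINKER_A),
        LayoutElement("barcode", "bc2", whitelist=wls[1]),
        LayoutElement("linker", "lnk2", sequence=LINKER_B),
        LayoutElement("barcode", "bc3", whitelist=wls[2]),
        LayoutElement("umi", "umi", length=8),
    ]
    return LibraryDesign(
        elements=elements,
        read1_length=48,
        read2_length=40,
        jitter_probs=jitter_probs or {0: 1.0},
        one_sub_prob=one_sub_prob,
        truncate_probs=truncate_probs or {0: 1.0},
        rng_seed=rng_seed,
    )


@pytest.fixture(scope="session")
def jittered_library():
    """10 000 read pairs: 30% shifted +1, 10% with one substitution, rest
    clean (events mutually exclusive per read)."""
    design = make_three_round_design(
        rng_seed=42, jitter_probs={0: 0.7, 1: 0.3}, one_sub_prob=0.1
    )
    pairs, ledger = generate_library(design, 10_000)
    return design, pairs, ledger


@pytest.fixture(scope="session")
def jittered_library_files(jittered_library, tmp_path_factory):
    from jittertag.fixtures import write_ledger

    design, pairs, ledger = jittered_library
    root = tmp_path_factory.mktemp("jittered_lib")
    r1, r2 = root / "R1.fastq", root / "R2.fastq"
    for path, idx in ((r1, 0), (r2, 1)):
        with open(path, "wt") as fh:
            for pair in pairs:
                rec = pair[idx]
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
    ledger_path = root / "ledger.tsv"
    write_ledger(ledger, ledger_path)
    return design, r1, r2, ledger_path
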