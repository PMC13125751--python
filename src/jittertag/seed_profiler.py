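"""The ``seed`` stage: scan a subsample of reads for exact whitelist
occurrences at every position — no jitter, no mismatches — and profile the
start-position histogram per whitelist and read of the pair.
"""
from __future__ import annotations

import gzip
import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .barcode_model import PositionProfile, Whitelist, write_profiles_tsv
from .matcher_trie import build_trie

logger = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "SeedHit",
    "FastqFormatError",
    "PairingError",
    "open_text",
    "iter_fastq",
    "iter_read_tuples",
    "sample_reads",
    "scan_read_exact",
    "run_seed",
    "DEFAULT_N_SAMPLE",
]

DEFAULT_N_SAMPLE = 10_000


class FastqFormatError(ValueError):
    """Truncated or malformed FASTQ record."""


class PairingError(ValueError):
    """Paired FASTQ files with unequal record counts."""


@dataclass(frozen=True)
class ReadRecord:
    """A FASTQ record; ``id`` is the first whitespace token of the title."""

    id: str
    comment: str
    seq: str
    qual: str


def open_text(path: str | Path):
    """Open plain or gzip-compressed text transparently."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq(path: str | Path) -> Iterator[ReadRecord]:
    record_no = 0
    try:
        with open_text(path) as handle:
            for title, seq, qual in FastqGeneralIterator(handle):
                record_no += 1
                parts = title.split(None, 1)
                rid = parts[0] if parts else ""
                comment = parts[1] if len(parts) > 1 else ""
                yield ReadRecord(rid, comment, seq.upper(), qual)
    except ValueError as exc:
        raise FastqFormatError(
            f"{path}: malformed FASTQ near record {record_no + 1}: {exc}"
        ) from exc


def iter_read_tuples(
    paths: Sequence[str | Path],
) -> Iterator[tuple[ReadRecord, ...]]:
    """Iterate records of 1..k FASTQ files in lockstep.

    Raises PairingError if the files have unequal record counts (detected
    lazily when the shorter file runs out).
    """
    iters = [iter_fastq(p) for p in paths]
    sentinel = object()
    while True:
        row = [next(it, sentinel) for it in iters]
        done = [r is sentinel for r in row]
        if all(done):
            return
        if any(done):
            raise PairingError(
                f"paired FASTQ files have unequal record counts: "
                f"{[str(p) for p in paths]}"
            )
        yield tuple(row)  # type: ignore[arg-type]


def sample_reads(
    fastq_paths: Sequence[str | Path],
    n_sample: int,
    mode: str = "head",
    rng_seed: int | None = None,
) -> list[tuple[ReadRecord, ...]]:
    """Sample up to ``n_sample`` read tuples from paired FASTQ files.

    ``head`` takes the first n_sample tuples deterministically; ``reservoir``
    draws a uniform sample reproducible from ``rng_seed``.  Fewer available
    reads than requested yields all of them with a logged warning.
    """
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")
    if mode not in ("head", "reservoir"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    stream = iter_read_tuples(fastq_paths)
    if mode == "head":
        sample: list[tuple[ReadRecord, ...]] = []
        for tup in stream:
            sample.append(tup)
            if len(sample) >= n_sample:
                break
    else:
        rng = random.Random(rng_seed)
        sample = []
        for i, tup in enumerate(stream):
            if i < n_sample:
                sample.append(tup)
            else:
                j = rng.randrange(i + 1)
                if j < n_sample:
                    sample[j] = tup
    if len(sample) < n_sample:
        logger.warning(
            "requested %d reads but only %d available; using all of them",
            n_sample,
            len(sample),
        )
    return sample


@dataclass(frozen=True)
class SeedHit:
    """One exact whitelist occurrence in one read."""

    read_id: str
    read_index: int
    whitelist_name: str
    barcode: str
    start: int  # 1-based


def _make_members(
    whitelists: Sequence[Whitelist], backend: str
) -> list[tuple[Whitelist, Callable[[str], bool]]]:
    out: list[tuple[Whitelist, Callable[[str], bool]]] = []
    for wl in whitelists:
        if backend == "trie":
            trie = build_trie(wl)
            out.append((wl, trie.__contains__))
        else:
            out.append((wl, wl.members.__contains__))
    return out


def scan_read_exact(
    read: ReadRecord,
    read_index: int,
    whitelists: Sequence[Whitelist],
    backend: str = "set",
    _members=None,
) -> list[SeedHit]:
    """Every start position at which any whitelist barcode occurs exactly.

    All whitelists are scanned independently; a read shorter than a
    whitelist's barcode length yields no hits for that whitelist.
    """
    members = _members if _members is not None else _make_members(whitelists, backend)
    hits: list[SeedHit] = []
    seq = read.seq
    length = len(seq)
    for wl, contains in members:
        n = wl.n
        for s0 in range(length - n + 1):
            sub = seq[s0 : s0 + n]
            if contains(sub):
                hits.append(SeedHit(read.id, read_index, wl.name, sub, s0 + 1))
    return hits


def run_seed(
    fastq_paths: Sequence[str | Path],
    whitelist: Whitelist,
    n_sample: int = DEFAULT_N_SAMPLE,
    out_path: str | Path | None = None,
    hits_path: str | Path | None = None,
    mode: str = "head",
    rng_seed: int | None = None,
    backend: str = "set",
) -> list[PositionProfile]:
    """Profile exact-hit start positions of one whitelist over sampled reads.

    Returns one PositionProfile per FASTQ file (read index), including empty
    profiles for files where the whitelist never occurs.  A read contributes
    at most one count to each (read index, position).
    """
    sample = sample_reads(fastq_paths, n_sample, mode=mode, rng_seed=rng_seed)
    members = _make_members([whitelist], backend)
    counts: dict[int, dict[int, int]] = {
        ri: {} for ri in range(1, len(fastq_paths) + 1)
    }
    hits_fh = open(hits_path, "wt", encoding="utf-8") if hits_path else None
    try:
        if hits_fh:
            hits_fh.write("read_id\tread_index\twhitelist\tbarcode\tstart\n")
        for tup in sample:
            for ri, record in enumerate(tup, start=1):
                for hit in scan_read_exact(
                    record, ri, [whitelist], backend, _members=members
                ):
                    bucket = counts[ri]
                    bucket[hit.start] = bucket.get(hit.start, 0) + 1
                    if hits_fh:
                        hits_fh.write(
                            f"{hit.read_id}\t{ri}\t{hit.whitelist_name}\t"
                            f"{hit.barcode}\t{hit.start}\n"
                        )
    finally:
        if hits_fh:
            hits_fh.close()
    profiles = [
        PositionProfile(whitelist.name, ri, counts[ri], len(sample))
        for ri in range(1, len(fastq_paths) + 1)
    ]
    if out_path is not None:
        write_profiles_tsv(profiles, out_path)
    return profiles
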