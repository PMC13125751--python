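"""Synthetic combinatorial-library generator with a ground-truth ledger.

Reads are assembled from an ordered layout of barcode elements, linkers, a
UMI and random filler on read 1, with cDNA on read 2.  The error model
injects a per-read positional offset of the whole barcode block (random pad
bases inserted at the read start for positive offsets, leading-base deletion
for negative ones), substitutions, and edge truncations.  Every injected
event is recorded in the ledger so recovery can be scored exactly.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .barcode_model import ExpectedPosition, Whitelist
from .matcher_set import hamming
from .seed_profiler import ReadRecord

__all__ = [
    "InfeasibleWhitelistError",
    "LayoutElement",
    "LibraryDesign",
    "LedgerRow",
    "generate_whitelist",
    "generate_library",
    "write_library",
    "write_ledger",
    "read_ledger",
]

_BASES = "ACGT"


class InfeasibleWhitelistError(RuntimeError):
    """The requested whitelist constraints could not be satisfied."""


def _shift_conflict(a: str, b: str, max_shift: int, min_ham: int) -> bool:
    """True if any <=max_shift relative shift of ``a`` against ``b`` leaves
    their overlap within Hamming distance < min_ham.

    Guarding against this (including a == b, i.e. near-periodic barcodes)
    makes jittered fixtures unambiguous: no shifted view of one barcode can
    impersonate another within the mismatch budget.
    """
    n = len(a)
    for s in range(1, max_shift + 1):
        if hamming(a[s:], b[: n - s]) < min_ham:
            return True
        if hamming(b[s:], a[: n - s]) < min_ham:
            return True
    return False


def generate_whitelist(
    size: int,
    n: int,
    min_pairwise_hamming: int,
    rng_seed: int,
    name: str = "wl",
    max_shift: int = 0,
    shift_min_hamming: int = 0,
    max_attempts: int | None = None,
) -> Whitelist:
    """Sample ``size`` random barcodes of length ``n`` with pairwise Hamming
    distance >= ``min_pairwise_hamming``.

    When ``max_shift`` > 0, additionally require that every overlap of any
    barcode shifted by 1..max_shift against any barcode (itself included)
    keeps Hamming distance >= ``shift_min_hamming``.  Reproducible from
    ``rng_seed``; raises after a bounded number of attempts instead of
    looping forever.
    """
    if min_pairwise_hamming > n:
        raise InfeasibleWhitelistError(
            f"min pairwise Hamming {min_pairwise_hamming} cannot exceed "
            f"barcode length {n}"
        )
    if size > 4**n:
        raise InfeasibleWhitelistError(
            f"cannot draw {size} distinct barcodes of length {n}"
        )
    rng = random.Random(rng_seed)
    if max_attempts is None:
        max_attempts = max(200_000, 2_000 * size)
    accepted: list[str] = []
    seen: set[str] = set()
    distinct_only = min_pairwise_hamming <= 1 and not max_shift
    attempts = 0
    while len(accepted) < size:
        attempts += 1
        if attempts > max_attempts:
            raise InfeasibleWhitelistError(
                f"gave up after {max_attempts} attempts with "
                f"{len(accepted)}/{size} barcodes accepted; relax the "
                f"distance constraints"
            )
        cand = "".join(rng.choice(_BASES) for _ in range(n))
        if cand in seen:
            continue
        if distinct_only:
            seen.add(cand)
            accepted.append(cand)
            continue
        if max_shift and _shift_conflict(cand, cand, max_shift, shift_min_hamming):
            continue
        ok = True
        for b in accepted:
            if hamming(cand, b) < min_pairwise_hamming:
                ok = False
                break
            if max_shift and _shift_conflict(cand, b, max_shift, shift_min_hamming):
                ok = False
                break
        if ok:
            seen.add(cand)
            accepted.append(cand)
    return Whitelist(name, accepted)


@dataclass(frozen=True)
class LayoutElement:
    """One slot of the read-1 layout.

    kind ``barcode`` draws from ``whitelist``; ``linker`` emits the fixed
    ``sequence``; ``umi`` emits ``length`` random bases.
    """

    kind: str
    name: str
    whitelist: Whitelist | None = None
    sequence: str | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("barcode", "linker", "umi"):
            raise ValueError(f"unknown layout element kind {self.kind!r}")
        if self.kind == "barcode" and self.whitelist is None:
            raise ValueError(f"barcode element {self.name!r} needs a whitelist")
        if self.kind == "linker" and not self.sequence:
            raise ValueError(f"linker element {self.name!r} needs a sequence")
        if self.kind == "umi" and not self.length:
            raise ValueError(f"umi element {self.name!r} needs a length")

    @property
    def width(self) -> int:
        if self.kind == "barcode":
            assert self.whitelist is not None
            return self.whitelist.n
        if self.kind == "linker":
            assert self.sequence is not None
            return len(self.sequence)
        assert self.length is not None
        return self.length


@dataclass
class LibraryDesign:
    """Layout plus error model for one synthetic library.

    ``jitter_probs`` maps per-read offsets to probabilities (must sum to 1).
    With ``exclusive_errors`` (the default) each read draws a single event —
    a non-zero offset, a single random substitution in one barcode element
    (``one_sub_prob``), a leading-edge truncation (``truncate_probs``), or
    nothing — so injected error classes never stack within a read.  With
    ``exclusive_errors=False`` the offset is drawn independently, every base
    of read 1 mutates at ``sub_rate``, and truncation is drawn on top.
    """

    elements: list[LayoutElement]
    read1_length: int
    read2_length: int
    jitter_probs: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    one_sub_prob: float = 0.0
    sub_rate: float = 0.0
    truncate_probs: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    exclusive_errors: bool = True
    header_barcode: Whitelist | None = None
    fill_read1: bool = True  # pad read 1 to read1_length with random bases
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.elements_width()) + max(
            (o for o in self.jitter_probs if o > 0), default=0
        )
        if total > self.read1_length:
            raise ValueError(
                f"layout width plus max positive jitter ({total}) exceeds "
                f"read1_length {self.read1_length}"
            )
        for probs, label in ((self.jitter_probs, "jitter_probs"),
                             (self.truncate_probs, "truncate_probs")):
            s = sum(probs.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{label} must sum to 1, got {s}")
        names = [e.name for e in self.elements]
        if len(set(names)) != len(names):
            raise ValueError("layout element names must be unique")

    def elements_width(self) -> list[int]:
        return [e.width for e in self.elements]

    def element_starts(self) -> dict[str, int]:
        """Designed 1-based start of every element on read 1 (no jitter)."""
        starts: dict[str, int] = {}
        pos = 1
        for e in self.elements:
            starts[e.name] = pos
            pos += e.width
        return starts

    def barcode_elements(self) -> list[LayoutElement]:
        return [e for e in self.elements if e.kind == "barcode"]

    def positions(self) -> list[ExpectedPosition]:
        """Ground-truth expected positions of the barcode elements."""
        starts = self.element_starts()
        return [
            ExpectedPosition(e.name, 1, starts[e.name], 1.0)
            for e in self.barcode_elements()
        ]


@dataclass
class LedgerRow:
    """Ground truth for one generated read pair."""

    read_id: str
    barcodes: dict[str, str]  # element name -> true whitelist barcode
    offset: int
    truncation: int
    substitutions: list[tuple[str, int]]  # (region name, 0-based pos in region)
    umi: str
    header_barcode: str = ""


def _draw_event(
    design: LibraryDesign, rng: random.Random
) -> tuple[int, bool, int]:
    """Draw (offset, apply_one_sub, truncation) for one read under the
    exclusive error model."""
    u = rng.random()
    acc = 0.0
    for off, p in sorted(design.jitter_probs.items()):
        if off == 0:
            continue
        acc += p
        if u < acc:
            return off, False, 0
    acc += design.one_sub_prob
    if u < acc:
        return 0, True, 0
    for t, p in sorted(design.truncate_probs.items()):
        if t == 0:
            continue
        acc += p
        if u < acc:
            return 0, False, t
    return 0, False, 0


def generate_library(
    design: LibraryDesign, n_reads: int
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[LedgerRow]]:
    """Generate ``n_reads`` read pairs plus their ground-truth ledger.

    Byte-identical across reruns with the same design (including
    ``rng_seed``).
    """
    rng = random.Random(design.rng_seed)
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    ledger: list[LedgerRow] = []
    for i in range(n_reads):
        read_id = f"sim_{i:07d}"
        # Assemble read 1 from the layout.
        regions: list[tuple[str, str]] = []
        barcodes: dict[str, str] = {}
        umi = ""
        for e in design.elements:
            if e.kind == "barcode":
                assert e.whitelist is not None
                bc = rng.choice(e.whitelist.barcodes)
                barcodes[e.name] = bc
                regions.append((e.name, bc))
            elif e.kind == "linker":
                assert e.sequence is not None
                regions.append((e.name, e.sequence))
            else:
                assert e.length is not None
                umi = "".join(rng.choice(_BASES) for _ in range(e.length))
                regions.append((e.name, umi))

        subs: list[tuple[str, int]] = []
        if design.exclusive_errors:
            offset, one_sub, truncation = _draw_event(design, rng)
            if one_sub:
                bcs = design.barcode_elements()
                target = rng.choice(bcs)
                pos = rng.randrange(target.width)
                subs.append((target.name, pos))
        else:
            offset = _weighted_choice(design.jitter_probs, rng)
            truncation = _weighted_choice(design.truncate_probs, rng)
            if design.sub_rate > 0:
                for name, seq in regions:
                    for pos in range(len(seq)):
                        if rng.random() < design.sub_rate:
                            subs.append((name, pos))

        # Apply substitutions region by region.
        if subs:
            mutated: dict[str, list[str]] = {}
            for name, pos in subs:
                for rname, seq in regions:
                    if rname == name:
                        chars = mutated.setdefault(name, list(seq))
                        old = chars[pos]
                        chars[pos] = rng.choice([b for b in _BASES if b != old])
                        break
            regions = [
                (name, "".join(mutated[name]) if name in mutated else seq)
                for name, seq in regions
            ]

        read1 = "".join(seq for _, seq in regions)
        # Jitter: shift the whole barcode block via an upstream indel.
        if offset > 0:
            read1 = (
                "".join(rng.choice(_BASES) for _ in range(offset)) + read1
            )
        elif offset < 0:
            read1 = read1[-offset:]
        # Edge truncation clips the read start.
        if truncation > 0:
            read1 = read1[truncation:]
        # Fill to length with random bases, then trim.
        if design.fill_read1 and len(read1) < design.read1_length:
            read1 += "".join(
                rng.choice(_BASES)
                for _ in range(design.read1_length - len(read1))
            )
        read1 = read1[: design.read1_length]

        read2 = "".join(
            rng.choice(_BASES) for _ in range(design.read2_length)
        )
        header_bc = ""
        comment1 = comment2 = ""
        if design.header_barcode is not None:
            header_bc = rng.choice(design.header_barcode.barcodes)
            comment1 = f"1:N:0:{header_bc}"
            comment2 = f"2:N:0:{header_bc}"
        rec1 = ReadRecord(read_id, comment1, read1, "I" * len(read1))
        rec2 = ReadRecord(read_id, comment2, read2, "I" * len(read2))
        pairs.append((rec1, rec2))
        ledger.append(
            LedgerRow(read_id, barcodes, offset, truncation, subs, umi, header_bc)
        )
    return pairs, ledger


def _weighted_choice(probs: dict[int, float], rng: random.Random) -> int:
    u = rng.random()
    acc = 0.0
    for key in sorted(probs):
        acc += probs[key]
        if u < acc:
            return key
    return max(sorted(probs))


def _write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:  # type: ignore[operator]
        for rec in records:
            title = f"{rec.id} {rec.comment}".strip()
            fh.write(f"@{title}\n{rec.seq}\n+\n{rec.qual}\n")


def write_library(
    design: LibraryDesign,
    n_reads: int,
    r1_path: str | Path,
    r2_path: str | Path,
    ledger_path: str | Path | None = None,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[LedgerRow]]:
    """Generate and write the library FASTQ pair (and optionally the ledger)."""
    pairs, ledger = generate_library(design, n_reads)
    _write_fastq((p[0] for p in pairs), r1_path)
    _write_fastq((p[1] for p in pairs), r2_path)
    if ledger_path is not None:
        write_ledger(ledger, ledger_path)
    return pairs, ledger


LEDGER_COLUMNS = (
    "read_id",
    "barcodes",
    "offset",
    "truncation",
    "substitutions",
    "umi",
    "header_barcode",
)


def write_ledger(ledger: Sequence[LedgerRow], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(LEDGER_COLUMNS) + "\n")
        for row in ledger:
            bcs = ",".join(f"{k}={v}" for k, v in row.barcodes.items())
            subs = (
                ";".join(f"{name}:{pos}" for name, pos in row.substitutions)
                or "-"
            )
            fh.write(
                f"{row.read_id}\t{bcs}\t{row.offset}\t{row.truncation}\t"
                f"{subs}\t{row.umi}\t{row.header_barcode}\n"
            )


def read_ledger(path: str | Path) -> list[LedgerRow]:
    out: list[LedgerRow] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(LEDGER_COLUMNS):
            raise ValueError(f"{path}: not a ledger file (header {header!r})")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rid, bcs, offset, trunc, subs, umi, hbc = parts
            barcodes = dict(
                item.split("=", 1) for item in bcs.split(",") if item
            )
            substitutions = (
                [
                    (name, int(pos))
                    for name, pos in (s.split(":") for s in subs.split(";"))
                ]
                if subs != "-"
                else []
            )
            out.append(
                LedgerRow(
                    rid, barcodes, int(offset), int(trunc), substitutions, umi, hbc
                )
            )
    return out
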