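"""Core domain types and whitelist / positions / profile I/O shared by all stages.

Coordinate convention: everything user-facing (CSV files, logs, the types in
this module) uses 1-based inclusive start positions.  Internal slicing code
converts to 0-based half-open intervals at the point of use.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGT")

__all__ = [
    "ALPHABET",
    "Whitelist",
    "MatchParams",
    "ExpectedPosition",
    "MatchStatus",
    "BarcodeHit",
    "PositionProfile",
    "WhitelistError",
    "BarcodeLengthError",
    "DuplicateBarcodeError",
    "AlphabetError",
    "PositionsCsvError",
    "ProfileTsvError",
    "NULL_MISMATCHES",
    "NULL_OFFSET",
    "null_hit",
    "load_whitelist",
    "write_whitelist",
    "read_positions_csv",
    "write_positions_csv",
    "check_position_overlaps",
    "read_profiles_tsv",
    "write_profiles_tsv",
]


class WhitelistError(ValueError):
    """A whitelist violates one of its structural invariants."""


class BarcodeLengthError(WhitelistError):
    """Barcodes of unequal length within one whitelist."""


class DuplicateBarcodeError(WhitelistError):
    """The same barcode appears more than once in one whitelist."""


class AlphabetError(WhitelistError):
    """A barcode contains a character outside {A, C, G, T}."""


class PositionsCsvError(ValueError):
    """Malformed expected-positions CSV."""


class ProfileTsvError(ValueError):
    """Malformed position-profile TSV."""


class Whitelist:
    """A named, ordered collection of equal-length ACGT barcodes.

    Parameters
    ----------
    name
        Short identifier for the barcoding round this whitelist represents.
    barcodes
        Barcode sequences; lowercase is accepted and uppercased.  Order is
        preserved.

    Raises
    ------
    BarcodeLengthError, DuplicateBarcodeError, AlphabetError
        If the sequences violate a whitelist invariant.
    """

    __slots__ = ("name", "barcodes", "n", "_members")

    def __init__(self, name: str, barcodes: Iterable[str]):
        seqs = tuple(b.upper() for b in barcodes)
        if not seqs:
            raise WhitelistError(f"whitelist {name!r} contains no barcodes")
        n = len(seqs[0])
        seen: set[str] = set()
        for i, b in enumerate(seqs, start=1):
            if len(b) != n:
                raise BarcodeLengthError(
                    f"whitelist {name!r}: barcode #{i} ({b!r}) has length "
                    f"{len(b)}, expected {n}"
                )
            bad = set(b) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"whitelist {name!r}: barcode #{i} ({b!r}) contains "
                    f"non-ACGT character(s) {sorted(bad)}"
                )
            if b in seen:
                raise DuplicateBarcodeError(
                    f"whitelist {name!r}: barcode #{i} ({b!r}) is a duplicate"
                )
            seen.add(b)
        self.name = name
        self.barcodes = seqs
        self.n = n
        self._members = frozenset(seqs)

    def __contains__(self, seq: object) -> bool:
        return seq in self._members

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.barcodes)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Whitelist)
            and other.name == self.name
            and other.barcodes == self.barcodes
        )

    def __hash__(self) -> int:
        return hash((self.name, self.barcodes))

    def __repr__(self) -> str:
        return f"Whitelist(name={self.name!r}, n={self.n}, size={len(self)})"

    @property
    def members(self) -> frozenset[str]:
        return self._members


def load_whitelist(path: str | Path, name: str | None = None) -> Whitelist:
    """Load a whitelist from a plain-text file, one barcode per line.

    Blank lines are ignored; lowercase is uppercased.  Errors name the
    offending line number.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    barcodes: list[str] = []
    lines: list[int] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            b = raw.strip().upper()
            if not b:
                continue
            barcodes.append(b)
            lines.append(lineno)
    if not barcodes:
        raise WhitelistError(f"whitelist file {path} contains no barcodes")
    n = len(barcodes[0])
    seen: dict[str, int] = {}
    for b, lineno in zip(barcodes, lines):
        if len(b) != n:
            raise BarcodeLengthError(
                f"{path}:{lineno}: barcode {b!r} has length {len(b)}, but "
                f"line {lines[0]} established length {n}"
            )
        bad = set(b) - ALPHABET
        if bad:
            raise AlphabetError(
                f"{path}:{lineno}: barcode {b!r} contains non-ACGT "
                f"character(s) {sorted(bad)}"
            )
        if b in seen:
            raise DuplicateBarcodeError(
                f"{path}:{lineno}: barcode {b!r} duplicates line {seen[b]}"
            )
        seen[b] = lineno
    return Whitelist(name, barcodes)


def write_whitelist(wl: Whitelist, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for b in wl.barcodes:
            fh.write(b + "\n")


@dataclass(frozen=True)
class MatchParams:
    """Knobs governing approximate barcode matching.

    Attributes
    ----------
    jitter
        Maximum positional deviation x (nucleotides) from the expected start.
    max_mismatches
        Maximum Hamming substitutions m tolerated (N pads count).
    backend
        ``"set"`` or ``"trie"``.
    seed_kmer_length
        k for the optional k-mer candidate filter of the trie backend.
    """

    jitter: int = 1
    max_mismatches: int = 1
    backend: str = "set"
    seed_kmer_length: int | None = None

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.backend not in ("set", "trie"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.seed_kmer_length is not None and self.seed_kmer_length < 1:
            raise ValueError("seed_kmer_length must be >= 1")

    def validate_for(self, wl: Whitelist) -> None:
        """Reject parameter/whitelist combinations that cannot work."""
        if self.max_mismatches >= wl.n:
            raise ValueError(
                f"max_mismatches={self.max_mismatches} must be < barcode "
                f"length {wl.n} of whitelist {wl.name!r}"
            )
        if self.backend == "trie" and self.seed_kmer_length is not None:
            if self.seed_kmer_length > wl.n:
                raise ValueError(
                    f"seed_kmer_length={self.seed_kmer_length} must be <= "
                    f"barcode length {wl.n} of whitelist {wl.name!r}"
                )


@dataclass(frozen=True)
class ExpectedPosition:
    """One barcode element's location: whitelist, read of the pair, start."""

    whitelist_name: str
    read_index: int
    start: int
    read_fraction: float

    def __post_init__(self) -> None:
        if self.read_index not in (1, 2):
            raise ValueError(f"read_index must be 1 or 2, got {self.read_index}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1 (1-based), got {self.start}")
        if not 0.0 <= self.read_fraction <= 1.0:
            raise ValueError(
                f"read_fraction must be in [0, 1], got {self.read_fraction}"
            )


class MatchStatus(str, Enum):
    EXACT = "exact"
    CORRECTED = "corrected"
    AMBIGUOUS_NULL = "ambiguous_null"
    NO_MATCH_NULL = "no_match_null"

    @property
    def is_null(self) -> bool:
        return self in (MatchStatus.AMBIGUOUS_NULL, MatchStatus.NO_MATCH_NULL)


# Sentinel field values carried by null hits.
NULL_MISMATCHES = -1
NULL_OFFSET = 0


@dataclass(frozen=True)
class BarcodeHit:
    """Result of matching one barcode element in one read."""

    status: MatchStatus
    barcode: str
    mismatches: int
    offset: int
    observed: str

    @property
    def is_null(self) -> bool:
        return self.status.is_null


def null_hit(status: MatchStatus, n: int, observed: str) -> BarcodeHit:
    """Build an all-N null hit of element length ``n``."""
    if not status.is_null:
        raise ValueError(f"{status} is not a null status")
    return BarcodeHit(status, "N" * n, NULL_MISMATCHES, NULL_OFFSET, observed)


@dataclass
class PositionProfile:
    """Histogram of exact-hit start positions for one whitelist on one read.

    ``counts`` maps 1-based start position to the number of sampled reads with
    at least one exact hit starting there; each (read, position) contributes
    at most once.
    """

    whitelist_name: str
    read_index: int
    counts: dict[int, int] = field(default_factory=dict)
    reads_sampled: int = 0

    def read_fraction(self, start: int) -> float:
        if self.reads_sampled == 0:
            return 0.0
        return self.counts.get(start, 0) / self.reads_sampled


# ---------------------------------------------------------------------------
# Expected-positions CSV

POSITIONS_CSV_COLUMNS = ("whitelist", "read_index", "start", "read_fraction")


def write_positions_csv(
    positions: Sequence[ExpectedPosition], path: str | Path
) -> None:
    """Write positions to CSV with header ``whitelist,read_index,start,read_fraction``."""
    if not positions:
        raise ValueError("refusing to write an empty positions CSV")
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(POSITIONS_CSV_COLUMNS)
        for p in positions:
            writer.writerow(
                [p.whitelist_name, p.read_index, p.start, repr(p.read_fraction)]
            )


def read_positions_csv(path: str | Path) -> list[ExpectedPosition]:
    positions: list[ExpectedPosition] = []
    with open(path, "rt", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(
            POSITIONS_CSV_COLUMNS
        ):
            raise PositionsCsvError(
                f"{path}:1: expected header "
                f"{','.join(POSITIONS_CSV_COLUMNS)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(POSITIONS_CSV_COLUMNS):
                raise PositionsCsvError(
                    f"{path}:{lineno}: expected {len(POSITIONS_CSV_COLUMNS)} "
                    f"columns, got {len(row)}"
                )
            try:
                positions.append(
                    ExpectedPosition(
                        whitelist_name=row[0],
                        read_index=int(row[1]),
                        start=int(row[2]),
                        read_fraction=float(row[3]),
                    )
                )
            except ValueError as exc:
                raise PositionsCsvError(f"{path}:{lineno}: {exc}") from exc
    return positions


def check_position_overlaps(
    positions: Sequence[ExpectedPosition], lengths: Mapping[str, int]
) -> list[str]:
    """Warn about same-read positions whose [start, start+n) intervals overlap.

    Overlaps are accepted (the matcher copes) but usually indicate a
    misconfigured layout, so each one is logged.  Returns the warning strings.
    """
    warnings: list[str] = []
    by_read: dict[int, list[ExpectedPosition]] = {}
    for p in positions:
        by_read.setdefault(p.read_index, []).append(p)
    for read_index, group in by_read.items():
        group = sorted(group, key=lambda p: p.start)
        for a, b in zip(group, group[1:]):
            n_a = lengths.get(a.whitelist_name)
            if n_a is None:
                continue
            if a.start + n_a > b.start:
                msg = (
                    f"read {read_index}: element {a.whitelist_name!r} "
                    f"[{a.start}, {a.start + n_a}) overlaps element "
                    f"{b.whitelist_name!r} starting at {b.start}"
                )
                warnings.append(msg)
                logger.warning("%s", msg)
    return warnings


# ---------------------------------------------------------------------------
# Position-profile TSV (seed output / harvest input)
#
# One row per (whitelist, read_index, start).  A whitelist with zero hits on a
# read still emits one sentinel row with start=0, count=0 so that downstream
# stages can distinguish "absent from reads" from "profile never computed".

PROFILE_TSV_COLUMNS = ("whitelist", "read_index", "start", "count", "reads_sampled")


def write_profiles_tsv(
    profiles: Sequence[PositionProfile], path: str | Path
) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(PROFILE_TSV_COLUMNS) + "\n")
        for prof in profiles:
            if prof.counts:
                for start in sorted(prof.counts):
                    fh.write(
                        f"{prof.whitelist_name}\t{prof.read_index}\t{start}\t"
                        f"{prof.counts[start]}\t{prof.reads_sampled}\n"
                    )
            else:
                fh.write(
                    f"{prof.whitelist_name}\t{prof.read_index}\t0\t0\t"
                    f"{prof.reads_sampled}\n"
                )


def read_profiles_tsv(path: str | Path) -> list[PositionProfile]:
    profiles: dict[tuple[str, int], PositionProfile] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(PROFILE_TSV_COLUMNS):
            expected = "\t".join(PROFILE_TSV_COLUMNS)
            raise ProfileTsvError(
                f"{path}:1: expected header {expected!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(PROFILE_TSV_COLUMNS):
                raise ProfileTsvError(
                    f"{path}:{lineno}: expected {len(PROFILE_TSV_COLUMNS)} "
                    f"columns, got {len(parts)}"
                )
            try:
                name = parts[0]
                read_index = int(parts[1])
                start = int(parts[2])
                count = int(parts[3])
                reads_sampled = int(parts[4])
            except ValueError as exc:
                raise ProfileTsvError(f"{path}:{lineno}: {exc}") from exc
            key = (name, read_index)
            prof = profiles.get(key)
            if prof is None:
                prof = PositionProfile(name, read_index, {}, reads_sampled)
                profiles[key] = prof
            prof.reads_sampled = reads_sampled
            if start >= 1:
                prof.counts[start] = count
    return list(profiles.values())
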