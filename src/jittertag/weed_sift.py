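"""Optional stages: ``weed`` recovers a barcode that the sequencing provider
already demultiplexed into the FASTQ header, and ``sift`` drops reads whose
extracted barcodes contain null elements.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pysam

from .barcode_model import (
    BarcodeHit,
    MatchParams,
    MatchStatus,
    Whitelist,
    null_hit,
)
from .matcher_set import hamming
from .seed_profiler import PairingError, iter_fastq

logger = logging.getLogger(__name__)

__all__ = [
    "HeaderBarcodeSpec",
    "WeedError",
    "extract_header_token",
    "weed_extract",
    "run_weed",
    "read_weed_table",
    "SiftPolicy",
    "parse_sift_policy",
    "sift_sam",
    "sift_interleaved_fastq",
]


class WeedError(ValueError):
    pass


@dataclass(frozen=True)
class HeaderBarcodeSpec:
    """How to pull a barcode out of a FASTQ header.

    Token mode splits the header on whitespace, takes the last field (the
    CASAVA-style comment), splits that on ``token_delimiter`` and takes the
    ``token_index``-th token counting from the end (1 = last).  Regex mode
    applies ``pattern`` to the full header and takes capture group 1.
    """

    whitelist_name: str
    mode: str = "token"
    token_delimiter: str = ":"
    token_index: int = 1
    pattern: str | None = None
    element_insert_index: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("token", "regex"):
            raise WeedError(f"unknown header extraction mode {self.mode!r}")
        if self.mode == "regex" and not self.pattern:
            raise WeedError("regex mode requires a pattern")
        if self.mode == "token" and self.token_index < 1:
            raise WeedError("token_index counts from the end and must be >= 1")


def extract_header_token(header: str, spec: HeaderBarcodeSpec) -> str | None:
    """Extract the raw barcode string from a header, or None on failure."""
    header = header.lstrip("@").strip()
    if not header:
        return None
    if spec.mode == "regex":
        assert spec.pattern is not None
        mobj = re.search(spec.pattern, header)
        if not mobj or not mobj.groups():
            return None
        return mobj.group(1)
    fields = header.split()
    if not fields:
        return None
    comment = fields[-1]
    tokens = comment.split(spec.token_delimiter)
    if len(tokens) < spec.token_index:
        return None
    token = tokens[-spec.token_index]
    return token or None


def weed_extract(
    header: str, spec: HeaderBarcodeSpec, wl: Whitelist, params: MatchParams
) -> BarcodeHit:
    """Match the header-extracted barcode against ``wl`` with zero jitter and
    up to ``params.max_mismatches`` substitutions.

    Header fields have no positional uncertainty, so only mismatch
    correction applies; every failure mode yields a null hit.
    """
    n = wl.n
    token = extract_header_token(header, spec)
    if token is None or len(token) != n:
        return null_hit(MatchStatus.NO_MATCH_NULL, n, "N" * n)
    token = token.upper()
    if token in wl:
        return BarcodeHit(MatchStatus.EXACT, token, 0, 0, token)
    m = params.max_mismatches
    best = m + 1
    hits: list[str] = []
    for bc in wl.barcodes:
        d = hamming(token, bc)
        if d < best:
            best = d
            hits = [bc]
        elif d == best:
            hits.append(bc)
    if best > m:
        return null_hit(MatchStatus.NO_MATCH_NULL, n, token)
    if len(hits) > 1:
        return null_hit(MatchStatus.AMBIGUOUS_NULL, n, token)
    return BarcodeHit(MatchStatus.CORRECTED, hits[0], best, 0, token)


def run_weed(
    fastq_path: str | Path,
    spec: HeaderBarcodeSpec,
    wl: Whitelist,
    params: MatchParams,
    out_tsv: str | Path,
) -> dict[str, int]:
    """Extract the header barcode of every read into a TSV keyed by read id."""
    counts = {s.value: 0 for s in MatchStatus}
    extraction_failures = 0
    with open(out_tsv, "wt", encoding="utf-8") as fh:
        fh.write("read_id\tstatus\tbarcode\tmismatches\tobserved\n")
        for rec in iter_fastq(fastq_path):
            header = f"{rec.id} {rec.comment}".strip()
            hit = weed_extract(header, spec, wl, params)
            if hit.status is MatchStatus.NO_MATCH_NULL and hit.observed == "N" * wl.n:
                extraction_failures += 1
            counts[hit.status.value] += 1
            fh.write(
                f"{rec.id}\t{hit.status.value}\t{hit.barcode}\t"
                f"{hit.mismatches}\t{hit.observed}\n"
            )
    if extraction_failures:
        logger.warning(
            "weed: header extraction failed for %d read(s)", extraction_failures
        )
    counts["extraction_failures"] = extraction_failures
    return counts


def read_weed_table(path: str | Path) -> dict[str, BarcodeHit]:
    """Load a weed TSV back into a read_id -> BarcodeHit mapping."""
    out: dict[str, BarcodeHit] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["read_id", "status", "barcode", "mismatches", "observed"]:
            raise WeedError(f"{path}: not a weed table (header {header!r})")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise WeedError(f"{path}:{lineno}: expected 5 columns")
            rid, status, barcode, mm, observed = parts
            out[rid] = BarcodeHit(
                MatchStatus(status), barcode, int(mm), 0, observed
            )
    return out


# ---------------------------------------------------------------------------
# sift


@dataclass(frozen=True)
class SiftPolicy:
    """``any_null_drop`` drops a read with >= 1 null element; ``max_invalid``
    keeps reads with at most ``max_invalid`` null elements."""

    mode: str = "any_null_drop"
    max_invalid: int = 0

    def keeps(self, n_null: int) -> bool:
        if self.mode == "any_null_drop":
            return n_null == 0
        return n_null <= self.max_invalid


def parse_sift_policy(text: str) -> SiftPolicy:
    if text == "any_null_drop":
        return SiftPolicy()
    mobj = re.match(r"^max_invalid:(\d+)$", text)
    if mobj:
        return SiftPolicy("max_invalid", int(mobj.group(1)))
    raise ValueError(
        f"bad sift policy {text!r}; expected 'any_null_drop' or 'max_invalid:<j>'"
    )


def _sam_null_count(aln: pysam.AlignedSegment) -> int:
    if aln.has_tag("XS"):
        statuses = str(aln.get_tag("XS")).split(",")
        return sum(1 for s in statuses if s.endswith("_null"))
    # No per-element record: fall back to CB presence.
    return 0 if aln.has_tag("CB") else 1


def sift_sam(
    in_path: str | Path,
    out_path: str | Path,
    policy: SiftPolicy = SiftPolicy(),
) -> tuple[int, int]:
    """Filter a reap SAM; returns (kept, dropped)."""
    kept = dropped = 0
    with pysam.AlignmentFile(str(in_path), "r", check_sq=False) as src:
        with pysam.AlignmentFile(str(out_path), "w", template=src) as dst:
            for aln in src.fetch(until_eof=True):
                if policy.keeps(_sam_null_count(aln)):
                    dst.write(aln)
                    kept += 1
                else:
                    dropped += 1
    logger.info("sift: kept %d, dropped %d", kept, dropped)
    return kept, dropped


def _fastq_null_count(
    barcode_seq: str, element_lengths: Sequence[int] | None
) -> int:
    if element_lengths is None:
        return 1 if "N" in barcode_seq else 0
    count = 0
    pos = 0
    for n in element_lengths:
        if "N" in barcode_seq[pos : pos + n]:
            count += 1
        pos += n
    return count


def sift_interleaved_fastq(
    in_path: str | Path,
    out_path: str | Path,
    policy: SiftPolicy = SiftPolicy(),
    barcode_length: int | None = None,
    element_lengths: Sequence[int] | None = None,
) -> tuple[int, int]:
    """Filter a reap interleaved FASTQ; A and B records are dropped together.

    Null detection looks for N within the barcode segment of each A record
    (the first ``barcode_length`` bases, or the whole sequence when not
    given).  ``max_invalid`` policies need ``element_lengths`` to count null
    elements.
    """
    if policy.mode == "max_invalid" and element_lengths is None:
        raise ValueError(
            "max_invalid sift policy on interleaved FASTQ requires element_lengths"
        )
    records = list(iter_fastq(in_path))
    if len(records) % 2 != 0:
        raise PairingError(
            f"{in_path}: interleaved FASTQ has an odd record count ({len(records)})"
        )
    kept = dropped = 0
    from .reap import _open_out

    with _open_out(out_path) as fh:
        for i in range(0, len(records), 2):
            a, b = records[i], records[i + 1]
            segment = a.seq[:barcode_length] if barcode_length else a.seq
            if policy.keeps(_fastq_null_count(segment, element_lengths)):
                for rec in (a, b):
                    title = f"{rec.id} {rec.comment}".strip()
                    fh.write(f"@{title}\n{rec.seq}\n+\n{rec.qual}\n")
                kept += 1
            else:
                dropped += 1
    logger.info("sift: kept %d, dropped %d", kept, dropped)
    return kept, dropped
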