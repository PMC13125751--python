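"""The ``reap`` stage: match every barcode element of every read under the
jitter and mismatch budgets, assemble the corrected barcode and UMI, and
emit an unaligned SAM or interleaved FASTQ plus a stats JSON.
"""
from __future__ import annotations

import gzip
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

from . import __version__
from .barcode_model import (
    BarcodeHit,
    ExpectedPosition,
    MatchParams,
    MatchStatus,
    Whitelist,
    check_position_overlaps,
    null_hit,
)
from .matcher_set import SetMatcher
from .matcher_trie import TrieMatcher
from .seed_profiler import ReadRecord, iter_read_tuples

logger = logging.getLogger(__name__)

__all__ = [
    "ReapError",
    "RegionSpec",
    "parse_region_spec",
    "TaggedRead",
    "ReapStats",
    "build_matcher",
    "tag_reads",
    "run_reap",
    "emit_sam",
    "emit_interleaved_fastq",
]

PAD_QUAL = "#"  # Phred 2 placeholder for N pads and null elements


class ReapError(ValueError):
    """Configuration or input error detected before/while reaping."""


_REGION_RE = re.compile(r"^read([12]):(?:(all)|(\d+)-(\d+))$")


@dataclass(frozen=True)
class RegionSpec:
    """A read region: read of the pair plus a 1-based inclusive range
    (``start``/``end`` of None mean the whole read)."""

    read_index: int
    start: int | None = None
    end: int | None = None

    def extract(self, records: Sequence[ReadRecord]) -> tuple[str, str]:
        if self.read_index > len(records):
            raise ReapError(
                f"region references read {self.read_index} but only "
                f"{len(records)} FASTQ file(s) were supplied"
            )
        rec = records[self.read_index - 1]
        if self.start is None:
            return rec.seq, rec.qual
        s0 = self.start - 1
        e0 = self.end if self.end is not None else len(rec.seq)
        return rec.seq[s0:e0], rec.qual[s0:e0]

    def shifted(self, offset: int) -> "RegionSpec":
        if self.start is None:
            return self
        return RegionSpec(self.read_index, self.start + offset, self.end + offset)


def parse_region_spec(spec: str) -> RegionSpec:
    """Parse ``read1:65-74`` or ``read2:all`` into a RegionSpec."""
    mobj = _REGION_RE.match(spec)
    if not mobj:
        raise ReapError(
            f"bad region spec {spec!r}; expected e.g. 'read1:65-74' or 'read2:all'"
        )
    read_index = int(mobj.group(1))
    if mobj.group(2) == "all":
        return RegionSpec(read_index)
    start, end = int(mobj.group(3)), int(mobj.group(4))
    if start < 1 or end < start:
        raise ReapError(f"bad region range in {spec!r}")
    return RegionSpec(read_index, start, end)


@dataclass
class TaggedRead:
    """A read pair plus its assembled barcode information."""

    read_id: str
    target_seq: str
    target_quals: str
    corrected_barcode: str
    raw_barcode: str
    barcode_quals: str
    umi_seq: str
    umi_quals: str
    element_hits: list[tuple[str, BarcodeHit]]

    @property
    def any_null(self) -> bool:
        return any(hit.is_null for _, hit in self.element_hits)

    @property
    def total_mismatches(self) -> int:
        return sum(
            hit.mismatches for _, hit in self.element_hits if not hit.is_null
        )


@dataclass
class ReapStats:
    """Counters accumulated over one reap run."""

    element_names: list[str]
    total_reads: int = 0
    reads_all_elements_valid: int = 0
    reads_all_elements_exact: int = 0
    status_counts: dict[str, Counter] = field(default_factory=dict)
    offset_histograms: dict[str, Counter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.element_names:
            self.status_counts.setdefault(name, Counter())
            self.offset_histograms.setdefault(name, Counter())

    def update(self, tagged: TaggedRead) -> None:
        self.total_reads += 1
        if not tagged.any_null:
            self.reads_all_elements_valid += 1
            if all(
                hit.status is MatchStatus.EXACT for _, hit in tagged.element_hits
            ):
                self.reads_all_elements_exact += 1
        for name, hit in tagged.element_hits:
            self.status_counts[name][hit.status.value] += 1
            if not hit.is_null:
                self.offset_histograms[name][hit.offset] += 1

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "reads_all_elements_valid": self.reads_all_elements_valid,
            "reads_all_elements_exact": self.reads_all_elements_exact,
            "elements": {
                name: {
                    "statuses": dict(self.status_counts[name]),
                    "offsets": {
                        str(k): v
                        for k, v in sorted(self.offset_histograms[name].items())
                    },
                }
                for name in self.element_names
            },
        }


def build_matcher(wl: Whitelist, params: MatchParams):
    if params.backend == "trie":
        return TrieMatcher(wl, params, use_kmer=params.seed_kmer_length is not None)
    return SetMatcher(wl, params)


def _element_quals(
    hit: BarcodeHit, record: ReadRecord, expected_start: int, n: int
) -> str:
    """Per-base qualities for one element of the corrected barcode: the
    read's qualities at the matched window, PAD_QUAL where off-read or null."""
    if hit.is_null:
        return PAD_QUAL * n
    s0 = expected_start - 1 + hit.offset
    quals = []
    for p in range(s0, s0 + n):
        quals.append(record.qual[p] if 0 <= p < len(record.qual) else PAD_QUAL)
    return "".join(quals)


def tag_reads(
    read_tuples: Iterable[tuple[ReadRecord, ...]],
    positions: Sequence[ExpectedPosition],
    matchers: Mapping[str, object],
    whitelists: Mapping[str, Whitelist],
    stats: ReapStats,
    umi_spec: RegionSpec | None = None,
    target_spec: RegionSpec | None = None,
    umi_anchor: str | None = None,
    weed_hits: Mapping[str, BarcodeHit] | None = None,
    weed_name: str | None = None,
    weed_insert_index: int = 0,
    weed_n: int = 0,
) -> Iterator[TaggedRead]:
    """Match elements read by read and yield TaggedReads, updating ``stats``."""
    for records in read_tuples:
        hits: list[tuple[str, BarcodeHit, str]] = []
        for ep in positions:
            if ep.read_index > len(records):
                raise ReapError(
                    f"positions CSV references read {ep.read_index} but only "
                    f"{len(records)} FASTQ file(s) were supplied"
                )
            record = records[ep.read_index - 1]
            matcher = matchers[ep.whitelist_name]
            hit = matcher.match(record.seq, ep.start)  # type: ignore[attr-defined]
            n = whitelists[ep.whitelist_name].n
            hits.append((ep.whitelist_name, hit, _element_quals(hit, record, ep.start, n)))
        if weed_hits is not None and weed_name is not None:
            whit = weed_hits.get(records[0].id)
            if whit is None:
                whit = null_hit(MatchStatus.NO_MATCH_NULL, weed_n, "N" * weed_n)
            wq = PAD_QUAL * weed_n if whit.is_null else "I" * weed_n
            hits.insert(weed_insert_index, (weed_name, whit, wq))

        anchor_offset = 0
        if umi_anchor is not None:
            for name, hit, _ in hits:
                if name == umi_anchor:
                    if not hit.is_null:
                        anchor_offset = hit.offset
                    break
            else:
                raise ReapError(f"--umi-anchor element {umi_anchor!r} not found")

        umi_seq = umi_quals = ""
        if umi_spec is not None:
            umi_seq, umi_quals = umi_spec.shifted(anchor_offset).extract(records)
        if target_spec is not None:
            target_seq, target_quals = target_spec.extract(records)
        else:
            rec = records[-1]
            target_seq, target_quals = rec.seq, rec.qual
        tagged = TaggedRead(
            read_id=records[0].id,
            target_seq=target_seq,
            target_quals=target_quals,
            corrected_barcode="".join(h.barcode for _, h, _ in hits),
            raw_barcode="".join(h.observed for _, h, _ in hits),
            barcode_quals="".join(q for _, _, q in hits),
            umi_seq=umi_seq,
            umi_quals=umi_quals,
            element_hits=[(nm, h) for nm, h, _ in hits],
        )
        stats.update(tagged)
        yield tagged


def emit_sam(
    tagged: Iterable[TaggedRead], out_path: str | Path, command_line: str = ""
) -> int:
    """Write unaligned SAM records (flag 4, no reference) with barcode tags.

    Tags: CR raw barcode, CB corrected barcode (omitted when any element is
    null), UR/UY UMI sequence/qualities, XM total mismatches, XJ per-element
    offsets, XS per-element statuses.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "PG": [
            {
                "ID": "jittertag",
                "PN": "jittertag",
                "VN": __version__,
                "CL": command_line or "jittertag reap",
            }
        ],
    }
    count = 0
    with pysam.AlignmentFile(str(out_path), "w", header=header) as sam:
        for tr in tagged:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = tr.read_id
            a.flag = 4  # unmapped
            a.query_sequence = tr.target_seq
            a.query_qualities = pysam.qualitystring_to_array(tr.target_quals)
            tags: list[tuple[str, object]] = [("CR", tr.raw_barcode)]
            if not tr.any_null:
                tags.append(("CB", tr.corrected_barcode))
            if tr.umi_seq:
                tags.append(("UR", tr.umi_seq))
                tags.append(("UY", tr.umi_quals))
            tags.append(("XM", tr.total_mismatches))
            tags.append(
                (
                    "XJ",
                    ",".join(
                        "." if h.is_null else str(h.offset)
                        for _, h in tr.element_hits
                    ),
                )
            )
            tags.append(
                ("XS", ",".join(h.status.value for _, h in tr.element_hits))
            )
            a.set_tags(tags)
            sam.write(a)
            count += 1
    return count


def iter_sam(path: str | Path) -> Iterator[pysam.AlignedSegment]:
    """Iterate an unaligned (reference-less) SAM file."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        yield from fh.fetch(until_eof=True)


def _open_out(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "wt")


def emit_interleaved_fastq(tagged: Iterable[TaggedRead], out_path: str | Path) -> int:
    """Write interleaved FASTQ: record A = corrected barcode + UMI, record B
    = target; A and B share the read id with /1 and /2 suffixes."""
    count = 0
    with _open_out(out_path) as fh:
        for tr in tagged:
            fh.write(
                f"@{tr.read_id}/1\n{tr.corrected_barcode}{tr.umi_seq}\n+\n"
                f"{tr.barcode_quals}{tr.umi_quals}\n"
            )
            fh.write(
                f"@{tr.read_id}/2\n{tr.target_seq}\n+\n{tr.target_quals}\n"
            )
            count += 1
    return count


def run_reap(
    fastq_paths: Sequence[str | Path],
    positions: Sequence[ExpectedPosition],
    whitelists: Mapping[str, Whitelist],
    params: MatchParams,
    out_path: str | Path,
    out_format: str = "sam",
    umi_spec: RegionSpec | str | None = None,
    target_spec: RegionSpec | str | None = None,
    umi_anchor: str | None = None,
    stats_path: str | Path | None = None,
    weed_hits: Mapping[str, BarcodeHit] | None = None,
    weed_name: str | None = None,
    weed_insert_index: int = 0,
    command_line: str = "",
) -> ReapStats:
    """Run the full extraction over every read pair.

    Every input read tuple yields exactly one output record; stats are
    serialized as JSON next to the output (``<out>.stats.json`` by default).
    """
    if out_format not in ("sam", "interleaved_fastq"):
        raise ReapError(f"unknown output format {out_format!r}")
    if isinstance(umi_spec, str):
        umi_spec = parse_region_spec(umi_spec)
    if isinstance(target_spec, str):
        target_spec = parse_region_spec(target_spec)
    missing = [p.whitelist_name for p in positions if p.whitelist_name not in whitelists]
    if missing:
        raise ReapError(
            f"positions CSV names whitelist(s) with no supplied file: {missing}"
        )
    check_position_overlaps(
        positions, {name: wl.n for name, wl in whitelists.items()}
    )
    matchers = {}
    for p in positions:
        if p.whitelist_name not in matchers:
            matchers[p.whitelist_name] = build_matcher(
                whitelists[p.whitelist_name], params
            )
    element_names = [p.whitelist_name for p in positions]
    weed_n = 0
    if weed_hits is not None:
        if weed_name is None:
            raise ReapError("weed_hits supplied without weed_name")
        if weed_name not in whitelists:
            raise ReapError(f"weed whitelist {weed_name!r} has no supplied file")
        weed_n = whitelists[weed_name].n
        element_names.insert(weed_insert_index, weed_name)
    stats = ReapStats(element_names)
    stream = tag_reads(
        iter_read_tuples(fastq_paths),
        positions,
        matchers,
        whitelists,
        stats,
        umi_spec=umi_spec,
        target_spec=target_spec,
        umi_anchor=umi_anchor,
        weed_hits=weed_hits,
        weed_name=weed_name if weed_hits is not None else None,
        weed_insert_index=weed_insert_index,
        weed_n=weed_n,
    )
    if out_format == "sam":
        written = emit_sam(stream, out_path, command_line=command_line)
    else:
        written = emit_interleaved_fastq(stream, out_path)
    logger.info(
        "reap: %d reads processed, %d with all elements valid, %d all exact",
        stats.total_reads,
        stats.reads_all_elements_valid,
        stats.reads_all_elements_exact,
    )
    assert written == stats.total_reads
    if stats_path is None:
        stats_path = str(out_path) + ".stats.json"
    payload = stats.to_dict()
    payload["parameters"] = {
        "jitter": params.jitter,
        "max_mismatches": params.max_mismatches,
        "backend": params.backend,
        "command_line": command_line,
    }
    with open(stats_path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return stats
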