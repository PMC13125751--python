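"""The ``harvest`` stage: aggregate seed profiles into an expected-positions
CSV and diagnose library-structure problems (low read fraction, multimodal
position histograms, whitelists absent from the reads).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .barcode_model import (
    ExpectedPosition,
    PositionProfile,
    read_profiles_tsv,
    write_positions_csv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LOW_FRACTION_THRESHOLD",
    "DEFAULT_MULTIMODAL_THRESHOLD",
    "HarvestEntry",
    "HarvestConflictError",
    "pick_expected_position",
    "run_harvest",
]

DEFAULT_LOW_FRACTION_THRESHOLD = 0.05
DEFAULT_MULTIMODAL_THRESHOLD = 0.5

FLAG_LOW_READ_FRACTION = "low_read_fraction"
FLAG_MULTIMODAL = "multimodal"
FLAG_ABSENT = "absent"


class HarvestConflictError(ValueError):
    """The same whitelist appears in more than one profile file."""


@dataclass(frozen=True)
class HarvestEntry:
    """Diagnostic summary for one whitelist."""

    whitelist_name: str
    position: ExpectedPosition | None  # None when absent
    peak_count: int
    secondary_peak_fraction: float
    flags: frozenset[str]


def _pick(
    whitelist_name: str,
    counts: dict[tuple[int, int], int],
    reads_sampled: int,
    low_fraction_threshold: float,
    multimodal_threshold: float,
) -> HarvestEntry:
    """Core peak-picker over counts keyed by (read_index, start)."""
    if not counts:
        return HarvestEntry(
            whitelist_name, None, 0, 0.0, frozenset({FLAG_ABSENT})
        )
    # argmax; ties broken toward (smaller read index, smaller start)
    peak_key = min(counts, key=lambda k: (-counts[k], k))
    peak_count = counts[peak_key]
    rest = [v for k, v in counts.items() if k != peak_key]
    secondary = max(rest) if rest else 0
    secondary_fraction = secondary / peak_count if peak_count else 0.0
    read_fraction = peak_count / reads_sampled if reads_sampled else 0.0
    flags = set()
    if read_fraction < low_fraction_threshold:
        flags.add(FLAG_LOW_READ_FRACTION)
    if secondary_fraction > multimodal_threshold:
        flags.add(FLAG_MULTIMODAL)
    position = ExpectedPosition(
        whitelist_name, peak_key[0], peak_key[1], read_fraction
    )
    return HarvestEntry(
        whitelist_name, position, peak_count, secondary_fraction, frozenset(flags)
    )


def pick_expected_position(
    profile: PositionProfile,
    low_fraction_threshold: float = DEFAULT_LOW_FRACTION_THRESHOLD,
    multimodal_threshold: float = DEFAULT_MULTIMODAL_THRESHOLD,
) -> HarvestEntry:
    """Choose the modal start of a single profile and derive its flags.

    start = argmax of counts (ties toward the smaller start);
    read_fraction = peak count / reads sampled.
    """
    counts = {(profile.read_index, s): c for s, c in profile.counts.items()}
    return _pick(
        profile.whitelist_name,
        counts,
        profile.reads_sampled,
        low_fraction_threshold,
        multimodal_threshold,
    )


def _combine_profiles(
    profiles: Sequence[PositionProfile],
    low_fraction_threshold: float,
    multimodal_threshold: float,
) -> HarvestEntry:
    """Pick across all read indices of one whitelist at once."""
    counts: dict[tuple[int, int], int] = {}
    reads_sampled = 0
    for prof in profiles:
        reads_sampled = max(reads_sampled, prof.reads_sampled)
        for start, c in prof.counts.items():
            counts[(prof.read_index, start)] = c
    return _pick(
        profiles[0].whitelist_name,
        counts,
        reads_sampled,
        low_fraction_threshold,
        multimodal_threshold,
    )


def format_report(entries: Sequence[HarvestEntry]) -> str:
    lines = []
    for e in entries:
        if e.position is None:
            lines.append(
                f"{e.whitelist_name}: ABSENT — no exact hits in the sampled "
                f"reads; row omitted from the positions CSV. Check whitelist "
                f"orientation and library structure."
            )
            continue
        flags = ",".join(sorted(e.flags)) if e.flags else "-"
        line = (
            f"{e.whitelist_name}: read={e.position.read_index} "
            f"start={e.position.start} peak_count={e.peak_count} "
            f"read_fraction={e.position.read_fraction:.4f} "
            f"secondary_peak_fraction={e.secondary_peak_fraction:.4f} "
            f"flags={flags}"
        )
        if FLAG_LOW_READ_FRACTION in e.flags:
            line += (
                " | low read fraction: this barcode may already have been "
                "demultiplexed by the provider — recover it from the FASTQ "
                "header with the weed command and remove its row from the "
                "positions CSV"
            )
        if FLAG_MULTIMODAL in e.flags:
            line += (
                " | multimodal position histogram: check for adapter "
                "trimming or variable library structure"
            )
        lines.append(line)
    return "\n".join(lines) + "\n"


def run_harvest(
    profile_paths: Sequence[str | Path],
    out_csv: str | Path,
    report_path: str | Path | None = None,
    low_fraction_threshold: float = DEFAULT_LOW_FRACTION_THRESHOLD,
    multimodal_threshold: float = DEFAULT_MULTIMODAL_THRESHOLD,
) -> list[HarvestEntry]:
    """Aggregate one or more profile TSVs into an expected-positions CSV.

    Emits one CSV row per non-absent whitelist, ordered by
    (read_index, start); that order defines barcode concatenation order in
    reap.  A plain-text report with per-whitelist diagnostics is written
    alongside when ``report_path`` is given.
    """
    if not profile_paths:
        raise ValueError("at least one profile file is required")
    by_whitelist: dict[str, list[PositionProfile]] = {}
    origin: dict[str, str] = {}
    for path in profile_paths:
        for prof in read_profiles_tsv(path):
            if prof.whitelist_name in origin and origin[prof.whitelist_name] != str(path):
                raise HarvestConflictError(
                    f"whitelist {prof.whitelist_name!r} appears in both "
                    f"{origin[prof.whitelist_name]} and {path}"
                )
            origin[prof.whitelist_name] = str(path)
            by_whitelist.setdefault(prof.whitelist_name, []).append(prof)
    entries = [
        _combine_profiles(profs, low_fraction_threshold, multimodal_threshold)
        for profs in by_whitelist.values()
    ]
    entries.sort(
        key=lambda e: (
            (e.position.read_index, e.position.start)
            if e.position is not None
            else (99, 10**9)
        )
    )
    positions = [e.position for e in entries if e.position is not None]
    for e in entries:
        if e.position is None:
            logger.warning(
                "whitelist %r: no exact hits found in sampled reads; "
                "omitted from %s",
                e.whitelist_name,
                out_csv,
            )
    if positions:
        write_positions_csv(positions, out_csv)
    else:
        logger.warning("no whitelist produced a position; %s not written", out_csv)
    if report_path is not None:
        with open(report_path, "wt", encoding="utf-8") as fh:
            fh.write(format_report(entries))
    return entries
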