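"""Mapping-based validation of k-mer containment results.

Given read alignments of a metagenome against a query genome, computes
breadth of coverage ("percentage of the genome detected": positions with
depth >= 1), effective coverage (mean depth over the detected portion —
this package's definition), and the number of primary-mapped reads, and
compares them with k-mer containment.  Read mapping tolerates mismatches
that break exact k-mers, so detection generally meets or exceeds
containment for genuinely present organisms.

Accepted alignment formats: PAF (minimap2-style) and SAM (via pysam).
Secondary/supplementary alignments contribute to depth but not to the
mapped-read count.  Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .search import SearchHit

__all__ = [
    "AlignmentRecord",
    "CoverageReport",
    "parse_alignments",
    "coverage_report",
    "compare_containment_vs_detection",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-genome alignment (0-based half-open target interval)."""

    read_id: str
    target_id: str
    target_start: int
    target_end: int
    aligned_bases: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.target_start < self.target_end:
            raise ValueError(
                f"invalid interval [{self.target_start}, {self.target_end}) "
                f"for read {self.read_id!r}"
            )
        if self.aligned_bases > self.target_end - self.target_start:
            raise ValueError(
                f"aligned_bases {self.aligned_bases} exceeds target span for "
                f"read {self.read_id!r}"
            )


@dataclass(frozen=True)
class CoverageReport:
    """Mapping-based detection metrics for one (query genome, sample) pair."""

    query_name: str
    subject_id: str
    genome_length_bp: int
    covered_bp: int
    detection_pct: float
    effective_coverage: float
    n_mapped_reads: int


def _parse_paf_line(line: str, lineno: int, path: str) -> AlignmentRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"{path}:{lineno}: PAF line has {len(fields)} fields (<12)")
    try:
        tstart, tend = int(fields[7]), int(fields[8])
        block_len = int(fields[10])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinate field") from exc
    is_primary = True
    for tag in fields[12:]:
        if tag.startswith("tp:A:"):
            is_primary = tag[5] == "P"
    return AlignmentRecord(
        read_id=fields[0],
        target_id=fields[5],
        target_start=tstart,
        target_end=tend,
        aligned_bases=min(block_len, tend - tstart),
        is_primary=is_primary,
    )


def _parse_paf(path: Path, known_targets: Mapping[str, int] | None) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            rec = _parse_paf_line(line, lineno, str(path))
            if rec.target_id == "*":
                continue  # unmapped
            if known_targets is not None and rec.target_id not in known_targets:
                raise ValueError(
                    f"{path}:{lineno}: unknown target_id {rec.target_id!r}"
                )
            records.append(rec)
    return records


def _parse_sam(path: Path, known_targets: Mapping[str, int] | None) -> list[AlignmentRecord]:
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            target_id = read.reference_name
            if known_targets is not None and target_id not in known_targets:
                raise ValueError(f"{path}: unknown target_id {target_id!r}")
            # aligned bases on the target: CIGAR M/=/X (deletions span but
            # do not align bases)
            aligned = sum(
                length for op, length in (read.cigartuples or []) if op in (0, 7, 8)
            )
            records.append(
                AlignmentRecord(
                    read_id=read.query_name,
                    target_id=target_id,
                    target_start=read.reference_start,
                    target_end=read.reference_end,
                    aligned_bases=aligned,
                    is_primary=not (read.is_secondary or read.is_supplementary),
                )
            )
    return records


def parse_alignments(
    path: str | Path,
    fmt: str | None = None,
    known_targets: Mapping[str, int] | None = None,
) -> list[AlignmentRecord]:
    """Parse a PAF or SAM alignment file into normalized records.

    ``fmt`` is inferred from the extension when omitted.  Unmapped records
    are skipped; malformed lines raise with a line diagnostic; with
    ``known_targets`` (target_id -> length), unknown targets raise.
    """
    path = Path(path)
    if fmt is None:
        ext = path.suffix.lower()
        fmt = {"paf": "paf", ".paf": "paf", ".sam": "sam"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer alignment format from {path.name!r}")
    if fmt == "paf":
        return _parse_paf(path, known_targets)
    if fmt == "sam":
        return _parse_sam(path, known_targets)
    raise ValueError(f"unsupported alignment format {fmt!r}")


def coverage_report(
    alignments: Sequence[AlignmentRecord],
    genome_length_bp: int,
    query_name: str,
    subject_id: str,
) -> CoverageReport:
    """Breadth/depth statistics from the union of alignment intervals.

    detection_pct = 100 × covered positions / genome length;
    effective_coverage = total aligned bases / covered positions (0 when
    nothing is covered); n_mapped_reads counts distinct read_ids with at
    least one primary alignment.  Order-invariant and deterministic.
    """
    if genome_length_bp <= 0:
        raise ValueError(f"genome_length_bp must be > 0, got {genome_length_bp}")
    delta = np.zeros(genome_length_bp + 1, dtype=np.int64)
    total_aligned = 0
    primary_reads: set[str] = set()
    for rec in alignments:
        if rec.target_end > genome_length_bp:
            raise ValueError(
                f"alignment [{rec.target_start}, {rec.target_end}) for read "
                f"{rec.read_id!r} exceeds genome length {genome_length_bp}"
            )
        delta[rec.target_start] += 1
        delta[rec.target_end] -= 1
        total_aligned += rec.aligned_bases
        if rec.is_primary:
            primary_reads.add(rec.read_id)
    depth = np.cumsum(delta[:-1])
    covered = int((depth > 0).sum())
    return CoverageReport(
        query_name=query_name,
        subject_id=subject_id,
        genome_length_bp=genome_length_bp,
        covered_bp=covered,
        detection_pct=100.0 * covered / genome_length_bp,
        effective_coverage=(total_aligned / covered) if covered else 0.0,
        n_mapped_reads=len(primary_reads),
    )


def compare_containment_vs_detection(
    hit: SearchHit, report: CoverageReport
) -> dict:
    """Side-by-side row of k-mer containment and mapping detection for one
    (query, sample) pair, with a flag for detection >= containment."""
    if (hit.query_name, hit.subject_id) != (report.query_name, report.subject_id):
        raise ValueError(
            f"pair mismatch: hit is ({hit.query_name!r}, {hit.subject_id!r}), "
            f"report is ({report.query_name!r}, {report.subject_id!r})"
        )
    containment_pct = 100.0 * hit.containment
    return {
        "query_name": hit.query_name,
        "subject_id": hit.subject_id,
        "containment_pct": containment_pct,
        "effective_coverage": report.effective_coverage,
        "detection_pct": report.detection_pct,
        "n_mapped_reads": report.n_mapped_reads,
        "detection_ge_containment": report.detection_pct >= containment_pct,
    }
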