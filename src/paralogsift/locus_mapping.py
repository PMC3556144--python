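"""Clustering of tabular local-alignment hits into gene-copy models.

A multi-copy gene family shows up in a genome search as runs of exon-sized
hits separated by intronic gaps; runs belonging to different copies are
separated by much larger inter-copy gaps.  Clustering hits along the subject
axis with a single gap threshold therefore recovers one model per gene copy,
with the member hits as its exons.

All coordinates are 1-based inclusive, matching the convention of tabular
BLAST output; conversion to 0-based half-open happens only when writing BED.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "HitRecord",
    "GeneCopyModel",
    "parse_hit_table",
    "cluster_hits",
    "locus_span",
    "write_bed",
    "write_report",
    "DEFAULT_MAX_GAP",
]

#: Default clustering gap (bp).  Intra-copy (intronic) gaps in a compact
#: three-exon gene are ~2 kb while inter-copy gaps are tens of kb or more,
#: so 10 kb separates the two regimes robustly.
DEFAULT_MAX_GAP = 10_000


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular local-alignment hit file, subject-normalized."""

    query_id: str
    subject_id: str
    subject_start: int  # 1-based inclusive, always <= subject_end
    subject_end: int
    percent_identity: float
    e_value: float
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.subject_start > self.subject_end:
            raise ValueError("subject_start must be <= subject_end")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must be in [0, 100]")
        if self.e_value < 0:
            raise ValueError("e_value must be nonnegative")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.subject_end - self.subject_start + 1


@dataclass
class GeneCopyModel:
    """A clustered set of exon intervals interpreted as one gene copy."""

    copy_id: str
    exons: list[tuple[int, int]]  # chromosome order, 1-based inclusive
    orientation: str
    chromosome: str = ""
    span_bp: int = field(init=False)

    def __post_init__(self) -> None:
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError("exons must be non-overlapping")
        self.exons = exons
        self.start = exons[0][0]
        self.end = exons[-1][1]
        self.span_bp = self.end - self.start + 1


def parse_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tabular hit file (BLAST ``-outfmt 6`` layout).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Subject coordinates given in descending
    order denote a minus-strand hit and are normalized to start <= end.

    Raises ``ValueError`` naming the offending line on malformed input.
    """
    records: list[HitRecord] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                sstart, send = int(fields[8]), int(fields[9])
                pident = float(fields[2])
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            strand = "+" if sstart <= send else "-"
            if strand == "-":
                sstart, send = send, sstart
            records.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    subject_start=sstart,
                    subject_end=send,
                    percent_identity=pident,
                    e_value=evalue,
                    strand=strand,
                )
            )
    return records


def cluster_hits(
    hits: Iterable[HitRecord],
    max_gap: int = DEFAULT_MAX_GAP,
    copy_prefix: str = "copy",
) -> list[GeneCopyModel]:
    """Cluster hits along the subject axis into gene-copy models.

    Hits are sorted by start; a new copy begins whenever the gap from the
    previous hit's end to the next hit's start exceeds ``max_gap``.  Copy
    orientation is the majority strand of the member hits (ties resolve to
    "+" with a warning).  Hit order in the input is irrelevant.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    hits = sorted(hits, key=lambda h: (h.subject_start, h.subject_end))
    if not hits:
        return []
    subjects = {h.subject_id for h in hits}
    if len(subjects) > 1:
        raise ValueError(f"hits span multiple subjects: {sorted(subjects)}")
    chromosome = hits[0].subject_id

    groups: list[list[HitRecord]] = [[hits[0]]]
    for hit in hits[1:]:
        gap = hit.subject_start - groups[-1][-1].subject_end
        if gap > max_gap:
            groups.append([hit])
        else:
            groups[-1].append(hit)

    copies = []
    for i, group in enumerate(groups, start=1):
        plus = sum(1 for h in group if h.strand == "+")
        minus = len(group) - plus
        if plus == minus:
            orientation = "+"
            if minus:  # a real tie, not an all-plus group of even size
                warnings.warn(
                    f"{copy_prefix}{i}: strand tie ({plus}+/{minus}-); "
                    "defaulting orientation to '+'",
                    stacklevel=2,
                )
        else:
            orientation = "+" if plus > minus else "-"
        copies.append(
            GeneCopyModel(
                copy_id=f"{copy_prefix}{i}",
                exons=[(h.subject_start, h.subject_end) for h in group],
                orientation=orientation,
                chromosome=chromosome,
            )
        )
    return copies


def locus_span(copies: Sequence[GeneCopyModel]) -> int:
    """Span in bp from the first to the last exon base over all copies."""
    if not copies:
        raise ValueError("locus_span requires at least one copy")
    start = min(c.start for c in copies)
    end = max(c.end for c in copies)
    return end - start + 1


def write_bed(copies: Sequence[GeneCopyModel], path: str | Path) -> None:
    """Write copy models as BED6 (0-based half-open), one line per copy."""
    with Path(path).open("w") as fh:
        for c in copies:
            fh.write(
                f"{c.chromosome}\t{c.start - 1}\t{c.end}\t{c.copy_id}\t0\t{c.orientation}\n"
            )


def write_report(copies: Sequence[GeneCopyModel], path: str | Path) -> None:
    payload = {
        "n_copies": len(copies),
        "locus_span_bp": locus_span(copies) if copies else 0,
        "copies": [
            {
                "copy_id": c.copy_id,
                "chromosome": c.chromosome,
                "orientation": c.orientation,
                "span_bp": c.span_bp,
                "exons": [list(e) for e in c.exons],
            }
            for c in copies
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
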