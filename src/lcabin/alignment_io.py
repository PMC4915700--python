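"""Tabular DNA-to-protein alignment parsing and reference-id resolution.

Reads the 12-column BLAST tabular format (``blastx -outfmt 6`` /
``diamond --outfmt 6`` / "m8"): qseqid, sseqid, pident, length, mismatch,
gapopen, qstart, qend, sstart, send, evalue, bitscore.  Query coordinates
are nucleotides on the read, subject coordinates amino acids on the
reference; a query start greater than the query end encodes a
reverse-strand (negative-frame) alignment and is normalized on input
(start/end swapped, ``reverse`` flag set) and restored on output.

Reference headers are resolved to taxonomic or functional class ids by
one of three mechanisms: an embedded ``tag|id`` token (e.g. ``tax|666``),
a numeric-id lookup table, or an accession table consulted with and
without the trailing version suffix.
"""

from __future__ import annotations

import gzip
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

__all__ = [
    "AlignmentRecord",
    "ReadAlignments",
    "RefClassMap",
    "ParseError",
    "parse_tabular",
    "group_by_read",
    "serialize_record",
    "resolve_class",
    "filter_significant",
    "open_maybe_gzip",
]


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentRecord:
    """One parsed alignment row (coordinates 1-based inclusive)."""

    read_id: str
    ref_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    evalue: float
    bitscore: float
    reverse: bool = False

    def __post_init__(self) -> None:
        if self.bitscore < 0 or self.evalue < 0:
            raise ParseError(
                f"negative score/evalue for read {self.read_id!r}: "
                f"bitscore={self.bitscore}, evalue={self.evalue}"
            )
        if min(self.read_start, self.read_end, self.ref_start, self.ref_end) < 1:
            raise ParseError(f"non-positive coordinate for read {self.read_id!r}")

    @property
    def read_span(self) -> int:
        return abs(self.read_end - self.read_start) + 1


@dataclass
class ReadAlignments:
    """All alignments of one read, ordered by descending bitscore."""

    read_id: str
    records: list[AlignmentRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"empty alignment set for read {self.read_id!r}")
        # stable: preserves input order among equal scores
        self.records = sorted(self.records, key=lambda r: -r.bitscore)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AlignmentRecord]:
        return iter(self.records)


_TAG_CACHE: dict[str, re.Pattern[str]] = {}


@dataclass(frozen=True)
class RefClassMap:
    """Deterministic reference-header → class-id resolution.

    mode ``header-tag``: scan the header for ``<tag>|<integer>``.
    mode ``numeric-id-table``: look the first whitespace-free token up.
    mode ``accession-table``: as above, falling back to the
    version-stripped token (``ABC123.2`` → ``ABC123``).
    """

    mode: str  # {header-tag, numeric-id-table, accession-table}
    tag: str = "tax"
    table: dict[str, int | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("header-tag", "numeric-id-table", "accession-table"):
            raise ValueError(f"unknown mapping mode {self.mode!r}")


def resolve_class(ref_map: RefClassMap, ref_header: str):
    """Class id for *ref_header*, or ``None`` when nothing resolves."""
    if not ref_header:
        raise ValueError("empty reference header")
    if ref_map.mode == "header-tag":
        pat = _TAG_CACHE.get(ref_map.tag)
        if pat is None:
            pat = re.compile(re.escape(ref_map.tag) + r"\|(\d+)")
            _TAG_CACHE[ref_map.tag] = pat
        m = pat.search(ref_header)
        return int(m.group(1)) if m else None
    token = ref_header.split()[0]
    hit = ref_map.table.get(token)
    if hit is None and ref_map.mode == "accession-table" and "." in token:
        hit = ref_map.table.get(token.rsplit(".", 1)[0])
    return hit


def open_maybe_gzip(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def parse_tabular(source: TextIO | Iterable[str]) -> Iterator[AlignmentRecord]:
    """Yield one :class:`AlignmentRecord` per well-formed 12-column row.

    Blank lines and ``#`` comments are skipped; short or non-numeric rows
    raise :class:`ParseError` naming the line.
    """
    for lineno, line in enumerate(source, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise ParseError(f"line {lineno}: expected >=12 tab-separated fields, got {len(fields)}")
        try:
            qstart, qend = int(fields[6]), int(fields[7])
            reverse = qstart > qend
            if reverse:
                qstart, qend = qend, qstart
            rec = AlignmentRecord(
                read_id=fields[0],
                ref_id=fields[1],
                percent_identity=float(fields[2]),
                align_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                read_start=qstart,
                read_end=qend,
                ref_start=int(fields[8]),
                ref_end=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
                reverse=reverse,
            )
        except (ValueError, ParseError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        yield rec


def serialize_record(rec: AlignmentRecord) -> str:
    """Inverse of :func:`parse_tabular` for one record (no newline)."""
    qstart, qend = rec.read_start, rec.read_end
    if rec.reverse:
        qstart, qend = qend, qstart

    def num(x: float) -> str:
        return f"{x:g}"

    return "\t".join(
        [
            rec.read_id,
            rec.ref_id,
            num(rec.percent_identity),
            str(rec.align_length),
            str(rec.mismatches),
            str(rec.gap_opens),
            str(qstart),
            str(qend),
            str(rec.ref_start),
            str(rec.ref_end),
            num(rec.evalue),
            num(rec.bitscore),
        ]
    )


def group_by_read(records: Iterable[AlignmentRecord]) -> Iterator[ReadAlignments]:
    """Group a read-contiguous record stream into per-read alignment sets.

    Input rows for one read must be adjacent (the natural order of
    aligner output); a read id reappearing after its group closed raises
    :class:`ParseError` rather than silently splitting the read.
    """
    seen: set[str] = set()
    current_id: str | None = None
    buffer: list[AlignmentRecord] = []
    for rec in records:
        if rec.read_id != current_id:
            if buffer:
                yield ReadAlignments(current_id, buffer)  # type: ignore[arg-type]
            if rec.read_id in seen:
                raise ParseError(
                    f"read {rec.read_id!r} reappears after its group closed; "
                    "input must be read-contiguous"
                )
            seen.add(rec.read_id)
            current_id = rec.read_id
            buffer = []
        buffer.append(rec)
    if buffer:
        yield ReadAlignments(current_id, buffer)  # type: ignore[arg-type]


def filter_significant(
    ra: ReadAlignments,
    min_score: float = 50.0,
    max_expected: float = 0.01,
    top_percent: float = 10.0,
    min_pid: float = 0.0,
) -> ReadAlignments | None:
    """Significance gate applied to one read's alignments.

    Keeps records passing the absolute filters (bitscore >= *min_score*,
    evalue <= *max_expected*, identity >= *min_pid*) and then, relative
    to the best surviving score, bitscore >= (1 - top_percent/100) x best.
    Returns ``None`` when nothing survives.  Idempotent.
    """
    if not 0 <= top_percent <= 100:
        raise ValueError("top_percent must be within [0, 100]")
    surviving = [
        r
        for r in ra.records
        if r.bitscore >= min_score
        and r.evalue <= max_expected
        and r.percent_identity >= min_pid
    ]
    if not surviving:
        return None
    cutoff = (1.0 - top_percent / 100.0) * surviving[0].bitscore
    kept = [r for r in surviving if r.bitscore >= cutoff or math.isclose(r.bitscore, cutoff)]
    return ReadAlignments(ra.read_id, kept)
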