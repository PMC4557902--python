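"""Peak-to-gene annotation: BED intervals against transcript coordinates.

A peak is assigned to a gene when it overlaps (by at least one base,
half-open semantics) the transcript span extended on the transcript's 5'
side by a promoter window (default 5 kb): before ``txStart`` on the ``+``
strand, after ``txEnd`` on ``-``.  A peak may hit several genes; all are
kept.  All coordinates are 0-based half-open, BED native.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class TranscriptRecord:
    gene: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"transcript for {self.gene} needs a +/- strand")


@dataclass
class PeakSet:
    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)


def _open(source: str | IO[str]) -> tuple[IO[str], bool]:
    if isinstance(source, str):
        return open(source), True
    return source, False


def read_bed(source: str | IO[str], label: str = "peaks") -> PeakSet:
    """Read BED3+ into a :class:`PeakSet`.

    ``track``/``browser``/``#`` lines are skipped.  Column 4 becomes the
    interval name and column 6 the strand when present.
    """
    handle, close = _open(source)
    intervals = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(
                    f"BED line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or end <= start:
                raise ValueError(
                    f"BED line {lineno}: invalid interval [{start}, {end})"
                )
            name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else None
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            intervals.append(
                GenomicInterval(cols[0], start, end, strand=strand, name=name)
            )
    finally:
        if close:
            handle.close()
    return PeakSet(label=label, intervals=intervals)


def write_bed(peaks: PeakSet, handle: IO[str]) -> None:
    for iv in peaks.intervals:
        name = iv.name if iv.name is not None else "."
        handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


TRANSCRIPT_COLUMNS = ("gene", "chrom", "txStart", "txEnd", "strand")


def read_transcript_table(source: str | IO[str]) -> list[TranscriptRecord]:
    """Read a refFlat-like TSV of transcript coordinates.

    Requires a header naming at least ``gene, chrom, txStart, txEnd, strand``
    (any order; extra columns ignored).  ``txStart`` is 0-based inclusive,
    ``txEnd`` exclusive — the same convention as BED, so peak/transcript
    overlap needs no coordinate shift.  Duplicate rows are deduplicated.
    """
    handle, close = _open(source)
    try:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {}
        for col in TRANSCRIPT_COLUMNS:
            if col not in header:
                raise ValueError(f"transcript table missing column {col!r}")
            idx[col] = header.index(col)
        seen: set[tuple] = set()
        records = []
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            key = (
                cols[idx["gene"]],
                cols[idx["chrom"]],
                int(cols[idx["txStart"]]),
                int(cols[idx["txEnd"]]),
                cols[idx["strand"]],
            )
            if key in seen:
                continue
            seen.add(key)
            records.append(
                TranscriptRecord(
                    gene=key[0],
                    interval=GenomicInterval(key[1], key[2], key[3], strand=key[4]),
                )
            )
    finally:
        if close:
            handle.close()
    return records


def read_gene_list(source: str | IO[str] | Iterable[str]) -> list[str]:
    """Read one gene identifier per line; order kept, duplicates dropped."""
    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    genes: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    try:
        for line in source:
            gene = line.strip()
            if not gene or gene.startswith("#"):
                continue
            if gene in seen:
                n_dup += 1
                continue
            seen.add(gene)
            genes.append(gene)
    finally:
        if close:
            source.close()
    if n_dup:
        logger.info("dropped %d duplicate gene ids", n_dup)
    if not genes:
        raise ValueError("gene list is empty")
    return genes


def _promoter_extended(t: TranscriptRecord, upstream: int) -> tuple[int, int]:
    iv = t.interval
    if iv.strand == "+":
        return max(0, iv.start - upstream), iv.end
    return iv.start, iv.end + upstream


def assign_genes(
    peaks: PeakSet,
    transcripts: Sequence[TranscriptRecord],
    upstream: int = 5000,
    strip_chr: bool = False,
) -> tuple[list[str], int]:
    """Assign peaks to genes by overlap with promoter-extended transcripts.

    Returns the ordered, deduplicated gene list (order of first assignment,
    scanning peaks in input order) and the count of peaks that hit no gene.
    Chromosome names match as exact strings unless ``strip_chr`` removes a
    leading ``chr`` from both sides first.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    if upstream < 0:
        raise ValueError("upstream must be >= 0")

    def norm(chrom: str) -> str:
        return chrom.removeprefix("chr") if strip_chr else chrom

    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        lo, hi = _promoter_extended(t, upstream)
        if hi <= lo:
            continue
        trees.setdefault(norm(t.interval.chrom), IntervalTree()).addi(lo, hi, t.gene)

    genes: list[str] = []
    seen: set[str] = set()
    unassigned = 0
    for peak in peaks.intervals:
        tree = trees.get(norm(peak.chrom))
        hits = tree.overlap(peak.start, peak.end) if tree is not None else ()
        if not hits:
            unassigned += 1
            continue
        # deterministic order within one peak
        for gene in sorted({h.data for h in hits}):
            if gene not in seen:
                seen.add(gene)
                genes.append(gene)
    return genes, unassigned
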