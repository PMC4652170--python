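"""Genomic interval primitives, standard-format I/O and the overlap engine.

Everything downstream works in 0-based half-open coordinates (BED
convention).  GTF input is converted on read; BED round-trips bit-exactly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_NONE = "."

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome.

    ``start`` is 0-based inclusive, ``end`` exclusive.  ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded); ``score`` is optional.
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in (STRAND_PLUS, STRAND_MINUS, STRAND_NONE):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site, 0-based, strand-required."""

    transcript_id: str
    gene_id: str
    chrom: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("TSS position must be >= 0")
        if self.strand not in (STRAND_PLUS, STRAND_MINUS):
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class PromoterRegion:
    """A TSS and its strand-aware promoter window.

    The window spans ``upstream`` bp 5' of the TSS and ``downstream`` bp 3'
    of it in transcript orientation, mirrored for the minus strand.
    """

    tss: TssRecord
    interval: GenomicInterval
    upstream: int = 1000
    downstream: int = 2000

    @property
    def promoter_id(self) -> str:
        return self.tss.transcript_id

    @property
    def gene_id(self) -> str:
        return self.tss.gene_id


def promoter_window(
    tss: TssRecord, upstream: int = 1000, downstream: int = 2000
) -> PromoterRegion:
    """Build the promoter window around a TSS.

    Plus strand: ``[position - upstream, position + downstream)``.  Minus
    strand mirrors the relative offsets: ``[position - downstream + 1,
    position + upstream + 1)``.  The start is clamped at 0 near the
    chromosome edge.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    if tss.strand == STRAND_PLUS:
        start, end = tss.position - upstream, tss.position + downstream
    else:
        start, end = tss.position - downstream + 1, tss.position + upstream + 1
    start = max(0, start)
    return PromoterRegion(
        tss=tss,
        interval=GenomicInterval(tss.chrom, start, end, strand=tss.strand),
        upstream=upstream,
        downstream=downstream,
    )


def promoter_windows(
    tss_records: Iterable[TssRecord], upstream: int = 1000, downstream: int = 2000
) -> list[PromoterRegion]:
    return [promoter_window(t, upstream, downstream) for t in tss_records]


class PeakSet:
    """A sorted, per-chromosome-indexed collection of intervals.

    This is the overlap engine used by every downstream module.  Queries are
    O(log n) for the any-overlap flag and near-output-sensitive for listing,
    using a sorted-starts index with a running maximum of interval ends.
    Peaks are never merged; duplicates are retained.
    """

    def __init__(
        self, sample_id: str, mark: str, intervals: Iterable[GenomicInterval]
    ) -> None:
        if not sample_id or not mark:
            raise ValueError("sample_id and mark must be non-empty")
        self.sample_id = sample_id
        self.mark = mark
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )
        self.n_rejected = 0  # populated by read_bed
        self._index: dict[str, tuple] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def _build_index(self) -> dict[str, tuple]:
        index: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            index.setdefault(iv.chrom, []).append(iv)
        built = {}
        for chrom, ivs in index.items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            built[chrom] = (
                ivs,
                starts,
                ends,
                np.maximum.accumulate(ends),
                int((ends - starts).max()),
            )
        return built

    @property
    def index(self) -> dict[str, tuple]:
        if self._index is None:
            self._index = self._build_index()
        return self._index

    def overlaps_any(self, region: GenomicInterval) -> bool:
        """True iff any peak shares >= 1 bp with ``region`` (strand ignored)."""
        entry = self.index.get(region.chrom)
        if entry is None:
            return False
        _, starts, _, cummax_ends, _ = entry
        hi = int(np.searchsorted(starts, region.end, side="left"))
        return hi > 0 and int(cummax_ends[hi - 1]) > region.start

    def overlapping(self, region: GenomicInterval) -> list[GenomicInterval]:
        """All peaks sharing >= 1 bp with ``region``, in start order."""
        entry = self.index.get(region.chrom)
        if entry is None:
            return []
        ivs, starts, ends, _, max_len = entry
        lo = int(np.searchsorted(starts, region.start - max_len, side="left"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        return [ivs[i] for i in range(lo, hi) if ends[i] > region.start]


def overlaps_any(region: GenomicInterval, peaks: PeakSet) -> bool:
    """Functional form of :meth:`PeakSet.overlaps_any`."""
    return peaks.overlaps_any(region)


def _as_lines(source) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, line) from a path, stream or iterable."""
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            yield from enumerate(handle, start=1)
    else:
        yield from enumerate(source, start=1)


def read_tss_annotation(source) -> list[TssRecord]:
    """Parse transcript features of a GENCODE-style GTF into TSS records.

    The TSS is the feature start for + strand transcripts and the feature
    end for - strand transcripts, converted from 1-based GTF coordinates to
    the internal 0-based convention.  Non-transcript features are skipped.

    Raises ``ValueError`` naming the offending line for malformed lines or
    transcript features lacking a ``transcript_id`` attribute.
    """
    records: list[TssRecord] = []
    for lineno, raw in _as_lines(source):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(
                f"GTF parse error at line {lineno}: expected 9 tab-separated "
                f"fields, got {len(fields)}"
            )
        if fields[2] != "transcript":
            continue
        try:
            start_1b, end_1b = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise ValueError(f"GTF parse error at line {lineno}: {exc}") from exc
        strand = fields[6]
        if strand not in (STRAND_PLUS, STRAND_MINUS):
            raise ValueError(
                f"GTF parse error at line {lineno}: bad strand {strand!r}"
            )
        attrs = dict(_ATTR_RE.findall(fields[8]))
        if "transcript_id" not in attrs:
            raise ValueError(
                f"GTF record error at line {lineno}: transcript feature "
                "missing transcript_id"
            )
        position = start_1b - 1 if strand == STRAND_PLUS else end_1b - 1
        records.append(
            TssRecord(
                transcript_id=attrs["transcript_id"],
                gene_id=attrs.get("gene_id", attrs["transcript_id"]),
                chrom=fields[0],
                position=position,
                strand=strand,
            )
        )
    return records


def read_bed(source, sample_id: str, mark: str) -> PeakSet:
    """Read a BED3/BED5 file into a :class:`PeakSet`.

    Coordinates are stored exactly as in the file (0-based half-open).  An
    optional 5th column is parsed as the score.  Records with start >= end
    are rejected with a warning and counted in ``PeakSet.n_rejected``.
    """
    intervals: list[GenomicInterval] = []
    n_rejected = 0
    for lineno, raw in _as_lines(source):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"BED parse error at line {lineno}: expected >= 3 columns"
            )
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            warnings.warn(
                f"BED line {lineno}: rejected record with start >= end "
                f"({chrom}:{start}-{end})",
                stacklevel=2,
            )
            n_rejected += 1
            continue
        score = None
        if len(fields) >= 5 and fields[4] not in ("", "."):
            score = float(fields[4])
        strand = STRAND_NONE
        if len(fields) >= 6 and fields[5] in (STRAND_PLUS, STRAND_MINUS):
            strand = fields[5]
        intervals.append(GenomicInterval(chrom, start, end, strand, score))
    peaks = PeakSet(sample_id, mark, intervals)
    peaks.n_rejected = n_rejected
    return peaks


def write_bed(peaks: PeakSet | Iterable[GenomicInterval], dest) -> None:
    """Write intervals as BED (BED5 when any score is present, else BED3)."""
    intervals = list(peaks)
    has_score = any(iv.score is not None for iv in intervals)
    lines = []
    for iv in intervals:
        if has_score:
            score = "." if iv.score is None else format(iv.score, "g")
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score}")
        else:
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


class BedGraph:
    """Sparse per-chromosome coverage from a bedGraph file.

    Intervals are assumed sorted and non-overlapping per chromosome, as the
    format requires; uncovered bases have value 0.
    """

    def __init__(
        self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    ) -> None:
        self._data = dict(data)

    @classmethod
    def read(cls, source) -> "BedGraph":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for lineno, raw in _as_lines(source):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"bedGraph parse error at line {lineno}: expected 4 columns"
                )
            per_chrom.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), float(fields[3]))
            )
        data = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            data[chrom] = (starts, ends, values)
        return cls(data)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Coverage averaged over [start, end); missing bases count as 0."""
        if end <= start:
            raise ValueError("end must exceed start")
        entry = self._data.get(chrom)
        if entry is None:
            return 0.0
        starts, ends, values = entry
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        total = 0.0
        for i in range(lo, hi):
            overlap = min(int(ends[i]), end) - max(int(starts[i]), start)
            if overlap > 0:
                total += overlap * float(values[i])
        return total / (end - start)


class Genome:
    """Random-access genome sequence, from an indexed FASTA or in-memory dict.

    ``fetch`` pads with ``N`` beyond chromosome ends so window extraction
    never fails at edges.
    """

    def __init__(self, seqs: Mapping[str, object]) -> None:
        self._seqs = seqs

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        import pyfaidx

        return cls(pyfaidx.Fasta(str(path)))

    @classmethod
    def from_dict(cls, seqs: Mapping[str, str]) -> "Genome":
        return cls(dict(seqs))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> list[str]:
        return list(self._seqs.keys())

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Uppercase sequence of [start, end), N-padded outside the chromosome."""
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        length = self.chrom_length(chrom)
        lo, hi = max(0, start), min(length, end)
        core = str(self._seqs[chrom][lo:hi]) if hi > lo else ""
        return ("N" * (lo - start) + core + "N" * (end - hi)).upper()


def write_fasta(seqs: Mapping[str, str], dest, width: int = 60) -> None:
    lines = []
    for name, seq in seqs.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    text = "\n".join(lines) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
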