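"""Fragment-level ATAC data: BED I/O, Tn5 offset correction, size classes, coverage.

Coordinates are 0-based half-open throughout (BED convention). A fragment
records the span between its two Tn5 insertion events; applying the insertion
offset correction moves the left end +4 bp and the right end -5 bp.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "FragmentRecord",
    "CoverageTrack",
    "SizeClass",
    "NFR",
    "NUCLEOSOMAL",
    "DEFAULT_SIZE_THRESHOLD",
    "BedFormatError",
    "DegenerateFragmentError",
    "read_fragment_bed",
    "write_fragment_bed",
    "tn5_shift",
    "tn5_shift_all",
    "classify_size",
    "coverage",
    "write_bedgraph",
    "read_bedgraph",
]

NFR = "NFR"
NUCLEOSOMAL = "NUCLEOSOMAL"

#: Fragments strictly longer than this are mono-nucleosomal.
DEFAULT_SIZE_THRESHOLD = 150

#: Left insertion-site shift (+) and right insertion-site shift (-).
TN5_LEFT_OFFSET = 4
TN5_RIGHT_OFFSET = 5


class BedFormatError(ValueError):
    """Malformed BED line (too few fields, bad coordinates, start >= end)."""


class DegenerateFragmentError(ValueError):
    """Fragment too short to survive the Tn5 offset correction."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shift(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced ATAC fragment (span between two Tn5 insertions)."""

    interval: GenomicInterval
    sample_id: str = ""
    replicate_id: str = ""

    @property
    def length(self) -> int:
        return self.interval.width

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class SizeClass:
    label: str
    threshold: int = DEFAULT_SIZE_THRESHOLD

    def __post_init__(self) -> None:
        if self.label not in (NFR, NUCLEOSOMAL):
            raise ValueError(f"unknown size class {self.label!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass
class CoverageTrack:
    """Per-bp integer coverage over ``[origin, origin + len(values))``."""

    chrom: str
    origin: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    @property
    def end(self) -> int:
        return self.origin + self.values.size


def _open_text(path, mode: str = "rt"):
    """gzip-transparent text open."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragment_bed(
    path,
    sample_id: str = "",
    replicate_id: str = "",
    *,
    permissive: bool = False,
) -> list[FragmentRecord]:
    """Read a BED3+ fragment file.

    Parameters
    ----------
    path
        Tab-separated file with at least chrom/start/end columns; may be
        gzip-compressed. No header.
    permissive
        If True, malformed lines are skipped (and counted on the returned
        list as ``.n_skipped``) instead of raising :class:`BedFormatError`.
    """
    records: list[FragmentRecord] = []
    n_skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 3:
                    raise BedFormatError(
                        f"line {lineno}: expected >= 3 tab-separated fields"
                    )
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                if start >= end:
                    raise BedFormatError(
                        f"line {lineno}: start ({start}) >= end ({end})"
                    )
                interval = GenomicInterval(chrom, start, end)
            except (ValueError, BedFormatError) as exc:
                if permissive:
                    n_skipped += 1
                    continue
                if isinstance(exc, BedFormatError):
                    raise
                raise BedFormatError(f"line {lineno}: {exc}") from exc
            records.append(FragmentRecord(interval, sample_id, replicate_id))
    out = _FragmentList(records)
    out.n_skipped = n_skipped
    return out


class _FragmentList(list):
    """List of fragments carrying a skipped-line counter."""

    n_skipped: int = 0


def write_fragment_bed(fragments: Iterable[FragmentRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for frag in fragments:
            iv = frag.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def tn5_shift(fragment: FragmentRecord) -> FragmentRecord:
    """Apply the Tn5 insertion-center correction: left +4 bp, right -5 bp.

    Raises
    ------
    DegenerateFragmentError
        If the fragment is <= 9 bp and the shift would invert it.
    """
    iv = fragment.interval
    if iv.width <= TN5_LEFT_OFFSET + TN5_RIGHT_OFFSET:
        raise DegenerateFragmentError(
            f"fragment {iv.chrom}:{iv.start}-{iv.end} is {iv.width} bp; "
            f"Tn5 shift requires > {TN5_LEFT_OFFSET + TN5_RIGHT_OFFSET} bp"
        )
    shifted = replace(iv, start=iv.start + TN5_LEFT_OFFSET, end=iv.end - TN5_RIGHT_OFFSET)
    return replace(fragment, interval=shifted)


def tn5_shift_all(
    fragments: Iterable[FragmentRecord],
) -> tuple[list[FragmentRecord], int]:
    """Shift every fragment; degenerate ones are dropped and counted."""
    out: list[FragmentRecord] = []
    n_dropped = 0
    for frag in fragments:
        try:
            out.append(tn5_shift(frag))
        except DegenerateFragmentError:
            n_dropped += 1
    return out, n_dropped


def classify_size(
    fragment: FragmentRecord, threshold: int = DEFAULT_SIZE_THRESHOLD
) -> str:
    """NFR if length <= threshold, NUCLEOSOMAL if strictly greater."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return NUCLEOSOMAL if fragment.length > threshold else NFR


def coverage(
    fragments: Iterable[FragmentRecord],
    chrom: str,
    window: GenomicInterval,
) -> CoverageTrack:
    """Per-bp fragment coverage over ``window`` on ``chrom``.

    ``values[i]`` counts the fragments overlapping position
    ``window.start + i``. Fragments on other chromosomes are ignored.
    """
    n = window.width
    # difference array: +1 at clipped start, -1 at clipped end
    diff = np.zeros(n + 1, dtype=np.int64)
    for frag in fragments:
        iv = frag.interval
        if iv.chrom != chrom:
            continue
        lo = max(iv.start, window.start) - window.start
        hi = min(iv.end, window.end) - window.start
        if lo < hi:
            diff[lo] += 1
            diff[hi] -= 1
    return CoverageTrack(chrom, window.start, np.cumsum(diff[:n]))


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a 4-column bedGraph, run-length merging equal values.

    Zero-valued runs are omitted; readers treat absent positions as zero.
    """
    values = np.asarray(track.values)
    with _open_text(path, "wt") as fh:
        _write_bedgraph_lines(fh, track.chrom, track.origin, values)


def _write_bedgraph_lines(fh, chrom: str, origin: int, values: np.ndarray) -> None:
    if values.size == 0:
        return
    # boundaries of equal-value runs
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [values.size]))
    for s, e in zip(starts, ends):
        v = values[s]
        if v == 0:
            continue
        val = int(v) if float(v).is_integer() else float(v)
        fh.write(f"{chrom}\t{origin + s}\t{origin + e}\t{val}\n")


def read_bedgraph(path, window: GenomicInterval) -> CoverageTrack:
    """Read per-bp values over ``window``; absent positions are zero."""
    values = np.zeros(window.width, dtype=np.float64)
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            if chrom != window.chrom:
                continue
            lo = max(int(start), window.start) - window.start
            hi = min(int(end), window.end) - window.start
            if lo < hi:
                values[lo:hi] = float(value)
    if np.all(values == np.floor(values)):
        values = values.astype(np.int64)
    return CoverageTrack(window.chrom, window.start, values)
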