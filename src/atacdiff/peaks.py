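"""Coverage-slicing peak caller, interval union, conservation filter, consensus scanner."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .fragments import CoverageTrack, GenomicInterval, _open_text

__all__ = [
    "Peak",
    "MotifSite",
    "ConservationRecord",
    "MissingAnnotationError",
    "PatternError",
    "call_peaks",
    "union_intervals",
    "filter_conserved",
    "scan_consensus",
    "motif_centric_windows",
    "write_peaks_bed",
    "read_intervals_bed",
    "read_conservation_table",
    "reverse_complement",
]


class MissingAnnotationError(KeyError):
    """An interval lacks a required annotation record."""


class PatternError(ValueError):
    """Invalid degenerate consensus pattern."""


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    summit: int
    max_coverage: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie inside the peak interval")


@dataclass(frozen=True)
class MotifSite:
    interval: GenomicInterval
    motif_name: str
    matched_sequence: str
    strand: str

    def __post_init__(self) -> None:
        if self.interval.width != len(self.matched_sequence):
            raise ValueError("interval width must equal matched sequence length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class ConservationRecord:
    interval: GenomicInterval
    mean_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_score <= 1.0:
            raise ValueError("mean_score must be in [0, 1]")


def call_peaks(
    track: CoverageTrack,
    min_coverage: int = 10,
    width: int = 500,
    sample_id: str = "",
) -> list[Peak]:
    """Slice a coverage track into fixed-width summit-centered peaks.

    Maximal runs of positions with coverage >= ``min_coverage`` become raw
    regions; the summit is each region's leftmost coverage maximum; each peak
    is the ``width``-bp interval centered at the summit, clipped at 0.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if width < 1:
        raise ValueError("width must be >= 1")
    values = np.asarray(track.values)
    above = values >= min_coverage
    if not above.any():
        return []
    # run boundaries of the boolean mask
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    peaks: list[Peak] = []
    half = width // 2
    for s, e in zip(starts, ends):
        run = values[s:e]
        summit = track.origin + s + int(np.argmax(run))  # leftmost max
        lo = max(summit - half, 0)  # clipped at chromosome start
        hi = summit + (width - half)
        interval = GenomicInterval(track.chrom, lo, hi)
        peaks.append(
            Peak(interval, summit, int(run.max()), sample_id)
        )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def union_intervals(
    peak_sets: Sequence[Sequence[Peak | GenomicInterval]],
) -> list[GenomicInterval]:
    """Merge all peak intervals across samples into maximal disjoint intervals.

    Bookended intervals (end == next start) are merged too.
    """
    intervals: list[GenomicInterval] = []
    for peak_set in peak_sets:
        for p in peak_set:
            intervals.append(p.interval if isinstance(p, Peak) else p)
    if not intervals:
        return []
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur = intervals[0]
    for iv in intervals[1:]:
        if iv.chrom == cur.chrom and iv.start <= cur.end:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
        else:
            merged.append(cur)
            cur = iv
    merged.append(cur)
    return [GenomicInterval(iv.chrom, iv.start, iv.end) for iv in merged]


def filter_conserved(
    intervals: Sequence[GenomicInterval],
    scores: Sequence[ConservationRecord],
    min_score: float = 0.8,
) -> list[GenomicInterval]:
    """Keep intervals whose mean conservation score is strictly > ``min_score``."""
    lookup = {
        (r.interval.chrom, r.interval.start, r.interval.end): r.mean_score
        for r in scores
    }
    kept: list[GenomicInterval] = []
    for iv in intervals:
        key = (iv.chrom, iv.start, iv.end)
        if key not in lookup:
            raise MissingAnnotationError(
                f"no conservation score for {iv.chrom}:{iv.start}-{iv.end}"
            )
        if lookup[key] > min_score:
            kept.append(iv)
    return kept


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC degeneracy codes accepted alongside (A/C/G)-style alternatives
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _parse_consensus(pattern: str) -> list[frozenset[str]]:
    """Parse ``(A/C/G)AGGAA(G/A)T``-style or IUPAC patterns into per-position sets."""
    positions: list[frozenset[str]] = []
    i = 0
    pattern = pattern.strip()
    while i < len(pattern):
        ch = pattern[i]
        if ch == "(":
            j = pattern.find(")", i)
            if j < 0:
                raise PatternError(f"unclosed '(' at position {i}")
            alts = pattern[i + 1 : j].upper().split("/")
            bases = set()
            for alt in alts:
                if len(alt) != 1 or alt not in "ACGT":
                    raise PatternError(f"invalid alternative {alt!r}")
                bases.add(alt)
            positions.append(frozenset(bases))
            i = j + 1
        else:
            up = ch.upper()
            if up not in _IUPAC:
                raise PatternError(f"invalid pattern character {ch!r}")
            positions.append(frozenset(_IUPAC[up]))
            i += 1
    if not positions:
        raise PatternError("empty pattern")
    return positions


def _complement_positions(positions: list[frozenset[str]]) -> list[frozenset[str]]:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return [frozenset(comp[b] for b in pos) for pos in reversed(positions)]


def scan_consensus(
    sequence: str,
    consensus: str,
    offset: int = 0,
    chrom: str = "seq",
    motif_name: str | None = None,
) -> list[MotifSite]:
    """Scan both strands for matches to a degenerate consensus.

    Minus-strand matches are found via the reverse-complement pattern;
    coordinates are always reported on the forward strand. ``N`` in the
    sequence never matches. ``offset`` is added to all coordinates.
    """
    fwd = _parse_consensus(consensus)
    rev = _complement_positions(fwd)
    name = motif_name if motif_name is not None else consensus
    seq = sequence.upper()
    m = len(fwd)
    sites: list[MotifSite] = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        for strand, positions in (("+", fwd), ("-", rev)):
            if all(base in pos for base, pos in zip(window, positions)):
                sites.append(
                    MotifSite(
                        GenomicInterval(chrom, offset + i, offset + i + m),
                        name,
                        window,
                        strand,
                    )
                )
    return sites


def motif_centric_windows(
    sites: Sequence[MotifSite], width: int = 640
) -> list[GenomicInterval]:
    """Fixed-width windows centered at each motif midpoint.

    Windows that would extend below 0 are clipped at 0 (and thus narrower).
    """
    if width % 2 != 0:
        raise ValueError("width must be even")
    half = width // 2
    windows: list[GenomicInterval] = []
    for site in sites:
        mid = site.interval.midpoint
        lo = max(mid - half, 0)
        windows.append(GenomicInterval(site.interval.chrom, lo, mid + half))
    return windows


def write_peaks_bed(peaks: Iterable[Peak], path) -> None:
    with _open_text(path, "wt") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            name = f"peak_{i + 1}" if not p.sample_id else f"{p.sample_id}_peak_{i + 1}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{p.max_coverage}\t.\n"
            )


def read_intervals_bed(path) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return intervals


def read_conservation_table(path) -> list[ConservationRecord]:
    """Tab-delimited (chrom, start, end, mean_score) table."""
    records: list[ConservationRecord] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, score = line.split("\t")[:4]
            records.append(
                ConservationRecord(
                    GenomicInterval(chrom, int(start), int(end)), float(score)
                )
            )
    return records
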