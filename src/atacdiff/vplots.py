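"""V-plot construction and aggregation, size-partitioned tracks, occupancy proxy.

A V-plot is a 2-D histogram of fragment midpoint position (columns) versus
fragment length (rows) around a fixed-width genomic window. Fragments are
assigned by midpoint; the size range is half-open [size_min, size_max).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .fragments import (
    DEFAULT_SIZE_THRESHOLD,
    NFR,
    NUCLEOSOMAL,
    CoverageTrack,
    FragmentRecord,
    GenomicInterval,
    classify_size,
    coverage,
)

__all__ = [
    "VPlotGrid",
    "VPlot",
    "AggregatedVPlot",
    "GeometryError",
    "EmptyAggregateError",
    "build_vplot",
    "aggregate_vplots",
    "size_partitioned_track",
    "accessibility_ratio_track",
    "occupancy_proxy",
]


class GeometryError(ValueError):
    """Mismatched window/grid geometry."""


class EmptyAggregateError(ValueError):
    """No V-plots (with mass) available to aggregate."""


@dataclass(frozen=True)
class VPlotGrid:
    """Binning geometry of a V-plot.

    Defaults: 640-bp window in 10-bp position bins (64 columns) and fragment
    sizes [50, 370) in 10-bp bins (32 rows).
    """

    window_width: int = 640
    position_bin: int = 10
    size_min: int = 50
    size_max: int = 370
    size_bin: int = 10

    def __post_init__(self) -> None:
        for name in ("window_width", "position_bin", "size_min", "size_max", "size_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_width % self.position_bin != 0:
            raise ValueError("window_width must be divisible by position_bin")
        if (self.size_max - self.size_min) % self.size_bin != 0:
            raise ValueError("(size_max - size_min) must be divisible by size_bin")

    @property
    def n_position_bins(self) -> int:
        return self.window_width // self.position_bin

    @property
    def n_size_bins(self) -> int:
        return (self.size_max - self.size_min) // self.size_bin

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_size_bins, self.n_position_bins)


@dataclass
class VPlot:
    """Position x fragment-size count matrix for one window."""

    region: GenomicInterval
    grid: VPlotGrid
    counts: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.grid.shape:
            raise GeometryError(
                f"counts shape {self.counts.shape} != grid shape {self.grid.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def density(self) -> np.ndarray:
        t = self.total
        if t == 0:
            raise ValueError("zero-total V-plot has no density")
        return self.counts / t


@dataclass
class AggregatedVPlot:
    grid: VPlotGrid
    density: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != self.grid.shape:
            raise GeometryError("density shape mismatch")


def build_vplot(
    fragments: Iterable[FragmentRecord],
    region: GenomicInterval,
    grid: VPlotGrid | None = None,
    sample_id: str = "",
) -> VPlot:
    """Bin fragments into a V-plot count matrix for one window.

    A fragment contributes one count at (size bin of its length, position bin
    of its midpoint) iff its midpoint lies inside ``region`` and its length is
    within [size_min, size_max). Total mass equals the number of qualifying
    fragments.
    """
    grid = grid or VPlotGrid()
    if region.width != grid.window_width:
        raise GeometryError(
            f"region width {region.width} != grid window_width {grid.window_width}"
        )
    counts = np.zeros(grid.shape, dtype=np.int64)
    for frag in fragments:
        if frag.chrom != region.chrom:
            continue
        mid = frag.midpoint
        if not (region.start <= mid < region.end):
            continue
        length = frag.length
        if not (grid.size_min <= length < grid.size_max):
            continue
        row = (length - grid.size_min) // grid.size_bin
        col = (mid - region.start) // grid.position_bin
        counts[row, col] += 1
    return VPlot(region, grid, counts, sample_id)


def aggregate_vplots(vplots: Sequence[VPlot]) -> AggregatedVPlot:
    """Average per-region densities and renormalize to sum 1.

    Zero-total V-plots are skipped (they carry no density information);
    ``n_regions`` counts only contributing V-plots.
    """
    if not vplots:
        raise EmptyAggregateError("no V-plots to aggregate")
    grid = vplots[0].grid
    acc = np.zeros(grid.shape, dtype=float)
    n = 0
    for vp in vplots:
        if vp.grid != grid:
            raise GeometryError("all V-plots must share one grid")
        if vp.total == 0:
            continue
        acc += vp.density()
        n += 1
    if n == 0:
        raise EmptyAggregateError("all V-plots have zero total")
    acc /= acc.sum()
    return AggregatedVPlot(grid, acc, n)


def size_partitioned_track(
    fragments: Iterable[FragmentRecord],
    window: GenomicInterval,
    keep: str,
    threshold: int = DEFAULT_SIZE_THRESHOLD,
) -> CoverageTrack:
    """Coverage over only the fragments of one size class."""
    if keep not in (NFR, NUCLEOSOMAL):
        raise ValueError(f"unknown size class {keep!r}")
    kept = [f for f in fragments if classify_size(f, threshold) == keep]
    return coverage(kept, window.chrom, window)


def accessibility_ratio_track(
    numerator: CoverageTrack,
    denominator: CoverageTrack,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Per-bp signal ratio after within-window depth normalization.

    Each track is scaled to equal total mass (the mean of the two totals)
    before the pseudocounted ratio is taken.
    """
    if (
        numerator.chrom != denominator.chrom
        or numerator.origin != denominator.origin
        or numerator.values.size != denominator.values.size
    ):
        raise GeometryError("tracks must cover the same window")
    num = np.asarray(numerator.values, dtype=float)
    den = np.asarray(denominator.values, dtype=float)
    target = (num.sum() + den.sum()) / 2.0
    if num.sum() > 0:
        num = num * (target / num.sum())
    if den.sum() > 0:
        den = den * (target / den.sum())
    return (num + pseudocount) / (den + pseudocount)


def occupancy_proxy(
    fragments: Iterable[FragmentRecord],
    window: GenomicInterval,
    threshold: int = DEFAULT_SIZE_THRESHOLD,
    kernel_sd: float = 20.0,
) -> np.ndarray:
    """Nucleosome-occupancy stand-in: Gaussian-smoothed mono-nucleosomal
    fragment midpoint density.

    The track sums to the number of in-window nucleosomal midpoints when the
    kernel support fits inside the window.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be > 0")
    mids = [
        f.midpoint
        for f in fragments
        if f.chrom == window.chrom
        and classify_size(f, threshold) == NUCLEOSOMAL
        and window.start <= f.midpoint < window.end
    ]
    track = np.zeros(window.width, dtype=float)
    if not mids:
        return track
    positions = np.arange(window.start, window.end, dtype=float)
    mids_arr = np.asarray(mids, dtype=float)
    # sum of unit-mass Gaussian kernels over per-bp sample points
    z = (positions[:, None] - mids_arr[None, :]) / kernel_sd
    track = np.exp(-0.5 * z**2).sum(axis=1) / (kernel_sd * np.sqrt(2 * np.pi))
    return track
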