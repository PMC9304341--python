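"""Four-way open/closed classification of motif-centric regions across two
reference samples, plus per-group annotation-enrichment proportions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .fragments import GenomicInterval
from .peaks import Peak

__all__ = [
    "AccessibilityGroup",
    "GroupEnrichment",
    "GROUP_CODES",
    "assign_groups",
    "group_enrichment",
    "write_groups_bed",
]

GROUP_CODES = ("00", "01", "10", "11")


@dataclass(frozen=True)
class AccessibilityGroup:
    region: GenomicInterval
    code: str  # first digit: open in sample A; second: open in sample B

    def __post_init__(self) -> None:
        if self.code not in GROUP_CODES:
            raise ValueError(f"invalid group code {self.code!r}")


@dataclass(frozen=True)
class GroupEnrichment:
    code: str
    n_regions: int
    n_annotated: int

    @property
    def proportion(self) -> float | None:
        """Fraction of group regions overlapping an annotation; None if empty group."""
        if self.n_regions == 0:
            return None
        return self.n_annotated / self.n_regions


def _central_window(region: GenomicInterval, center_width: int) -> GenomicInterval:
    mid = region.midpoint
    lo = max(mid - center_width // 2, 0)
    return GenomicInterval(region.chrom, lo, mid + (center_width - center_width // 2))


def _overlaps_any(window: GenomicInterval, intervals: Sequence[GenomicInterval]) -> bool:
    return any(window.overlaps(iv) for iv in intervals)


def assign_groups(
    regions: Sequence[GenomicInterval],
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    center_width: int = 200,
) -> list[AccessibilityGroup]:
    """Classify each region as open/closed in two reference samples.

    A region is open in a sample iff its central ``center_width`` window
    overlaps (>= 1 bp) any called peak of that sample. Codes concatenate the
    sample-A then sample-B state ('1' = open).
    """
    ivs_a = [p.interval for p in peaks_a]
    ivs_b = [p.interval for p in peaks_b]
    groups: list[AccessibilityGroup] = []
    for region in regions:
        if center_width > region.width:
            raise ValueError(
                f"center_width {center_width} exceeds region width {region.width}"
            )
        window = _central_window(region, center_width)
        a = "1" if _overlaps_any(window, ivs_a) else "0"
        b = "1" if _overlaps_any(window, ivs_b) else "0"
        groups.append(AccessibilityGroup(region, a + b))
    return groups


def group_enrichment(
    groups: Sequence[AccessibilityGroup],
    annotation: Sequence[GenomicInterval],
) -> list[GroupEnrichment]:
    """Per-code counts and proportions of regions overlapping an annotation."""
    out: list[GroupEnrichment] = []
    for code in GROUP_CODES:
        members = [g.region for g in groups if g.code == code]
        n_ann = sum(1 for r in members if _overlaps_any(r, annotation))
        out.append(GroupEnrichment(code, len(members), n_ann))
    return out


def write_groups_bed(groups: Sequence[AccessibilityGroup], path) -> None:
    with open(path, "w") as fh:
        for g in groups:
            iv = g.region
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.code}\n")
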