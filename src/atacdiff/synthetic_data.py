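"""Seeded synthetic ATAC fragment generator with known ground truth.

Each synthetic region is a 640-bp window holding a central nucleosome dyad
under the motif and an NFR occupying the same central stretch: a fragment is
either sub-nucleosomal (midpoint uniform in the NFR) with probability pi, or
mono-nucleosomal (midpoint near a dyad). Displaced regions of condition B
raise pi, moving mass from central nucleosomal to central sub-nucleosomal
fragments. Per-sample length shifts emulate batch-specific fragment-size
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments import FragmentRecord, GenomicInterval, write_fragment_bed
from .peaks import scan_consensus

__all__ = [
    "RegionSpec",
    "GeneratorConfig",
    "SyntheticDataset",
    "generate",
    "generate_grouping_fixture",
    "generate_motif_fasta",
    "CHROM",
    "REGION_WIDTH",
    "REGION_SPACING",
]

CHROM = "chrS"
REGION_WIDTH = 640
REGION_SPACING = 2000


@dataclass(frozen=True)
class RegionSpec:
    interval: GenomicInterval
    dyads: tuple[int, ...]  # offsets from region start
    nfr: tuple[int, int]  # sub-interval offsets from region start
    pi_nfr: float
    displaced: bool
    motif_offset: int

    def __post_init__(self) -> None:
        for d in self.dyads:
            if not 0 <= d < self.interval.width:
                raise ValueError("dyad offsets must lie inside the region")
        if not (0 <= self.nfr[0] < self.nfr[1] <= self.interval.width):
            raise ValueError("NFR must lie inside the region")
        if not 0.0 <= self.pi_nfr <= 1.0:
            raise ValueError("pi_nfr must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    n_regions: int = 200
    n_displaced: int = 40
    fragments_per_region: int = 300
    replicates_per_condition: int = 2
    pi_nfr_base: float = 0.2
    pi_nfr_displaced: float = 0.7
    nfr_len_mean: float = 75.0
    nfr_len_sd: float = 15.0
    nuc_len_mean: float = 200.0
    nuc_len_sd: float = 25.0
    dyad_jitter_sd: float = 10.0
    batch_len_shift: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    # truncation bounds keep the two classes on either side of 150 bp
    NFR_LEN_BOUNDS = (30, 150)
    NUC_LEN_BOUNDS = (151, 330)

    def __post_init__(self) -> None:
        if self.n_displaced > self.n_regions:
            raise ValueError("n_displaced must be <= n_regions")
        for p in (self.pi_nfr_base, self.pi_nfr_displaced):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for sd in (self.nfr_len_sd, self.nuc_len_sd, self.dyad_jitter_sd):
            if sd <= 0:
                raise ValueError("standard deviations must be > 0")
        for shift in self.batch_len_shift.values():
            if self.nfr_len_mean + shift >= self.NFR_LEN_BOUNDS[1] + 4 * self.nfr_len_sd:
                raise ValueError("batch shift pushes NFR lengths past truncation")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_rep{r + 1}"
            for cond in ("A", "B")
            for r in range(self.replicates_per_condition)
        ]


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    regions: list[RegionSpec]
    fragments: dict[str, list[FragmentRecord]]  # sample_id -> fragments

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for spec in self.regions:
            iv = spec.interval
            rows.append(
                {
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "displaced": spec.displaced,
                    "motif_position": iv.start + spec.motif_offset,
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sample_id, frags in self.fragments.items():
            path = outdir / f"{sample_id}.fragments.bed"
            write_fragment_bed(frags, path)
            paths[sample_id] = path
        truth_path = outdir / "truth.tsv"
        self.truth_table().to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        return paths


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds inclusive after rounding)."""
    if lo >= hi:
        raise ValueError(f"impossible truncation bounds [{lo}, {hi}]")
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = rng.normal(mean, sd, size=need.size)
        ok = (draw >= lo) & (draw <= hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def default_regions(config: GeneratorConfig, rng: np.random.Generator) -> list[RegionSpec]:
    """Region layout: evenly spaced windows, central dyad, central NFR."""
    displaced_idx = set(
        rng.choice(config.n_regions, size=config.n_displaced, replace=False).tolist()
    )
    regions = []
    half = REGION_WIDTH // 2
    for i in range(config.n_regions):
        start = 1000 + i * REGION_SPACING
        interval = GenomicInterval(CHROM, start, start + REGION_WIDTH)
        regions.append(
            RegionSpec(
                interval=interval,
                dyads=(half,),
                nfr=(half - 75, half + 75),
                pi_nfr=config.pi_nfr_base,
                displaced=i in displaced_idx,
                motif_offset=half,
            )
        )
    return regions


def _sample_region_fragments(
    rng: np.random.Generator,
    spec: RegionSpec,
    n: int,
    pi: float,
    len_shift: float,
    config: GeneratorConfig,
    sample_id: str,
    replicate_id: str,
) -> list[FragmentRecord]:
    iv = spec.interval
    is_nfr = rng.random(n) < pi
    n_nfr = int(is_nfr.sum())
    n_nuc = n - n_nfr

    lengths = np.empty(n, dtype=int)
    mids = np.empty(n, dtype=int)

    if n_nfr:
        lo, hi = config.NFR_LEN_BOUNDS
        lengths[is_nfr] = np.round(
            _truncated_normal(rng, config.nfr_len_mean + len_shift,
                              config.nfr_len_sd, lo, hi, n_nfr)
        ).astype(int)
        mids[is_nfr] = iv.start + rng.integers(spec.nfr[0], spec.nfr[1], size=n_nfr)
    if n_nuc:
        lo, hi = config.NUC_LEN_BOUNDS
        lengths[~is_nfr] = np.round(
            _truncated_normal(rng, config.nuc_len_mean + len_shift,
                              config.nuc_len_sd, lo, hi, n_nuc)
        ).astype(int)
        # anchor uniform in region, snapped to the nearest dyad, then jittered
        anchors = rng.integers(0, iv.width, size=n_nuc)
        dyads = np.asarray(spec.dyads)
        nearest = dyads[np.argmin(np.abs(anchors[:, None] - dyads[None, :]), axis=1)]
        jitter = rng.normal(0.0, config.dyad_jitter_sd, size=n_nuc)
        mids[~is_nfr] = iv.start + np.clip(
            np.round(nearest + jitter).astype(int), 0, iv.width - 1
        )

    lengths = np.clip(lengths, 20, None)
    starts = np.maximum(mids - lengths // 2, 0)
    ends = starts + lengths
    return [
        FragmentRecord(GenomicInterval(iv.chrom, int(s), int(e)), sample_id, replicate_id)
        for s, e in zip(starts, ends)
    ]


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate per-sample fragments plus a ground-truth region table.

    Condition B samples use ``pi_nfr_displaced`` at displaced regions; all
    other region x sample cells use ``pi_nfr_base``. Per-sample fragment-size
    shifts come from ``config.batch_len_shift`` keyed by sample id.
    """
    rng = np.random.default_rng(config.seed)
    regions = default_regions(config, rng)
    fragments: dict[str, list[FragmentRecord]] = {}
    for sample_id in config.sample_ids:
        condition, replicate = sample_id.split("_")
        shift = float(config.batch_len_shift.get(sample_id, 0.0))
        frags: list[FragmentRecord] = []
        for spec in regions:
            pi = (
                config.pi_nfr_displaced
                if (spec.displaced and condition == "B")
                else config.pi_nfr_base
            )
            frags.extend(
                _sample_region_fragments(
                    rng, spec, config.fragments_per_region, pi, shift,
                    config, sample_id, replicate,
                )
            )
        fragments[sample_id] = frags
    return SyntheticDataset(config, regions, fragments)


def generate_grouping_fixture(
    n_per_code: int,
    seed: int = 0,
    open_depth: int = 20,
    closed_depth: int = 2,
) -> tuple[dict[str, list[FragmentRecord]], list[tuple[GenomicInterval, str]]]:
    """Two-sample fixture whose peak calls recover known group codes exactly.

    Open regions receive ``open_depth`` stacked central fragments (coverage
    >= the default peak-calling threshold); closed regions receive
    ``closed_depth`` (below threshold). Returns ({sample: fragments},
    [(region, code), ...]) with codes cycling 00, 01, 10, 11.
    """
    if n_per_code < 1:
        raise ValueError("n_per_code must be >= 1")
    rng = np.random.default_rng(seed)
    codes = [code for code in ("00", "01", "10", "11") for _ in range(n_per_code)]
    rng.shuffle(codes)
    fragments: dict[str, list[FragmentRecord]] = {"A": [], "B": []}
    truth: list[tuple[GenomicInterval, str]] = []
    for i, code in enumerate(codes):
        start = 1000 + i * REGION_SPACING
        region = GenomicInterval(CHROM, start, start + REGION_WIDTH)
        truth.append((region, code))
        mid = region.midpoint
        for sample, digit in zip(("A", "B"), code):
            depth = open_depth if digit == "1" else closed_depth
            iv = GenomicInterval(CHROM, mid - 50, mid + 50)
            fragments[sample].extend(
                FragmentRecord(iv, sample, "rep1") for _ in range(depth)
            )
    return fragments, truth


def generate_motif_fasta(
    n_sites: int = 5,
    consensus_instance: str = "CAGGAAGT",
    length: int = 2000,
    seed: int = 0,
    scan_pattern: str = "(A/C/G)AGGAA(G/A)T",
) -> tuple[str, list[int]]:
    """Random sequence with planted motif instances at known positions.

    The background is regenerated until it contains no accidental matches to
    ``scan_pattern`` on either strand, so the planted positions are the
    complete ground truth.
    """
    rng = np.random.default_rng(seed)
    m = len(consensus_instance)
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        positions = sorted(
            rng.choice((length - m) // (2 * m), size=n_sites, replace=False) * 2 * m
        )
        chars = list(seq)
        for pos in positions:
            chars[pos : pos + m] = consensus_instance
        planted = "".join(chars)
        hits = scan_consensus(planted, scan_pattern)
        if sorted({h.interval.start for h in hits}) == [int(p) for p in positions]:
            return planted, [int(p) for p in positions]
    raise RuntimeError("could not build a collision-free motif fixture")
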