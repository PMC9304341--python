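import collections

import numpy as np
import pytest

from atacdiff import seatac, synthetic_data, vplots
from atacdiff.fragments import FragmentRecord, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_fragment(start, end, chrom="chr1", sample="s1", rep="r1"):
    return FragmentRecord(GenomicInterval(chrom, start, end), sample, rep)


def random_fragments(rng, n, chrom="chr1", lo=0, hi=10_000, max_len=400):
    out = []
    for _ in range(n):
        start = int(rng.integers(lo, hi))
        length = int(rng.integers(1, max_len))
        out.append(make_fragment(start, start + length, chrom=chrom))
    return out


def vplots_by_sample(dataset, grid=None):
    """Bucket a synthetic dataset's fragments into per-region V-plots."""
    grid = grid or vplots.VPlotGrid()
    starts = np.array([r.interval.start for r in dataset.regions])
    out = {}
    for sample_id, frags in dataset.fragments.items():
        buckets = collections.defaultdict(list)
        for f in frags:
            idx = int(np.searchsorted(starts, f.midpoint, side="right")) - 1
            if 0 <= idx < len(dataset.regions):
                iv = dataset.regions[idx].interval
                if iv.start <= f.midpoint < iv.end:
                    buckets[idx].append(f)
        out[sample_id] = [
            vplots.build_vplot(buckets.get(i, []), r.interval, grid, sample_id)
            for i, r in enumerate(dataset.regions)
        ]
    return out


def train_on_dataset(dataset, total_steps=4000, hidden=128, seed=11, **kw):
    """Train the conditional VAE on every region x sample V-plot of a dataset."""
    grid = vplots.VPlotGrid()
    by_sample = vplots_by_sample(dataset, grid)
    samples = [seatac.SampleInfo(s, i) for i, s in enumerate(dataset.fragments)]
    all_vp, all_s = [], []
    for s in samples:
        all_vp.extend(by_sample[s.sample_id])
        all_s.extend([s] * len(dataset.regions))
    config = seatac.ModelConfig(
        n_samples=len(samples), total_steps=total_steps, warmup_steps=50,
        hidden=hidden, seed=seed, grid=grid, **kw,
    )
    model, history = seatac.train(all_vp, all_s, config)
    return model, history, samples, by_sample


def condition_vplots(dataset, by_sample, samples, condition):
    """Region-major list of per-replicate V-plots for one condition prefix."""
    cond_samples = [s for s in samples if s.sample_id.startswith(condition)]
    n = len(dataset.regions)
    return cond_samples, [
        [by_sample[s.sample_id][i] for s in cond_samples] for i in range(n)
    ]
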