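"""Sample-conditioned variational autoencoder over V-plots and the
chi-squared latent-space test for differential accessibility.

The model treats each region x sample V-plot as a multinomial draw over the
grid cells. An encoder maps (V-plot density, sample one-hot) to a diagonal
Gaussian posterior over K latent dimensions; a decoder maps (z, sample
one-hot) back to cell probabilities. Conditioning both networks on the sample
indicator lets the latent space absorb region structure while the decoder
explains sample-specific nuisance (e.g. fragment-size profile shifts).

The networks are dense two-layer stacks implemented directly in NumPy with
hand-written backpropagation, trained with Adam under a linear-warmup /
cosine-decay learning-rate schedule. One reparameterized Monte Carlo draw is
used per training step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .fragments import GenomicInterval
from .vplots import GeometryError, VPlot, VPlotGrid

__all__ = [
    "ModelConfig",
    "SampleInfo",
    "LatentPosterior",
    "DifferentialResult",
    "TrainingDivergedError",
    "VPlotVAE",
    "encode",
    "elbo",
    "train",
    "chi2_test",
    "bh_adjust",
    "log_ratio",
    "rank_regions",
    "differential_test",
    "write_results_tsv",
]

_LOGSD_MIN, _LOGSD_MAX = -5.0, 5.0


class TrainingDivergedError(RuntimeError):
    """NaN/inf loss encountered during training."""


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    indicator_index: int
    n_fragments: int = 0

    def __post_init__(self) -> None:
        if self.indicator_index < 0:
            raise ValueError("indicator_index must be >= 0")


@dataclass(frozen=True)
class ModelConfig:
    K: int = 5
    grid: VPlotGrid = field(default_factory=VPlotGrid)
    n_samples: int = 2
    hidden: int = 128
    learning_rate: float = 0.01
    warmup_steps: int = 50
    total_steps: int = 2000
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not self.warmup_steps < self.total_steps:
            raise ValueError("warmup_steps must be < total_steps")


@dataclass(frozen=True)
class LatentPosterior:
    """Diagonal-Gaussian posterior q(z | x, s) for one region x sample."""

    region: GenomicInterval
    sample: SampleInfo
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have the same shape")
        if np.any(self.sd <= 0):
            raise ValueError("sd entries must be > 0")


@dataclass
class DifferentialResult:
    region: GenomicInterval
    chi2_stat: float
    df: int
    p_value: float
    p_adjusted: float
    log_ratio: float
    rank: int = 0


def _cosine_warmup_lr(step: int, base_lr: float, warmup: int, total: int) -> float:
    """Linear warmup to base_lr over ``warmup`` steps, cosine decay to 0 at ``total``."""
    if step < warmup:
        return base_lr * (step + 1) / warmup
    progress = (step - warmup) / max(total - warmup, 1)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * min(progress, 1.0)))


class VPlotVAE:
    """Conditional VAE over flattened V-plot grids (NumPy, manual gradients)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        grid = config.grid
        self.D = grid.n_size_bins * grid.n_position_bins
        self.S = config.n_samples
        self.K = config.K
        self.H = config.hidden
        rng = np.random.default_rng(config.seed)
        self.params = self._init_params(rng)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        def glorot(n_in: int, n_out: int) -> np.ndarray:
            scale = np.sqrt(2.0 / (n_in + n_out))
            return rng.normal(0.0, scale, size=(n_in, n_out))

        D, S, K, H = self.D, self.S, self.K, self.H
        return {
            "W1": glorot(D + S, H), "b1": np.zeros(H),
            "Wm": glorot(H, K), "bm": np.zeros(K),
            "Ws": glorot(H, K), "bs": np.zeros(K),
            "W2": glorot(K + S, H), "b2": np.zeros(H),
            "W3": glorot(H, D), "b3": np.zeros(D),
        }

    # ---- forward pieces -------------------------------------------------

    @staticmethod
    def _density(counts: np.ndarray) -> np.ndarray:
        """Row-normalized flattened counts (zero rows stay zero)."""
        flat = counts.reshape(counts.shape[0], -1).astype(float)
        totals = flat.sum(axis=1, keepdims=True)
        safe = np.where(totals > 0, totals, 1.0)
        return flat / safe

    def encode_batch(self, xd: np.ndarray, s_onehot: np.ndarray):
        p = self.params
        x_in = np.concatenate([xd, s_onehot], axis=1)
        pre1 = x_in @ p["W1"] + p["b1"]
        h1 = np.maximum(pre1, 0.0)
        mu = h1 @ p["Wm"] + p["bm"]
        logsd = np.clip(h1 @ p["Ws"] + p["bs"], _LOGSD_MIN, _LOGSD_MAX)
        return mu, logsd, (x_in, pre1, h1)

    def decode_batch(self, z: np.ndarray, s_onehot: np.ndarray):
        p = self.params
        zd_in = np.concatenate([z, s_onehot], axis=1)
        pre2 = zd_in @ p["W2"] + p["b2"]
        h2 = np.maximum(pre2, 0.0)
        logits = h2 @ p["W3"] + p["b3"]
        logits = logits - logits.max(axis=1, keepdims=True)
        logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        return logp, (zd_in, pre2, h2)

    # ---- training -------------------------------------------------------

    def _step(self, counts: np.ndarray, s_onehot: np.ndarray,
              rng: np.random.Generator, lr: float) -> float:
        """One Adam step on a minibatch; returns mean negative ELBO."""
        B = counts.shape[0]
        flat = counts.reshape(B, -1).astype(float)
        totals = flat.sum(axis=1, keepdims=True)
        xd = self._density(counts)

        mu, logsd, (x_in, pre1, h1) = self.encode_batch(xd, s_onehot)
        sd = np.exp(logsd)
        eps = rng.standard_normal(mu.shape)
        z = mu + sd * eps
        logp, (zd_in, pre2, h2) = self.decode_batch(z, s_onehot)

        recon = (flat * logp).sum(axis=1)
        kl = 0.5 * (sd**2 + mu**2 - 1.0 - 2.0 * logsd).sum(axis=1)
        loss = float(np.mean(kl - recon))
        if not np.isfinite(loss):
            raise TrainingDivergedError(f"non-finite loss at step {self._adam_t}")

        p = self.params
        # d(-recon)/dlogits for a multinomial with per-row totals
        probs = np.exp(logp)
        dlogits = (totals * probs - flat) / B
        g = {}
        g["W3"] = h2.T @ dlogits
        g["b3"] = dlogits.sum(axis=0)
        dh2 = dlogits @ p["W3"].T
        dpre2 = dh2 * (pre2 > 0)
        g["W2"] = zd_in.T @ dpre2
        g["b2"] = dpre2.sum(axis=0)
        dz = dpre2 @ p["W2"][: self.K].T
        # KL gradients (mean over batch)
        dmu = dz + mu / B
        active = (logsd > _LOGSD_MIN) & (logsd < _LOGSD_MAX)
        dlogsd = (dz * eps * sd + (sd**2 - 1.0) / B) * active
        g["Wm"] = h1.T @ dmu
        g["bm"] = dmu.sum(axis=0)
        g["Ws"] = h1.T @ dlogsd
        g["bs"] = dlogsd.sum(axis=0)
        dh1 = dmu @ p["Wm"].T + dlogsd @ p["Ws"].T
        dpre1 = dh1 * (pre1 > 0)
        g["W1"] = x_in.T @ dpre1
        g["b1"] = dpre1.sum(axis=0)

        self._adam_t += 1
        b1, b2c, epsn = 0.9, 0.999, 1e-8
        t = self._adam_t
        for k in self.params:
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g[k]
            self._adam_v[k] = b2c * self._adam_v[k] + (1 - b2c) * g[k] ** 2
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2c**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + epsn)
        return loss

    def mean_elbo(self, counts: np.ndarray, s_onehot: np.ndarray,
                  rng: np.random.Generator | None = None, n_mc: int = 1) -> float:
        """Mean ELBO over a batch (MC reconstruction + analytic KL)."""
        B = counts.shape[0]
        flat = counts.reshape(B, -1).astype(float)
        xd = self._density(counts)
        mu, logsd, _ = self.encode_batch(xd, s_onehot)
        sd = np.exp(logsd)
        kl = 0.5 * (sd**2 + mu**2 - 1.0 - 2.0 * logsd).sum(axis=1)
        rng = rng or np.random.default_rng(0)
        recon = np.zeros(B)
        for _ in range(n_mc):
            z = mu + sd * rng.standard_normal(mu.shape)
            logp, _ = self.decode_batch(z, s_onehot)
            recon += (flat * logp).sum(axis=1)
        recon /= n_mc
        return float(np.mean(recon - kl))

    # ---- persistence ----------------------------------------------------

    def save(self, path) -> None:
        cfg = asdict(self.config)
        cfg["grid"] = asdict(self.config.grid)
        np.savez(
            path,
            _config=np.array(json.dumps(cfg)),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "VPlotVAE":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["_config"]))
        cfg["grid"] = VPlotGrid(**cfg["grid"])
        model = cls(ModelConfig(**cfg))
        for k in model.params:
            model.params[k] = data[k]
        return model


def _onehot(indices: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(indices), n))
    out[np.arange(len(indices)), indices] = 1.0
    return out


def encode(vplot: VPlot, sample: SampleInfo, model: VPlotVAE) -> LatentPosterior:
    """Posterior q(z | x, s) for one V-plot. Deterministic given model state."""
    if vplot.grid != model.config.grid:
        raise GeometryError("V-plot grid does not match model grid")
    counts = vplot.counts[None]
    s = _onehot(np.array([sample.indicator_index]), model.S)
    xd = model._density(counts)
    mu, logsd, _ = model.encode_batch(xd, s)
    return LatentPosterior(vplot.region, sample, mu[0], np.exp(logsd[0]))


def elbo(
    vplot: VPlot,
    sample: SampleInfo,
    posterior: LatentPosterior,
    model: VPlotVAE,
    n_mc: int = 1,
    rng: np.random.Generator | None = None,
) -> float:
    """ELBO = Monte Carlo reconstruction term - analytic KL(q || N(0, I))."""
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = rng or np.random.default_rng(0)
    flat = vplot.counts.reshape(-1).astype(float)
    s = _onehot(np.array([sample.indicator_index]), model.S)
    mu, sd = posterior.mean, posterior.sd
    kl = kl_diag_gaussian(mu, sd)
    recon = 0.0
    for _ in range(n_mc):
        z = (mu + sd * rng.standard_normal(mu.shape))[None]
        logp, _ = model.decode_batch(z, s)
        recon += float(flat @ logp[0])
    return recon / n_mc - kl


def kl_diag_gaussian(mean: np.ndarray, sd: np.ndarray) -> float:
    """Closed-form KL( N(mean, diag(sd^2)) || N(0, I) )."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    return float(0.5 * np.sum(sd**2 + mean**2 - 1.0 - 2.0 * np.log(sd)))


def train(
    vplots: Sequence[VPlot],
    samples: Sequence[SampleInfo],
    config: ModelConfig,
    holdout_fraction: float = 0.1,
) -> tuple[VPlotVAE, dict]:
    """Train the conditional VAE on region x sample V-plots.

    ``samples[i]`` is the sample of ``vplots[i]``. Returns the trained model
    and a history dict with initial/final held-out ELBO and the loss trace.
    """
    if len(vplots) < 2:
        raise ValueError("need at least 2 V-plots to train")
    if len(vplots) != len(samples):
        raise ValueError("vplots and samples must have equal length")
    counts = np.stack([vp.counts for vp in vplots])
    s_idx = np.array([s.indicator_index for s in samples])
    s_onehot = _onehot(s_idx, config.n_samples)

    rng = np.random.default_rng(config.seed)
    n = len(vplots)
    perm = rng.permutation(n)
    n_hold = max(1, int(round(holdout_fraction * n)))
    hold, tr = perm[:n_hold], perm[n_hold:]
    if tr.size == 0:
        tr = perm

    model = VPlotVAE(config)
    eval_rng = np.random.default_rng(config.seed + 1)
    initial_elbo = model.mean_elbo(counts[hold], s_onehot[hold],
                                   np.random.default_rng(config.seed + 2), n_mc=5)
    losses = []
    B = min(config.batch_size, tr.size)
    for step in range(config.total_steps):
        batch = rng.choice(tr, size=B, replace=False)
        lr = _cosine_warmup_lr(step, config.learning_rate,
                               config.warmup_steps, config.total_steps)
        losses.append(model._step(counts[batch], s_onehot[batch], rng, lr))
    final_elbo = model.mean_elbo(counts[hold], s_onehot[hold],
                                 np.random.default_rng(config.seed + 2), n_mc=5)
    history = {
        "initial_holdout_elbo": initial_elbo,
        "final_holdout_elbo": final_elbo,
        "losses": losses,
    }
    return model, history


def chi2_test(
    a: Sequence[LatentPosterior], b: Sequence[LatentPosterior]
) -> tuple[float, float]:
    """Chi-squared test with K degrees of freedom between two pooled posteriors.

    Replicates are pooled per condition: mean of posterior means, and mean of
    posterior variances divided by the replicate count. The statistic is the
    variance-standardized squared distance of the pooled means; the p-value
    is the upper tail of chi-squared with K df.
    """
    if not a or not b:
        raise ValueError("both conditions need >= 1 posterior")
    K = a[0].mean.size
    for post in list(a) + list(b):
        if post.mean.size != K:
            raise GeometryError("posteriors have mismatched K")
    mu_a = np.mean([p.mean for p in a], axis=0)
    mu_b = np.mean([p.mean for p in b], axis=0)
    var_a = np.mean([p.sd**2 for p in a], axis=0) / len(a)
    var_b = np.mean([p.sd**2 for p in b], axis=0) / len(b)
    t = float(np.sum((mu_a - mu_b) ** 2 / (var_a + var_b)))
    p = float(stats.chi2.sf(t, df=K))
    return t, max(p, np.finfo(float).tiny)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def log_ratio(
    vplot_a: VPlot,
    vplot_b: VPlot,
    center_width: int = 200,
    threshold: int = 150,
    pseudocount: float = 1.0,
) -> float:
    """Natural log of the ratio of central nucleosomal-fragment densities.

    Each side's central nucleosomal count is normalized by the V-plot total
    before the pseudocounted ratio; negative values mean condition A has
    proportionally fewer central nucleosomal fragments than condition B.
    Size bins whose lower edge is >= ``threshold`` count as nucleosomal.
    """
    if vplot_a.grid != vplot_b.grid:
        raise GeometryError("V-plots must share one grid")
    grid = vplot_a.grid

    def central_density(vp: VPlot) -> float:
        total = vp.total
        if total == 0:
            return 0.0
        row0 = max(0, -(-(threshold - grid.size_min) // grid.size_bin))
        col_lo = (grid.window_width - center_width) // 2 // grid.position_bin
        col_hi = (grid.window_width + center_width) // 2 // grid.position_bin
        central = vp.counts[row0:, col_lo:col_hi].sum()
        return float(central) / total

    da, db = central_density(vplot_a), central_density(vplot_b)
    return float(np.log((da + pseudocount) / (db + pseudocount)))


def rank_regions(
    results: Sequence[DifferentialResult],
    p_cut: float = 0.05,
    lr_cut: float = -0.2,
    named_region: GenomicInterval | None = None,
) -> tuple[list[DifferentialResult], float | None]:
    """Select significant regions and rank all results.

    Selection: adjusted p < ``p_cut`` and log ratio < ``lr_cut``. Ranking is
    by ascending adjusted p with log ratio as tie-breaker; ranks are written
    back onto the results. If ``named_region`` is given, its percentile
    (rank / n) is returned.
    """
    ordered = sorted(results, key=lambda r: (r.p_adjusted, r.log_ratio))
    for rank, res in enumerate(ordered, start=1):
        res.rank = rank
    selected = [
        r for r in results if r.p_adjusted < p_cut and r.log_ratio < lr_cut
    ]
    percentile = None
    if named_region is not None:
        for res in ordered:
            if res.region == named_region:
                percentile = res.rank / len(ordered)
                break
    return selected, percentile


def differential_test(
    vplots_a: Sequence[Sequence[VPlot]],
    vplots_b: Sequence[Sequence[VPlot]],
    samples_a: Sequence[SampleInfo],
    samples_b: Sequence[SampleInfo],
    model: VPlotVAE,
    center_width: int = 200,
    threshold: int = 150,
) -> list[DifferentialResult]:
    """Per-region differential V-plot test between two conditions.

    ``vplots_a[i][r]`` is region ``i`` in replicate ``r`` of condition A.
    The chi-squared statistic compares pooled latent posteriors; the log
    ratio compares replicate-summed V-plots (A over B).
    """
    if len(vplots_a) != len(vplots_b):
        raise ValueError("conditions must cover the same regions")
    K = model.K
    results: list[DifferentialResult] = []
    p_values: list[float] = []
    for region_a, region_b in zip(vplots_a, vplots_b):
        post_a = [encode(vp, s, model) for vp, s in zip(region_a, samples_a)]
        post_b = [encode(vp, s, model) for vp, s in zip(region_b, samples_b)]
        t, p = chi2_test(post_a, post_b)
        pooled_a = VPlot(region_a[0].region, model.config.grid,
                         sum(vp.counts for vp in region_a))
        pooled_b = VPlot(region_b[0].region, model.config.grid,
                         sum(vp.counts for vp in region_b))
        lr = log_ratio(pooled_a, pooled_b, center_width=center_width,
                       threshold=threshold)
        results.append(DifferentialResult(region_a[0].region, t, K, p, 1.0, lr))
        p_values.append(p)
    adjusted = bh_adjust(p_values)
    for res, p_adj in zip(results, adjusted):
        res.p_adjusted = float(max(p_adj, res.p_value))
    return results


def write_results_tsv(results: Sequence[DifferentialResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tchi2\tdf\tp\tp_adj\tlog_ratio\trank\n")
        for r in results:
            iv = r.region
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.chi2_stat:.6g}\t{r.df}\t"
                f"{r.p_value:.6g}\t{r.p_adjusted:.6g}\t{r.log_ratio:.6g}\t{r.rank}\n"
            )
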