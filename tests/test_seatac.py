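import numpy as np
import pytest
from scipy import stats

from atacdiff import synthetic_data
from atacdiff.fragments import GenomicInterval
from atacdiff.seatac import (
    DifferentialResult,
    LatentPosterior,
    ModelConfig,
    SampleInfo,
    VPlotVAE,
    bh_adjust,
    chi2_test,
    elbo,
    encode,
    kl_diag_gaussian,
    log_ratio,
    rank_regions,
    train,
)
from atacdiff.vplots import GeometryError, VPlot, VPlotGrid

from conftest import condition_vplots, train_on_dataset, vplots_by_sample

GRID = VPlotGrid()
REGION = GenomicInterval("chr1", 0, 640)


def random_vplot(rng, total=200, region=REGION):
    counts = rng.multinomial(total, np.full(2048, 1 / 2048)).reshape(GRID.shape)
    return VPlot(region, GRID, counts)


def posterior(mean, sd, region=REGION, sample=None):
    sample = sample or SampleInfo("s", 0)
    return LatentPosterior(region, sample, np.asarray(mean, float), np.asarray(sd, float))


@pytest.fixture(scope="module")
def tiny_model():
    cfg = ModelConfig(n_samples=2, hidden=16, total_steps=20, warmup_steps=5, seed=3)
    return VPlotVAE(cfg)


@pytest.fixture(scope="module")
def trained_batch_model():
    """Converged-enough model on a small dataset with displacement and a
    batch-level fragment-size shift in condition B."""
    cfg = synthetic_data.GeneratorConfig(
        n_regions=60, n_displaced=12, fragments_per_region=200,
        batch_len_shift={"B_rep1": 15.0, "B_rep2": 15.0}, seed=5,
    )
    dataset = synthetic_data.generate(cfg)
    model, history, samples, by_sample = train_on_dataset(
        dataset, total_steps=1500, hidden=64, seed=21,
    )
    return dataset, model, history, samples, by_sample


class TestKL:
    def test_zero_at_prior(self):
        assert kl_diag_gaussian(np.zeros(5), np.ones(5)) == 0.0

    def test_analytic_spot_value(self):
        # mu = (1, 0, ...), sigma = 1 -> KL = 0.5
        mu = np.zeros(5)
        mu[0] = 1.0
        assert abs(kl_diag_gaussian(mu, np.ones(5)) - 0.5) < 1e-12

    def test_matches_closed_form_on_random_posteriors(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 8))
            mu = rng.normal(size=k)
            sd = rng.uniform(0.1, 3.0, size=k)
            expected = 0.5 * np.sum(sd**2 + mu**2 - 1.0 - 2.0 * np.log(sd))
            assert abs(kl_diag_gaussian(mu, sd) - expected) < 1e-10


class TestEncode:
    def test_deterministic(self, tiny_model, rng):
        vp = random_vplot(rng)
        s = SampleInfo("a", 0)
        p1 = encode(vp, s, tiny_model)
        p2 = encode(vp, s, tiny_model)
        assert np.array_equal(p1.mean, p2.mean)
        assert np.array_equal(p1.sd, p2.sd)

    def test_fresh_model_contract(self, tiny_model, rng):
        post = encode(random_vplot(rng), SampleInfo("a", 1), tiny_model)
        assert post.mean.shape == (5,)
        assert np.all(np.isfinite(post.mean))
        assert np.all(post.sd > 0)

    def test_grid_mismatch(self, tiny_model):
        grid = VPlotGrid(window_width=320)
        vp = VPlot(GenomicInterval("chr1", 0, 320), grid,
                   np.zeros(grid.shape, dtype=int))
        with pytest.raises(GeometryError):
            encode(vp, SampleInfo("a", 0), tiny_model)

    def test_batch_shift_closer_than_displacement(self, trained_batch_model):
        """Latent means of batch-shifted null pairs sit closer than those of
        genuinely displaced pairs (sample conditioning absorbs the batch)."""
        dataset, model, _, samples, by_sample = trained_batch_model
        a1 = next(s for s in samples if s.sample_id == "A_rep1")
        b1 = next(s for s in samples if s.sample_id == "B_rep1")

        def pair_distance(i):
            pa = encode(by_sample["A_rep1"][i], a1, model)
            pb = encode(by_sample["B_rep1"][i], b1, model)
            return float(np.linalg.norm(pa.mean - pb.mean))

        null_idx = [i for i, r in enumerate(dataset.regions) if not r.displaced]
        disp_idx = [i for i, r in enumerate(dataset.regions) if r.displaced]
        null_d = np.mean([pair_distance(i) for i in null_idx])
        disp_d = np.mean([pair_distance(i) for i in disp_idx])
        assert null_d < disp_d


class TestElbo:
    def test_kl_term_exact_at_prior(self, tiny_model, rng):
        vp = random_vplot(rng)
        s = SampleInfo("a", 0)
        prior_post = posterior(np.zeros(5), np.ones(5), sample=s)
        # with KL = 0, elbo equals the MC reconstruction term
        rng_fixed = np.random.default_rng(0)
        value = elbo(vp, s, prior_post, tiny_model, n_mc=3, rng=rng_fixed)
        rng_fixed = np.random.default_rng(0)
        flat = vp.counts.reshape(-1).astype(float)
        recon = 0.0
        for _ in range(3):
            z = prior_post.mean + prior_post.sd * rng_fixed.standard_normal(5)
            logp, _ = tiny_model.decode_batch(z[None], np.array([[1.0, 0.0]]))
            recon += float(flat @ logp[0])
        assert abs(value - recon / 3) < 1e-9

    def test_monte_carlo_convergence(self, tiny_model, rng):
        """Large-n_mc estimate agrees with averaged single-draw estimates."""
        vp = random_vplot(rng)
        s = SampleInfo("a", 0)
        post = encode(vp, s, tiny_model)
        big = elbo(vp, s, post, tiny_model, n_mc=4000, rng=np.random.default_rng(1))
        singles = [
            elbo(vp, s, post, tiny_model, n_mc=1, rng=np.random.default_rng(1000 + i))
            for i in range(400)
        ]
        se = np.std(singles, ddof=1) / np.sqrt(len(singles))
        assert abs(np.mean(singles) - big) < 5 * se + 1e-6

    def test_n_mc_validation(self, tiny_model, rng):
        vp = random_vplot(rng)
        s = SampleInfo("a", 0)
        with pytest.raises(ValueError):
            elbo(vp, s, encode(vp, s, tiny_model), tiny_model, n_mc=0)


class TestTrain:
    def test_elbo_improves(self, trained_batch_model):
        _, _, history, _, _ = trained_batch_model
        assert history["final_holdout_elbo"] > history["initial_holdout_elbo"]

    def test_serialization_roundtrip(self, trained_batch_model, tmp_path, rng):
        dataset, model, _, samples, by_sample = trained_batch_model
        path = tmp_path / "model.npz"
        model.save(path)
        reloaded = VPlotVAE.load(path)
        vp = by_sample["A_rep1"][0]
        p1 = encode(vp, samples[0], model)
        p2 = encode(vp, samples[0], reloaded)
        assert np.array_equal(p1.mean, p2.mean)
        assert np.array_equal(p1.sd, p2.sd)

    def test_too_few_vplots(self):
        cfg = ModelConfig(n_samples=1, total_steps=10, warmup_steps=1)
        with pytest.raises(ValueError):
            train([], [], cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(K=0)
        with pytest.raises(ValueError):
            ModelConfig(learning_rate=0)
        with pytest.raises(ValueError):
            ModelConfig(warmup_steps=100, total_steps=100)


class TestChi2Test:
    def test_identical_posteriors(self):
        a = [posterior(np.ones(5), np.ones(5))]
        b = [posterior(np.ones(5), np.ones(5))]
        t, p = chi2_test(a, b)
        assert t == 0.0
        assert p == 1.0

    def test_frozen_k1_spot_value(self):
        # K=1, mean difference 2, pooled variances 1 + 1 -> T = 2.
        # Upper tail of chi2_1 at 2, frozen from numeric integration of the
        # chi2 density (see test_spot_value_matches_numeric_integration).
        a = [posterior([2.0], [1.0])]
        b = [posterior([0.0], [1.0])]
        t, p = chi2_test(a, b)
        assert abs(t - 2.0) < 1e-12
        assert abs(p - 0.15730) < 1e-4

    def test_spot_value_matches_numeric_integration(self):
        # independent oracle: integrate the chi2_1 density on [2, inf)
        x = np.linspace(2.0, 200.0, 2_000_001)
        density = np.exp(-x / 2) / np.sqrt(2 * np.pi * x)
        integral = np.trapezoid(density, x)
        assert abs(integral - 0.15730) < 1e-4

    def test_replicate_pooling(self):
        # two replicates: pooled mean = mean of means,
        # pooled variance = mean of variances / 2
        a = [posterior([0.0], [1.0]), posterior([2.0], [1.0])]
        b = [posterior([0.0], [1.0]), posterior([0.0], [1.0])]
        t, _ = chi2_test(a, b)
        assert abs(t - 1.0**2 / (0.5 + 0.5)) < 1e-12

    def test_k_mismatch(self):
        with pytest.raises(GeometryError):
            chi2_test([posterior(np.zeros(5), np.ones(5))],
                      [posterior(np.zeros(3), np.ones(3))])

    def test_empty_condition(self):
        with pytest.raises(ValueError):
            chi2_test([], [posterior(np.zeros(5), np.ones(5))])

    def test_null_uniformity_small(self, rng):
        # quick calibration check; the full 10k version is in acceptance
        pvals = _null_pvalues(rng, n_rep=2, k=5, n_sims=2000)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def _null_pvalues(rng, n_rep, k, n_sims):
    """Draw posteriors per the statistic's own null model.

    Replicate posterior means scatter around a shared center with their own
    posterior sds, so the pooled mean difference is N(0, pooled variances).
    """
    pvals = np.empty(n_sims)
    for i in range(n_sims):
        center = rng.normal(size=k)
        a = [posterior(center + rng.normal(size=k) * sd, sd)
             for sd in [rng.uniform(0.5, 2.0, size=k) for _ in range(n_rep)]]
        b = [posterior(center + rng.normal(size=k) * sd, sd)
             for sd in [rng.uniform(0.5, 2.0, size=k) for _ in range(n_rep)]]
        pvals[i] = chi2_test(a, b)[1]
    return pvals


class TestBHAdjust:
    def test_hand_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])

    def test_order_preserved(self):
        p = [0.9, 0.001, 0.5]
        adj = bh_adjust(p)
        assert adj[1] == adj.min()

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    def test_against_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(1e-8, 1.0, size=int(rng.integers(1, 40)))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestLogRatio:
    def _vp(self, counts):
        return VPlot(REGION, GRID, counts)

    def test_identical_vplots(self, rng):
        vp = random_vplot(rng)
        assert log_ratio(vp, vp) == 0.0

    def test_sign_contract(self):
        counts = np.zeros(GRID.shape, dtype=int)
        counts[15, 30] = 50  # nucleosomal size (200 bp), central position
        counts[2, 10] = 50  # sub-nucleosomal, off-center
        intact = self._vp(counts)
        removed = counts.copy()
        removed[15, 30] = 0
        depleted = self._vp(removed)
        assert log_ratio(depleted, intact) < 0

    def test_hand_calculation(self):
        counts_a = np.zeros(GRID.shape, dtype=int)
        counts_a[15, 30] = 10  # central nucleosomal
        counts_a[2, 5] = 30
        counts_b = np.zeros(GRID.shape, dtype=int)
        counts_b[15, 30] = 30
        counts_b[2, 5] = 10
        # central nucleosomal densities: 10/40 vs 30/40
        expected = np.log((0.25 + 1.0) / (0.75 + 1.0))
        got = log_ratio(self._vp(counts_a), self._vp(counts_b))
        assert abs(got - expected) < 1e-12

    def test_grid_mismatch(self, rng):
        other_grid = VPlotGrid(window_width=320)
        other = VPlot(GenomicInterval("chr1", 0, 320), other_grid,
                      np.zeros(other_grid.shape, dtype=int))
        with pytest.raises(GeometryError):
            log_ratio(random_vplot(rng), other)


class TestRankRegions:
    def _result(self, i, p_adj, lr):
        region = GenomicInterval("chr1", i * 1000, i * 1000 + 640)
        return DifferentialResult(region, 1.0, 5, p_adj, p_adj, lr)

    def test_all_null(self):
        results = [self._result(i, 1.0, 0.0) for i in range(5)]
        selected, _ = rank_regions(results)
        assert selected == []

    def test_single_hit(self):
        results = [self._result(0, 0.01, -0.5)] + [
            self._result(i, 1.0, 0.0) for i in range(1, 5)
        ]
        selected, pct = rank_regions(results, named_region=results[0].region)
        assert selected == [results[0]]
        assert results[0].rank == 1
        assert pct == 1 / 5

    def test_filter_and_sort_oracle(self, rng):
        results = [
            self._result(i, float(p), float(lr))
            for i, (p, lr) in enumerate(zip(rng.uniform(0, 1, 50),
                                            rng.normal(0, 0.5, 50)))
        ]
        selected, _ = rank_regions(results)
        expected = [r for r in results if r.p_adjusted < 0.05 and r.log_ratio < -0.2]
        assert selected == expected
        ordered = sorted(results, key=lambda r: (r.p_adjusted, r.log_ratio))
        assert [r.rank for r in ordered] == list(range(1, 51))
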