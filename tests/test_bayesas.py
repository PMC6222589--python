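"""Region partitions, chain bookkeeping, and sampler structure/recovery."""

import numpy as np
import pytest

from wgblup import grm, mtblup
from wgblup.bayesas import (McmcConfig, derive_variance_components,
                            make_regions, run_multitrait_bayesas,
                            run_singletrait_bayesas)
from wgblup.grm import SnpCovarianceTrack, center_genotypes


def _hwe(rng, n, m, p_lo=0.1, p_hi=0.9):
    p = rng.uniform(p_lo, p_hi, m)
    D = ((rng.random((n, m)) < p).astype(np.int8)
         + (rng.random((n, m)) < p).astype(np.int8))
    return center_genotypes(D)


class TestRegions:
    def test_fixed_k_respects_chromosome_boundaries(self):
        part = make_regions([150, 100], "fixed_k", 100)
        assert part.sizes().tolist() == [100, 50, 100]
        assert part.starts.tolist() == [0, 100, 150]

    def test_per_snp_one_region_each(self):
        part = make_regions([30, 20], "per_snp")
        assert part.n_regions == 50
        assert (part.sizes() == 1).all()

    def test_genome_single_region(self):
        part = make_regions([30, 20], "genome")
        assert part.n_regions == 1
        assert part.sizes().tolist() == [50]

    def test_chromosome_mode(self):
        part = make_regions([30, 20], "chromosome")
        assert part.sizes().tolist() == [30, 20]

    def test_oversized_k_degrades_to_chromosomes(self, caplog):
        with caplog.at_level("WARNING"):
            part = make_regions([30, 20], "fixed_k", 500)
        assert part.sizes().tolist() == [30, 20]
        assert "exceeds" in caplog.text

    def test_region_of_is_partition(self):
        part = make_regions([7, 5], "fixed_k", 3)
        ro = part.region_of
        assert len(ro) == 12
        for s in range(part.n_regions):
            idx = np.flatnonzero(ro == s)
            assert idx.tolist() == list(range(part.starts[s], part.ends[s]))


class TestConfig:
    def test_default_chain_saves_1500_samples(self):
        assert McmcConfig().n_saved == 1_500

    def test_burn_in_must_precede_end(self):
        with pytest.raises(ValueError):
            McmcConfig(n_cycles=100, burn_in=100)

    def test_saved_sample_bookkeeping_matches_run(self, rng):
        X = _hwe(rng, 40, 30)
        y = rng.normal(0, 1, (2, 40))
        cfg = McmcConfig(n_cycles=73, burn_in=20, thinning=7, seed=1)
        s = run_multitrait_bayesas(y[0], y[1], X,
                                   make_regions([30], "genome"), cfg)
        assert s.n_saved == cfg.n_saved == (73 - 20) // 7


class TestMultiTrait:
    def test_genome_mode_variance_constant_across_snps(self, rng):
        X = _hwe(rng, 60, 40)
        y = rng.normal(0, 1, (2, 60))
        s = run_multitrait_bayesas(y[0], y[1], X, make_regions([40], "genome"),
                                   McmcConfig(n_cycles=200, burn_in=50,
                                              thinning=2, seed=3))
        assert np.ptp(s.track.var_L) == 0.0
        assert np.ptp(s.track.var_H) == 0.0
        assert np.ptp(s.track.cov_LH) == 0.0

    def test_chain_determinism(self, rng):
        X = _hwe(rng, 50, 30)
        y = rng.normal(0, 1, (2, 50))
        part = make_regions([30], "fixed_k", 10)
        cfg = McmcConfig(n_cycles=150, burn_in=50, thinning=2, seed=11)
        s1 = run_multitrait_bayesas(y[0], y[1], X, part, cfg)
        s2 = run_multitrait_bayesas(y[0], y[1], X, part, cfg)
        np.testing.assert_array_equal(s1.track.var_L, s2.track.var_L)
        np.testing.assert_array_equal(s1.beta_mean, s2.beta_mean)
        np.testing.assert_array_equal(s1.R0, s2.R0)

    def test_planted_region_attains_max_variance(self):
        # one region carries all the signal; its posterior variance should
        # dominate the nine null regions
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = _hwe(rng, 120, 200)
            beta = np.zeros((2, X.n_snps))
            beta[:, :20] = rng.normal(0, 0.4, (2, 20))
            u = beta @ X.X.T
            y = u + rng.normal(0, u.std(axis=1, keepdims=True), u.shape)
            part = make_regions([X.n_snps], "fixed_k", 20)
            s = run_multitrait_bayesas(y[0], y[1], X, part,
                                       McmcConfig(n_cycles=500, burn_in=150,
                                                  thinning=2, seed=seed))
            region_var = s.track.var_L[part.starts] + s.track.var_H[part.starts]
            hits += np.argmax(region_var) == 0
        assert hits >= 2

    def test_variance_component_recovery_generative(self):
        # data simulated from the model itself: derived genomic variance
        # should land near truth (wide stochastic band)
        rng = np.random.default_rng(42)
        X = _hwe(rng, 300, 150)
        m = X.n_snps
        true_var = 0.02
        beta = rng.normal(0, np.sqrt(true_var), (2, m))
        u = beta @ X.X.T
        e = rng.normal(0, 1.0, (2, 300))
        y = u + e
        s = run_multitrait_bayesas(y[0], y[1], X,
                                   make_regions([m], "fixed_k", 30),
                                   McmcConfig(n_cycles=1_000, burn_in=300,
                                              thinning=2, seed=7))
        s2uL, s2uH, _ = derive_variance_components(s.track, X.frequencies)
        truth = true_var * X.sum_2pq
        assert 0.4 * truth < s2uL < 2.5 * truth
        assert 0.4 * truth < s2uH < 2.5 * truth
        # residual variance recovered too
        assert 0.5 < s.R0[0, 0] < 2.0

    def test_missing_phenotypes_rejected(self, rng):
        X = _hwe(rng, 20, 10)
        y = rng.normal(0, 1, 20)
        y_bad = y.copy()
        y_bad[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            run_multitrait_bayesas(y, y_bad, X, make_regions([10], "genome"),
                                   McmcConfig(n_cycles=10, burn_in=2, thinning=1))

    def test_zero_variance_trait_rejected(self, rng):
        X = _hwe(rng, 20, 10)
        with pytest.raises(ValueError, match="variance"):
            run_multitrait_bayesas(np.ones(20), rng.normal(0, 1, 20), X,
                                   make_regions([10], "genome"),
                                   McmcConfig(n_cycles=10, burn_in=2, thinning=1))


class TestSingleTrait:
    def test_null_data_variance_near_fixed_floor(self, rng):
        # no genetic signal: per-SNP variance collapses to the fixed
        # trait-specific component plus a small r_ts contribution
        X = _hwe(rng, 150, 60)
        y = rng.normal(0, 1, 150)
        fixed = 0.01  # dominates the r_ts sampling floor of ~ s2e/|X s1|^2
        s = run_singletrait_bayesas(y, X, make_regions([60], "fixed_k", 20),
                                    McmcConfig(n_cycles=400, burn_in=100,
                                               thinning=2, seed=5),
                                    sigma2_beta_star_fixed=fixed)
        assert (s.track.var_L >= fixed).all()
        assert s.track.var_L.mean() < 2 * fixed

    def test_requires_positive_fixed_variance(self, rng):
        X = _hwe(rng, 20, 10)
        with pytest.raises(ValueError, match="positive"):
            run_singletrait_bayesas(rng.normal(0, 1, 20), X,
                                    make_regions([10], "genome"),
                                    McmcConfig(n_cycles=10, burn_in=2,
                                               thinning=1),
                                    sigma2_beta_star_fixed=0.0)

    def test_genome_mode_ebv_matches_single_trait_gblup(self):
        # infinitesimal data: whole-genome BayesAS shares GBLUP's assumptions
        rng = np.random.default_rng(9)
        X = _hwe(rng, 200, 300)
        beta = rng.normal(0, 0.05, X.n_snps)
        u = X.X @ beta
        y = u + rng.normal(0, u.std(), 200)
        s = run_singletrait_bayesas(y, X, make_regions([X.n_snps], "genome"),
                                    McmcConfig(n_cycles=800, burn_in=200,
                                               thinning=2, seed=2),
                                    sigma2_beta_star_fixed=0.05 ** 2)
        s2u, _, _ = derive_variance_components(s.track, X.frequencies)
        G = grm.build_grm(X).G
        ids = np.arange(200)
        tab = mtblup.solve_gblup_single(y, G, s2u, float(s.R0[0, 0]), ids,
                                        ids, np.array([], dtype=int))
        r = np.corrcoef(s.ebv_reference[:, 0], tab["ebv"].to_numpy())[0, 1]
        assert r > 0.98


class TestVarianceComponents:
    def test_hand_toy(self):
        track = SnpCovarianceTrack(var_L=np.array([1.0, 2.0]),
                                   var_H=np.array([0.5, 0.5]),
                                   cov_LH=np.array([0.2, -0.4]))
        p = np.array([0.5, 0.2])
        s2uL, s2uH, suLH = derive_variance_components(track, p)
        # 2pq = (0.5, 0.32): s2uL = 0.5*1 + 0.32*2 = 1.14
        assert s2uL == pytest.approx(1.14)
        assert s2uH == pytest.approx(0.5 * 0.5 + 0.32 * 0.5)
        assert suLH == pytest.approx(0.5 * 0.2 - 0.32 * 0.4)

    def test_uniform_track_recovers_homogeneous_identity(self, rng):
        m = 40
        p = rng.uniform(0.1, 0.9, m)
        track = SnpCovarianceTrack(var_L=np.full(m, 0.3),
                                   var_H=np.full(m, 0.3),
                                   cov_LH=np.full(m, 0.1))
        s2uL, _, suLH = derive_variance_components(track, p)
        s2pq = np.sum(2 * p * (1 - p))
        assert s2uL == pytest.approx(0.3 * s2pq)
        assert np.sign(suLH) == 1.0

    def test_misaligned_frequencies(self):
        track = SnpCovarianceTrack(var_L=np.ones(3), var_H=np.ones(3),
                                   cov_LH=np.zeros(3))
        with pytest.raises(ValueError, match="aligned"):
            derive_variance_components(track, np.array([0.5]))
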