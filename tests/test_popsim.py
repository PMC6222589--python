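"""Breeding-simulator behavior: maps, meiosis, mating design, drift."""

import numpy as np
import pytest
from scipy import stats

from wgblup import popsim
from wgblup.popsim import (GeneticMap, _meiosis_pattern, breed_generation,
                           default_map, generate_base_panel,
                           simulate_generations, simulate_meiosis)
from wgblup.traitsim import n_bins_per_chromosome


def _single_chrom_map(length_morgan, snp_pos_morgan, length_bp=1_000_000):
    pos_m = np.asarray(snp_pos_morgan, dtype=float)
    frac = pos_m / length_morgan if length_morgan > 0 else np.linspace(0.2, 0.8, len(pos_m))
    pos_bp = np.maximum((frac * length_bp).astype(np.int64), 1)
    pos_bp = np.unique(pos_bp)
    return GeneticMap((length_bp,), (length_morgan,), (pos_bp,), (pos_m,))


class TestGeneticMap:
    def test_default_map_matches_printed_bin_counts(self):
        gmap = default_map(11_154)
        assert gmap.n_snps == 11_154
        assert list(n_bins_per_chromosome(gmap)) == [159, 139, 127, 121, 125]
        # 1 cM/Mbp: a 159 Mbp chromosome is 1.59 Morgans
        assert gmap.lengths_morgan[0] == pytest.approx(1.59)

    def test_invalid_positions_rejected(self):
        with pytest.raises(ValueError):
            GeneticMap((100,), (0.1,), (np.array([0, 50]),),
                       (np.array([0.0, 0.05]),))  # bp position 0 not allowed
        with pytest.raises(ValueError):
            GeneticMap((100,), (0.1,), (np.array([10, 50]),),
                       (np.array([0.05, 0.01]),))  # decreasing Morgan


class TestBasePanel:
    def test_deterministic_given_seed(self, small_map):
        a = generate_base_panel(30, small_map, seed=7)
        b = generate_base_panel(30, small_map, seed=7)
        c = generate_base_panel(30, small_map, seed=8)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        assert not np.array_equal(a.haplotypes, c.haplotypes)

    def test_maf_floor_half_is_empty_domain(self, small_map):
        with pytest.raises(ValueError, match="maf_floor"):
            generate_base_panel(30, small_map, maf_floor=0.5)

    def test_maf_floor_enforced(self, small_map):
        panel = generate_base_panel(60, small_map, maf_floor=0.05, seed=3)
        assert panel.maf().min() >= 0.05
        assert panel.n_snps == small_map.n_snps  # count preserved by ascertainment

    def test_full_scale_snp_count(self):
        gmap = default_map(11_154)
        panel = generate_base_panel(20, gmap, seed=0)
        assert panel.haplotypes.shape == (20, 2, 11_154)

    def test_coalescent_panel_has_local_ld(self):
        # shared genealogy must leave adjacent SNPs more correlated than
        # distant ones on average — the signal region-wise weighting exploits
        gmap = default_map(400, chrom_mbp=(50,))
        panel = generate_base_panel(60, gmap, seed=11)
        H = panel.haplotypes.reshape(-1, panel.n_snps).astype(float)
        r_adj = [abs(np.corrcoef(H[:, j], H[:, j + 1])[0, 1])
                 for j in range(0, 300, 3)]
        r_far = [abs(np.corrcoef(H[:, j], H[:, j + 200])[0, 1])
                 for j in range(0, 200, 3)]
        assert np.mean(r_adj) > np.mean(r_far)


class TestMeiosis:
    def test_zero_morgan_chromosome_transmitted_intact(self, rng):
        gmap = _single_chrom_map(0.0, [0.0, 0.0, 0.0])
        parent = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.uint8)
        for _ in range(20):
            gamete = simulate_meiosis(parent, gmap, rng)
            assert gamete.tolist() in ([0, 0, 0], [1, 1, 1])

    def test_crossover_count_mean_matches_map_length(self, rng):
        # dense markers let us count crossovers as haplotype-origin switches
        gmap = _single_chrom_map(1.0, np.linspace(0.001, 0.999, 1000))
        switches = np.empty(10_000)
        for i in range(10_000):
            pat = _meiosis_pattern(gmap, rng).astype(int)
            switches[i] = np.abs(np.diff(pat)).sum()
        se = switches.std() / 100.0
        assert abs(switches.mean() - 1.0) < 3 * se + 0.01

    def test_crossover_counts_poisson_distributed(self, rng):
        gmap = _single_chrom_map(1.0, np.linspace(0.001, 0.999, 1000))
        counts = np.empty(10_000, dtype=int)
        for i in range(10_000):
            pat = _meiosis_pattern(gmap, rng).astype(int)
            counts[i] = np.abs(np.diff(pat)).sum()
        edges = [0, 1, 2, 3, 4]
        obs = np.array([(counts == k).sum() for k in edges[:-1]]
                       + [(counts >= 4).sum()])
        pois = stats.poisson(1.0)
        exp = np.array([pois.pmf(k) for k in edges[:-1]] + [pois.sf(3)]) * len(counts)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2(len(obs) - 1).ppf(0.99)

    def test_haldane_recombination_fraction(self, rng):
        # two loci 0.1 M apart: r = (1 - exp(-0.2)) / 2 ~ 0.0906
        gmap = _single_chrom_map(0.2, [0.05, 0.15])
        n = 100_000
        rec = 0
        for _ in range(n):
            pat = _meiosis_pattern(gmap, rng)
            rec += pat[0] != pat[1]
        r_hat = rec / n
        r_true = 0.5 * (1 - np.exp(-0.2))
        se = np.sqrt(r_true * (1 - r_true) / n)
        assert abs(r_hat - r_true) < 3 * se

    def test_gamete_alleles_traceable_to_parent(self, small_map, rng):
        parent = (rng.random((2, small_map.n_snps)) < 0.5).astype(np.uint8)
        for _ in range(10):
            gamete = simulate_meiosis(parent, small_map, rng)
            ok = (gamete == parent[0]) | (gamete == parent[1])
            assert ok.all()


class TestBreeding:
    def test_scaled_design_offspring_count(self, small_map, rng):
        panel = generate_base_panel(22, small_map, seed=5, n_males=2)
        off, ped = breed_generation(panel, rng, dams_per_sire=10)
        assert off.n_individuals == 22  # 2 x 10 matings + 2 replicated
        assert (ped["replicate"] == 1).sum() == 2
        assert (off.sex == popsim.MALE).sum() == 2

    def test_full_design_retains_population_size(self):
        gmap = default_map(20, chrom_mbp=(10,))
        panel = generate_base_panel(2_200, gmap, seed=6, n_males=200)
        off, ped = breed_generation(panel, np.random.default_rng(0))
        assert off.n_individuals == 2_200
        assert (off.sex == popsim.MALE).sum() == 200
        sire_counts = ped.groupby("sire").size()
        assert (sire_counts == 11).all()  # 10 matings + 1 replicate each
        dam_counts = ped[ped.replicate == 0].groupby("dam").size()
        assert (dam_counts == 1).all()  # dams distinct within and across sires

    def test_determinism(self, small_panel):
        o1, p1 = breed_generation(small_panel, np.random.default_rng(3),
                                  dams_per_sire=9)
        o2, p2 = breed_generation(small_panel, np.random.default_rng(3),
                                  dams_per_sire=9)
        np.testing.assert_array_equal(o1.haplotypes, o2.haplotypes)
        assert p1.equals(p2)

    def test_insufficient_parents(self, small_map, rng):
        panel = generate_base_panel(10, small_map, seed=1, n_males=5)
        with pytest.raises(ValueError, match="females"):
            breed_generation(panel, rng, dams_per_sire=10)

    def test_generation_chain_and_pedigree_consistency(self, small_panel, rng):
        panels, ped = simulate_generations(small_panel, 3, rng, dams_per_sire=9)
        assert [p.generation for p in panels] == [1, 2, 3]
        id_gen = dict(zip(ped["id"], ped["generation"]))
        id_sex = dict(zip(ped["id"], ped["sex"]))
        for _, row in ped[ped.generation > 0].iterrows():
            assert id_gen[row.sire] == row.generation - 1
            assert id_gen[row.dam] == row.generation - 1
            assert id_sex[row.sire] == popsim.MALE
            assert id_sex[row.dam] == popsim.FEMALE

    def test_no_mutation_allele_sets_never_grow(self, small_panel, rng):
        panels, _ = simulate_generations(small_panel, 2, rng, dams_per_sire=9)
        prev = small_panel
        for panel in panels:
            for j in range(panel.n_snps):
                prev_alleles = set(prev.haplotypes[:, :, j].ravel())
                new_alleles = set(panel.haplotypes[:, :, j].ravel())
                assert new_alleles <= prev_alleles
            prev = panel

    def test_drift_magnitude_matches_binomial_sampling(self):
        # one generation at 10 sires x 100 dams: Ne = 4*10*100/110 ~ 36.4,
        # so var(dp) ~ p(1-p)/(2 Ne); equalized sire family sizes make the
        # design slightly more conservative, hence the wide band
        gmap = default_map(200, chrom_mbp=(20,))
        ratios = []
        for seed in range(5):
            panel = generate_base_panel(110, gmap, seed=seed, n_males=10)
            off, _ = breed_generation(panel, np.random.default_rng(seed + 100))
            p0 = panel.allele_frequencies()
            dp = off.allele_frequencies() - p0
            expected = p0 * (1 - p0) / (2 * (4 * 10 * 100 / 110))
            ratios.append(np.mean(dp ** 2) / np.mean(expected))
        assert 0.3 < np.mean(ratios) < 2.0


class TestIO:
    def test_panel_and_map_roundtrip(self, small_panel, small_map, tmp_path):
        popsim.write_panel(small_panel, tmp_path / "panel.tsv")
        popsim.write_map(small_map, tmp_path / "map.tsv")
        gmap2 = popsim.read_map(tmp_path / "map.tsv",
                                lengths_bp=small_map.lengths_bp)
        panel2 = popsim.read_panel(tmp_path / "panel.tsv", gmap2,
                                   sex=small_panel.sex)
        np.testing.assert_array_equal(panel2.haplotypes, small_panel.haplotypes)
        np.testing.assert_allclose(np.concatenate(gmap2.snp_pos_morgan),
                                   np.concatenate(small_map.snp_pos_morgan))

    def test_pedigree_roundtrip(self, small_panel, rng, tmp_path):
        _, ped = breed_generation(small_panel, rng, dams_per_sire=9)
        popsim.write_pedigree(ped, tmp_path / "ped.tsv")
        assert popsim.read_pedigree(tmp_path / "ped.tsv").equals(ped)

    def test_vcf_readable_by_cyvcf2(self, small_map, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        panel = generate_base_panel(5, small_map, seed=2)
        path = tmp_path / "panel.vcf"
        popsim.write_vcf(panel, str(path))
        variants = list(cyvcf2.VCF(str(path)))
        assert len(variants) == panel.n_snps
        v0 = variants[0]
        got = np.array([[g[0], g[1]] for g in v0.genotypes])
        np.testing.assert_array_equal(got, panel.haplotypes[:, :, 0])
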