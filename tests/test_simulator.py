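import numpy as np
import pytest

from linkstrat.pedigree import mendelian_consistent
from linkstrat.simulator import (
    DEFAULT_SIBSHIP_RATIO,
    SimulationConfig,
    ascertain,
    ascertained_mean_sibship,
    ascertainment_probability,
    calibrate_sibship_ratio,
    default_map,
    sample_family,
    sample_sibship_size,
    simulate_dataset,
    simulate_study,
    truncated_geometric_sibship,
    _drop_gametes,
    _simulate_size_batch,
)
from linkstrat.trait_models import from_name

from conftest import make_individual


class TestDefaultMap:
    def test_study_geometry(self):
        gmap, haps = default_map(from_name("RR"))
        assert gmap.n_loci == 18
        assert (gmap.index_A, gmap.index_B, gmap.index_ld_marker) == (4, 12, 3)
        # A and B unlinked through the free-recombination gap
        assert gmap.compound_theta(gmap.index_A, gmap.index_B) == 0.5
        # the associated marker rides with A
        assert gmap.theta[3] == 0.0
        assert gmap.loci[gmap.index_A].allele_freqs[0] == 0.2
        # matched marker frequency by default
        assert gmap.loci[gmap.index_ld_marker].allele_freqs[0] == 0.2
        other = [l.allele_freqs[0] for i, l in enumerate(gmap.loci)
                 if l.kind == "marker" and i != 3]
        assert all(f == 0.5 for f in other)

    def test_marker_freq_override(self):
        gmap, haps = default_map(from_name("DD"), d_prime=0.8,
                                 marker_allele_freq=0.4)
        assert gmap.loci[3].allele_freqs[0] == 0.4
        assert haps.d_prime == pytest.approx(0.8)


class TestSibshipDistribution:
    def test_point_mass(self, dd_config, rng):
        cfg = SimulationConfig.from_model(
            "DD", sibship_dist=[1] + [0] * 8)
        assert all(sample_sibship_size(cfg, rng) == 2 for _ in range(20))

    def test_support_and_config_validation(self):
        with pytest.raises(ValueError, match="entries"):
            SimulationConfig.from_model("DD", sibship_dist=[0.5, 0.5])
        with pytest.raises(ValueError, match="probability"):
            SimulationConfig.from_model("DD", sibship_dist=[0.5] * 9)

    def test_empirical_mean_matches_analytic(self, rng):
        dist = truncated_geometric_sibship(DEFAULT_SIBSHIP_RATIO)
        sizes = rng.choice(np.arange(2, 11), size=100_000, p=dist)
        analytic = (np.arange(2, 11) * dist).sum()
        se = sizes.std() / np.sqrt(sizes.size)
        assert abs(sizes.mean() - analytic) < 3 * se

    def test_calibration_solver_inverts_mean(self):
        trait = from_name("DD")
        target = 3.2
        r = calibrate_sibship_ratio(target, trait)
        assert ascertained_mean_sibship(r, trait) == pytest.approx(target,
                                                                   abs=1e-9)


class TestGeneDropping:
    def test_no_recombination_transmits_intact_haplotypes(self, rng):
        cfg = SimulationConfig.from_model("DD")
        founder = rng.integers(1, 3, (50, 2, 2, 18)).astype(np.int8)
        geno, bits = _drop_gametes(founder, 4, [0.0] * 17, rng)
        # each gamete must equal one intact parental haplotype
        assert (bits == bits[..., :1]).all()
        k, s = 5, 2
        hap = founder[k, 0, bits[k, s, 0, 0]]
        assert np.array_equal(geno[k, s, :, 0], hap)

    def test_empirical_recombination_fraction(self, rng):
        cfg = SimulationConfig.from_model("DD")
        founder = rng.integers(1, 3, (25_000, 2, 2, 18)).astype(np.int8)
        _, bits = _drop_gametes(founder, 1, cfg.gmap.theta, rng)
        rec = (bits[..., 1:] != bits[..., :-1]).astype(float)
        # 50k meioses per interval
        emp = rec.mean(axis=(0, 1, 2))
        for k, t in enumerate(cfg.gmap.theta):
            se = np.sqrt(max(t, 1e-4) * (1 - max(t, 1e-4)) / 50_000)
            assert abs(emp[k] - t) < 4 * se

    def test_founder_disease_frequency(self, rng):
        cfg = SimulationConfig.from_model("DD")
        founder, *_ = _simulate_size_batch(cfg, 2, 50_000, rng)
        freq = (founder[:, :, :, cfg.gmap.index_A] == 1).mean()
        se = np.sqrt(0.1 * 0.9 / (4 * 50_000))
        assert abs(freq - 0.1) < 3 * se

    def test_double_het_parents_offspring_affected_nine_sixteenths(self, rng):
        """Under DD epistasis with both parents AaBb, an offspring is
        affected with probability (3/4)*(3/4) = 9/16."""
        cfg = SimulationConfig.from_model("DD")
        gmap = cfg.gmap
        n = 40_000
        founder = np.where(rng.random((n, 2, 2, 18)) < 0.5, 1, 2).astype(np.int8)
        founder[:, :, 0, gmap.index_A] = 1
        founder[:, :, 1, gmap.index_A] = 2
        founder[:, :, 0, gmap.index_B] = 1
        founder[:, :, 1, gmap.index_B] = 2
        geno, _ = _drop_gametes(founder, 1, gmap.theta, rng)
        from linkstrat.simulator import _assign_affection

        _, off_aff = _assign_affection(cfg, founder, geno, rng)
        p = off_aff.mean()
        se = np.sqrt(9 / 16 * 7 / 16 / n)
        assert abs(p - 9 / 16) < 4 * se

    def test_mendelian_consistency_across_models(self, rng):
        for model in ("DD", "RR", "D+R"):
            cfg = SimulationConfig.from_model(model, families_per_dataset=20)
            ds = simulate_dataset(cfg, rng)
            assert all(mendelian_consistent(p) for p in ds)

    def test_ld_pair_sampled_jointly(self, rng):
        """At D' = 1 every founder haplotype carries the associated marker
        allele iff it carries the disease allele."""
        cfg = SimulationConfig.from_model("RR", d_prime=1.0)
        founder, *_ = _simulate_size_batch(cfg, 2, 20_000, rng)
        at_a = founder[:, :, :, cfg.gmap.index_A] == 1
        at_m = founder[:, :, :, cfg.gmap.index_ld_marker] == 1
        assert (at_a == at_m).all()


class TestAscertainment:
    def test_rule(self, small_map, rng):
        from conftest import random_nuclear_family

        ped = random_nuclear_family(rng, small_map, 2)
        for o in ped.offspring:
            o.affected = False
        assert not ascertain(ped)
        ped.offspring[0].affected = True
        assert ascertain(ped)
        trio = random_nuclear_family(rng, small_map, 1)
        trio.offspring[0].affected = True
        assert not ascertain(trio)

    def test_datasets_have_exact_size_and_affected_offspring(self, rng):
        cfg = SimulationConfig.from_model("RD", families_per_dataset=30)
        ds = simulate_dataset(cfg, rng)
        assert len(ds) == 30
        assert all(ascertain(p) for p in ds)
        assert all(2 <= len(p.offspring) <= 10 for p in ds)

    def test_analytic_ascertainment_probability_matches_simulation(self, rng):
        cfg = SimulationConfig.from_model("DD")
        for s in (2, 4):
            *_, off_aff = _simulate_size_batch(cfg, s, 60_000, rng)
            emp = off_aff.any(axis=1).mean()
            p = ascertainment_probability(cfg.trait, s)
            se = np.sqrt(p * (1 - p) / 60_000)
            assert abs(emp - p) < 4 * se

    def test_sampled_sibship_not_biased_by_batching(self, rng):
        """Truncating a rejection batch must not favour any sibship size:
        the ascertained size distribution matches the analytic one."""
        cfg = SimulationConfig.from_model("DD", families_per_dataset=50)
        sizes = []
        for _ in range(60):
            sizes += [len(p.offspring) for p in simulate_dataset(cfg, rng)]
        sizes = np.asarray(sizes)
        expected = ascertained_mean_sibship(DEFAULT_SIBSHIP_RATIO,
                                            cfg.trait)
        se = sizes.std() / np.sqrt(sizes.size)
        assert abs(sizes.mean() - expected) < 4 * se


class TestSeededReproducibility:
    def test_same_seed_same_datasets(self):
        cfg = SimulationConfig.from_model("DD", families_per_dataset=10,
                                          n_datasets=3)
        runs = []
        for _ in range(2):
            out = []
            for i, child_seed, ds in simulate_study(cfg, seed=42):
                out.append(
                    (i, child_seed,
                     [tuple(m.genotypes.ravel()) + (m.affected,)
                      for p in ds for m in p.members])
                )
            runs.append(out)
        assert runs[0] == runs[1]

    def test_sample_family_returns_unascertained_family(self, rng):
        cfg = SimulationConfig.from_model("DD")
        ped = sample_family(cfg, rng)
        assert 2 <= len(ped.offspring) <= 10
        assert len(ped.founders) == 2
        assert mendelian_consistent(ped)


class TestSegregationShift:
    def test_conditioning_on_locus_a_raises_affection_rate(self, rng):
        """The core mechanism: among ascertained families, offspring
        carrying the disease genotype at A are affected far more often
        than non-carriers (the apparent penetrance at B rises)."""
        cfg = SimulationConfig.from_model("DD", families_per_dataset=200)
        ds = simulate_dataset(cfg, rng)
        iA = cfg.gmap.index_A
        carrier_aff, noncarrier_aff = [], []
        for p in ds:
            for o in p.offspring:
                if (o.genotypes[iA] == 1).any():
                    carrier_aff.append(o.affected)
                else:
                    noncarrier_aff.append(o.affected)
        assert np.mean(carrier_aff) > 5 * max(np.mean(noncarrier_aff), 1e-9)
        assert np.mean(noncarrier_aff) == 0.0  # epistasis: non-carriers never affected
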