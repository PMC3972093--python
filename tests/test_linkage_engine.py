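import numpy as np
import pytest

from linkstrat.linkage_engine import (
    AnalysisModel,
    FamilyTooLargeError,
    MendelianError,
    b_interval_grid,
    elston_stewart_lod,
    elston_stewart_loglik,
    max_lod_in_interval,
    multipoint_lod,
)
from linkstrat.pedigree import GeneticMap, Locus, Pedigree, haldane_cm
from linkstrat.simulator import SimulationConfig, simulate_dataset

from conftest import (
    make_individual,
    random_nuclear_family,
    random_small_analysis,
    random_small_map,
)


class TestAnalysisModel:
    def test_penetrance_vectors(self):
        dom = AnalysisModel("dominant", 0.1, 0.5)
        rec = AnalysisModel("recessive", 0.2, 0.5)
        assert dom.penetrance_vector.tolist() == [0.0, 0.5, 0.5]
        assert rec.penetrance_vector.tolist() == [0.0, 0.0, 0.5]

    def test_matched_to_generating_model_at_B(self):
        from linkstrat.trait_models import from_name

        a = AnalysisModel.matched_to_B(from_name("RD"))
        assert (a.mode, a.disease_allele_freq, a.penetrance_carrier) == (
            "dominant", 0.1, 0.5,
        )


class TestOracleBasics:
    def test_single_founder_heterozygote_hardy_weinberg(self):
        """Marker-only likelihood of one observed heterozygous founder
        couple member is 2 p (1-p) per parent."""
        loci = (Locus("marker", (0.3, 0.7), "M1"),
                Locus("disease", (0.1, 0.9), "A"),
                Locus("disease", (0.2, 0.8), "B"),
                Locus("marker", (0.3, 0.7), "M2"))
        gmap = GeneticMap(loci, (0.1, 0.1, 0.1), 1, 2, 0)
        g_het = np.array([[1, 2], [0, 0], [0, 0], [0, 0]], dtype=np.int8)
        g_mis = np.zeros((4, 2), dtype=np.int8)
        ped = Pedigree(1, [
            make_individual(1, None, None, 1, False, g_het),
            make_individual(2, None, None, 2, False, g_mis),
        ])
        ll = elston_stewart_loglik(ped, gmap, include_phenotypes=False)
        assert 10**ll == pytest.approx(2 * 0.3 * 0.7)

    def test_mendelian_error_is_structured(self, small_map):
        fg = np.full((4, 2), 1, dtype=np.int8)
        cg = np.full((4, 2), 2, dtype=np.int8)
        ped = Pedigree(7, [
            make_individual(1, None, None, 1, False, fg),
            make_individual(2, None, None, 2, False, fg),
            make_individual(3, 1, 2, 1, False, cg),
        ])
        with pytest.raises(MendelianError, match="family 7"):
            elston_stewart_loglik(ped, small_map, include_phenotypes=False)
        analysis = AnalysisModel("dominant", 0.1, 0.5)
        with pytest.raises(MendelianError, match="family 7"):
            multipoint_lod([ped], small_map, analysis)

    def test_size_limits_refused(self, small_map, rng):
        ped = random_nuclear_family(rng, small_map, 5)
        with pytest.raises(FamilyTooLargeError):
            elston_stewart_loglik(ped, small_map, include_phenotypes=False)


class TestEngineAgainstOracle:
    def test_randomized_equivalence(self, rng):
        """HMM engine and brute-force enumeration agree to 1e-9 on random
        small pedigrees (the full 200-case suite runs in acceptance)."""
        for trial in range(25):
            gmap = random_small_map(rng, 2 if trial % 3 else 3)
            ped = random_nuclear_family(
                rng, gmap, int(rng.integers(2, 4)),
                duplicate_rate=0.5 if trial % 2 else 0.0,
            )
            analysis = random_small_analysis(rng)
            pos = float(rng.choice(b_interval_grid(gmap)))
            lod_e = multipoint_lod([ped], gmap, analysis, positions=[pos]).lod[0]
            lod_o = elston_stewart_lod(ped, gmap, analysis, pos)
            assert lod_e == pytest.approx(lod_o, abs=1e-9)

    def test_equivalence_with_free_recombination_gap(self, rng):
        """The engine skips markers across a theta=0.5 gap; the oracle does
        not -- they must still agree exactly."""
        loci = (Locus("marker", (0.4, 0.6), "M1"),
                Locus("disease", (0.15, 0.85), "A"),
                Locus("marker", (0.5, 0.5), "M2"),
                Locus("disease", (0.2, 0.8), "B"),
                Locus("marker", (0.3, 0.7), "M3"))
        gmap = GeneticMap(loci, (0.2, 0.5, 0.01, 0.05), 1, 3, 0)
        analysis = AnalysisModel("recessive", 0.2, 0.5)
        for _ in range(8):
            ped = random_nuclear_family(rng, gmap, 3)
            for pos in b_interval_grid(gmap)[::4]:
                lod_e = multipoint_lod([ped], gmap, analysis,
                                       positions=[pos]).lod[0]
                assert lod_e == pytest.approx(
                    elston_stewart_lod(ped, gmap, analysis, float(pos)),
                    abs=1e-9,
                )


class TestLodProperties:
    def test_all_missing_genotypes_give_zero_lod(self, small_map, rng):
        ped = random_nuclear_family(rng, small_map, 3, missing_rate=0.0)
        for m in ped.members:
            m.genotypes = np.zeros_like(m.genotypes)
        analysis = AnalysisModel("dominant", 0.1, 0.5)
        curve = multipoint_lod([ped], small_map, analysis)
        assert curve.lod == pytest.approx(np.zeros_like(curve.lod), abs=1e-12)

    def test_dataset_lod_is_sum_of_family_lods(self, rng):
        cfg = SimulationConfig.from_model("DD", families_per_dataset=8)
        ds = simulate_dataset(cfg, rng)
        analysis = AnalysisModel.matched_to_B(cfg.trait)
        curve = multipoint_lod(ds, cfg.gmap, analysis, keep_per_family=True)
        assert curve.per_family.sum(axis=0) == pytest.approx(curve.lod)
        singles = [
            multipoint_lod([p], cfg.gmap, analysis).lod for p in ds
        ]
        assert np.sum(singles, axis=0) == pytest.approx(curve.lod)

    def test_offspring_order_irrelevant(self, rng):
        cfg = SimulationConfig.from_model("RR", families_per_dataset=4)
        ds = simulate_dataset(cfg, rng)
        analysis = AnalysisModel.matched_to_B(cfg.trait)
        base = multipoint_lod(ds, cfg.gmap, analysis).lod
        for p in ds:
            off = p.offspring
            p.members = p.founders + off[::-1]
        flipped = multipoint_lod(ds, cfg.gmap, analysis).lod
        assert flipped == pytest.approx(base, abs=1e-9)

    def test_null_lod_nonpositive_on_average(self, rng):
        """Phenotypes independent of all markers: the expected lod at the
        test position is <= 0 (likelihood-ratio property)."""
        cfg = SimulationConfig.from_model("DD", families_per_dataset=5)
        analysis = AnalysisModel("dominant", 0.1, 0.5)
        tot = 0.0
        n = 60
        for k in range(n):
            local = np.random.default_rng(1000 + k)
            ds = simulate_dataset(cfg, local)
            for p in ds:  # shuffle affection across members: null linkage
                aff = [m.affected for m in p.members]
                local.shuffle(aff)
                for m, a in zip(p.members, aff):
                    m.affected = bool(a)
            tot += multipoint_lod(ds, cfg.gmap, analysis).lod.max()
        assert tot / n < 0.05

    def test_phase_unknown_affected_sibs_closed_form(self):
        """Fully penetrant dominant disease at theta=0 from an informative
        marker: n affected sibs sharing the paternal allele give a lod
        approaching (n-1) log10(2) as the disease allele becomes rare."""
        for n_off in (2, 3, 4):
            loci = (Locus("marker", (0.5, 0.5), "M1"),
                    Locus("disease", (0.001, 0.999), "A"),
                    Locus("disease", (0.001, 0.999), "B"),
                    Locus("marker", (0.5, 0.5), "M2"))
            # B rides at theta ~0 with marker M2
            gmap = GeneticMap(loci, (0.3, 0.3, 1e-9), 1, 2, 0)
            L = 4
            fg = np.array([[0, 0], [0, 0], [1, 2], [1, 2]], dtype=np.int8).reshape(L, 2)
            mg = np.array([[0, 0], [0, 0], [2, 2], [2, 2]], dtype=np.int8).reshape(L, 2)
            members = [
                make_individual(1, None, None, 1, True, fg),
                make_individual(2, None, None, 2, False, mg),
            ]
            cg = np.array([[0, 0], [0, 0], [1, 2], [1, 2]], dtype=np.int8)
            for j in range(n_off):
                members.append(make_individual(3 + j, 1, 2, 1, True, cg.copy()))
            ped = Pedigree(1, members)
            analysis = AnalysisModel("dominant", 0.001, 1.0)
            pos = gmap.positions()[gmap.index_B]
            lod = multipoint_lod([ped], gmap, analysis, positions=[pos]).lod[0]
            expected = (n_off - 1) * np.log10(2)
            assert lod == pytest.approx(expected, abs=0.02)
            # and the value is exactly what the enumeration oracle gives
            assert lod == pytest.approx(
                elston_stewart_lod(ped, gmap, analysis, float(pos)), abs=1e-9
            )


class TestIntervalMax:
    def test_grid_covers_flanks_and_B(self):
        cfg = SimulationConfig.from_model("DD")
        grid = b_interval_grid(cfg.gmap)
        pos = cfg.gmap.positions()
        assert grid[0] == pytest.approx(pos[11])
        assert grid[-1] == pytest.approx(pos[13])
        assert np.any(np.isclose(grid, pos[cfg.gmap.index_B]))
        assert len(grid) == 11

    def test_max_lod_returns_peak_position(self):
        from linkstrat.linkage_engine import LodCurve

        curve = LodCurve(np.array([0.0, 1.0, 2.0]), np.array([1.0, 3.0, 2.0]))
        assert max_lod_in_interval(curve) == (1.0, 3.0)
        curve2 = LodCurve(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        assert max_lod_in_interval(curve2) == (1.0, 2.0)  # monotone: endpoint
        with pytest.raises(ValueError, match="no evaluated positions"):
            max_lod_in_interval(curve, lo=5.0)
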