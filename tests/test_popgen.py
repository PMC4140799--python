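import numpy as np
import pytest

from antpolyandry.genotypes import Locus, ParentSet, frequencies_from_counts
from antpolyandry.inference import assign_patrilines, filter_workers
from antpolyandry.popgen import (
    expected_heterozygosity,
    fst_weir_cockerham,
    inbreeding_coefficient,
    mate_pairs,
    observed_heterozygosity,
    qg_relatedness,
    queen_mate_pairs,
    worker_pairs,
)
from antpolyandry.simulate import SimulationConfig, simulate_colony, \
    simulate_frequencies

from conftest import draw_diploids


def diploids_from_freqs(freqs, n, rng):
    return [tuple(ind) for ind in draw_diploids(freqs, n, rng)]


class TestHeterozygosities:
    def test_observed_all_heterozygous_is_one(self, sim_colony_with_truth):
        colony, truth, _ = sim_colony_with_truth
        kept, _ = filter_workers(colony)
        part = assign_patrilines(kept, truth.queen)
        ho = observed_heterozygosity(kept, part, seed=0)
        assert all(0 <= v <= 1 for v in ho.per_locus.values())

    def test_observed_matches_generating_diversity(self):
        """Sampling one worker per patriline, H_O tracks the expected
        heterozygosity of the generating frequencies."""
        vals, expected = [], []
        for rep in range(10):
            cfg = SimulationConfig(n_loci=10, alleles_per_locus=10,
                                   freq_concentration=5.0, k_mates=20,
                                   n_workers=120, missing_rate=0.0,
                                   seed=60 + rep)
            freqs, subs = simulate_frequencies(cfg, n_subpops=1)
            colony, truth = simulate_colony(subs[0], cfg, seed=80 + rep)
            part = assign_patrilines(colony, truth.queen)
            ho = observed_heterozygosity(colony, part, seed=rep)
            vals.append(ho.value)
            expected.append(np.mean([1 - freqs.homozygosity(l)
                                     for l in freqs.loci]))
        assert np.mean(vals) == pytest.approx(np.mean(expected), abs=0.05)

    def test_observed_seeded_subsample_reproducible(self, sim_colony_with_truth):
        colony, truth, _ = sim_colony_with_truth
        kept, _ = filter_workers(colony)
        part = assign_patrilines(kept, truth.queen)
        a = observed_heterozygosity(kept, part, seed=5)
        b = observed_heterozygosity(kept, part, seed=5)
        assert a.per_locus == b.per_locus

    def test_expected_heterozygosity_formulas(self):
        panel = [Locus("L1"), Locus("L2")]
        # L1: two alleles at 0.5 each over many parents; L2 monomorphic
        males = [(100, 300) if i % 2 else (102, 300) for i in range(40)]
        parents = [ParentSet("c", panel, queen=((100, 102), (300, 300)),
                             males=males)]
        hs = expected_heterozygosity(parents)
        n_copies = 2 + 40  # queen (2 copies) + haploid males, gene_copy
        corr = n_copies / (n_copies - 1)
        assert hs.per_locus["L1"] == pytest.approx(corr * 0.5, rel=1e-6)
        assert hs.per_locus["L2"] == 0.0


class TestInbreedingCoefficient:
    def test_equal_heterozygosities_give_zero(self):
        from antpolyandry.popgen import PopGenSummary
        h = PopGenSummary("H", 0.7, {"L1": 0.7, "L2": 0.6}, None, None, None, None)
        fis = inbreeding_coefficient(h, h)
        assert fis.value == pytest.approx(0.0)

    def test_ratio_arithmetic(self):
        from antpolyandry.popgen import PopGenSummary
        ho = PopGenSummary("H_O", 0.67, {"L1": 0.67}, None, None, None, None)
        hs = PopGenSummary("H_S", 0.70, {"L1": 0.70}, None, None, None, None)
        fis = inbreeding_coefficient(ho, hs)
        assert fis.value == pytest.approx(1 - 0.67 / 0.70)

    def test_outbred_population_near_zero(self):
        """Simulated panmictic parents: mean F_IS over replicates ~ 0."""
        vals = []
        for rep in range(25):
            cfg = SimulationConfig(n_loci=8, alleles_per_locus=8,
                                   k_mates=15, n_workers=60,
                                   missing_rate=0.0, seed=700 + rep)
            freqs, subs = simulate_frequencies(cfg, n_subpops=1)
            colony, truth = simulate_colony(subs[0], cfg, seed=800 + rep)
            part = assign_patrilines(colony, truth.queen)
            ho = observed_heterozygosity(colony, part, seed=rep)
            parents = [truth.parents(colony.colony_id, colony.panel)]
            hs = expected_heterozygosity(parents)
            fis = inbreeding_coefficient(ho, hs)
            vals.append(fis.value)
        assert np.mean(vals) == pytest.approx(0.0, abs=0.03)


class TestFst:
    def test_no_differentiation_near_zero(self):
        cfg = SimulationConfig(n_loci=10, alleles_per_locus=8, seed=1)
        freqs, _ = simulate_frequencies(cfg, n_subpops=1)
        rng = np.random.default_rng(2)
        pops = [diploids_from_freqs(freqs, 100, rng) for _ in range(4)]
        fst = fst_weir_cockerham(pops, freqs.loci)
        assert abs(fst.value) < 0.01

    def test_fixed_differences_give_one(self):
        loci = ["L1", "L2"]
        pop1 = [((1, 1), (1, 1))] * 20
        pop2 = [((2, 2), (2, 2))] * 20
        fst = fst_weir_cockerham([pop1, pop2], loci)
        assert fst.value == pytest.approx(1.0)

    def test_monomorphic_dataset_rejected(self):
        pop = [((1, 1),)] * 10
        with pytest.raises(ValueError):
            fst_weir_cockerham([pop, pop], ["L1"])

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        cfg = SimulationConfig(n_loci=5, alleles_per_locus=4,
                               divergence=0.1, seed=4)
        _, subs = simulate_frequencies(cfg, n_subpops=3)
        pops = [diploids_from_freqs(s, 40, rng) for s in subs]
        base = fst_weir_cockerham(pops, subs[0].loci).value
        relabeled = [
            [tuple(tuple(a + 1000 for a in g) for g in ind) for ind in pop]
            for pop in pops
        ]
        assert fst_weir_cockerham(relabeled, subs[0].loci).value == \
            pytest.approx(base)

    def test_balding_nichols_recovery(self):
        """theta = 0.05 Balding-Nichols populations recover ~0.05."""
        ests = []
        for rep in range(15):
            cfg = SimulationConfig(n_loci=10, alleles_per_locus=8,
                                   divergence=0.05, seed=900 + rep)
            _, subs = simulate_frequencies(cfg, n_subpops=20)
            rng = np.random.default_rng(950 + rep)
            pops = [diploids_from_freqs(s, 30, rng) for s in subs]
            ests.append(fst_weir_cockerham(pops, subs[0].loci).value)
        assert np.mean(ests) == pytest.approx(0.05, abs=0.02)


class TestRelatedness:
    def test_self_relatedness_is_one(self):
        freqs = frequencies_from_counts(
            {"L1": {1: 3, 2: 5, 3: 2}, "L2": {1: 4, 2: 6}})
        ind = ((1, 2), (1, 1))
        r = qg_relatedness([(ind, ind)], freqs, freqs.loci)
        assert r.value == pytest.approx(1.0)

    def test_unrelated_diploids_average_zero(self):
        cfg = SimulationConfig(n_loci=10, alleles_per_locus=8, seed=6)
        freqs, _ = simulate_frequencies(cfg, n_subpops=1)
        rng = np.random.default_rng(7)
        inds = diploids_from_freqs(freqs, 400, rng)
        pairs = [(inds[2 * i], inds[2 * i + 1]) for i in range(200)]
        # 200 independent pairs; the ratio-of-sums estimator is near 0
        r = qg_relatedness(pairs, freqs, freqs.loci)
        assert r.value == pytest.approx(0.0, abs=0.05)

    def test_full_sisters_of_monandrous_queen(self):
        """Workers of a singly-mated queen are super-sisters: r_ww = 0.75."""
        vals = []
        for rep in range(5):
            cfg = SimulationConfig(n_loci=10, alleles_per_locus=8, k_mates=1,
                                   n_workers=50, missing_rate=0.0,
                                   seed=30 + rep)
            freqs, subs = simulate_frequencies(cfg, n_subpops=1)
            colony, _ = simulate_colony(subs[0], cfg, seed=40 + rep)
            r = qg_relatedness(worker_pairs(colony, max_pairs=500, seed=rep),
                               freqs, freqs.loci)
            vals.append(r.value)
        assert np.mean(vals) == pytest.approx(0.75, abs=0.03)

    def test_queen_mate_and_mate_mate_near_zero(self):
        cfg = SimulationConfig(n_loci=10, alleles_per_locus=8, k_mates=20,
                               seed=50)
        freqs, subs = simulate_frequencies(cfg, n_subpops=1)
        vals_qm, vals_mm = [], []
        for rep in range(10):
            _, truth = simulate_colony(subs[0], cfg, seed=60 + rep)
            parents = truth.parents("c", _panel_of(freqs))
            vals_qm.append(qg_relatedness(queen_mate_pairs(parents), freqs,
                                          freqs.loci).value)
            vals_mm.append(qg_relatedness(mate_pairs(parents), freqs,
                                          freqs.loci).value)
        assert np.mean(vals_qm) == pytest.approx(0.0, abs=0.05)
        assert np.mean(vals_mm) == pytest.approx(0.0, abs=0.05)

    def test_jackknife_se_reported_with_multiple_loci(self):
        freqs = frequencies_from_counts(
            {"L1": {1: 3, 2: 5}, "L2": {1: 4, 2: 6}, "L3": {1: 1, 2: 1}})
        x = ((1, 2), (1, 2), (1, 1))
        y = ((1, 1), (2, 2), (1, 2))
        r = qg_relatedness([(x, y)], freqs, freqs.loci)
        assert r.se is not None and r.se >= 0


def _panel_of(freqs):
    return [Locus(name) for name in freqs.loci]
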