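import numpy as np
import pytest

from antpolyandry.genotypes import ColonySample, Locus
from antpolyandry.simulate import (
    SimulationConfig,
    simulate_colony,
    simulate_frequencies,
)


@pytest.fixture
def toy_panel():
    return [Locus("Lp2"), Locus("Lp4"), Locus("Eb06")]


@pytest.fixture
def toy_colony(toy_panel):
    """Four workers of a queen 100/102, 104/104, 200/202; two fathers."""
    workers = [
        ((100, 110), (104, 106), (200, 204)),   # father A: 110,106,204
        ((102, 110), (104, 106), (202, 204)),
        ((100, 112), (104, 108), (200, 206)),   # father B: 112,108,206
        ((102, 112), (104, 108), (202, 206)),
    ]
    return ColonySample(
        colony_id="toy1", species_id="toy", location="lab",
        panel=toy_panel, workers=workers,
    )


@pytest.fixture
def sim_colony_with_truth():
    """A mid-size simulated colony (10 loci, 12 patrilines, 100 workers)."""
    cfg = SimulationConfig(n_loci=10, alleles_per_locus=8, k_mates=12,
                           n_workers=100, missing_rate=0.02, seed=11)
    global_freqs, subs = simulate_frequencies(cfg, n_subpops=1)
    colony, truth = simulate_colony(subs[0], cfg, seed=12)
    return colony, truth, global_freqs


def draw_diploids(freqs, n, rng):
    """Unrelated diploid individuals from an allele frequency table."""
    inds = []
    for _ in range(n):
        ind = []
        for locus in freqs.loci:
            alleles = sorted(freqs.freqs[locus])
            p = np.array([freqs.freqs[locus][a] for a in alleles])
            ind.append(tuple(sorted(rng.choice(alleles, 2, p=p / p.sum()))))
        inds.append(tuple(ind))
    return inds
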