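"""Synthetic colonies with known ground truth.

Emulates the mating system of a monogyne, highly polyandrous ant: a
single diploid queen mates with ``k_mates`` haploid males, paternity
shares follow a symmetric Dirichlet (the concentration is the one knob
moving from near-even to strongly skewed paternity), and each sampled
worker inherits one random queen allele plus its father's allele per
locus.  Population substructure follows the Balding–Nichols
construction, so the divergence parameter theta maps directly onto the
expected Weir–Cockerham F_ST and estimator-recovery tests are
quantitative.

Every simulation routine takes an explicit seed and is deterministic;
per-colony streams are split from the master seed so adding colonies
never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genotypes import (
    AlleleFrequencyTable,
    ColonySample,
    DiploidGenotype,
    Haplotype,
    Locus,
    ParentSet,
)

__all__ = [
    "SimulationConfig",
    "ColonyTruth",
    "simulate_frequencies",
    "simulate_colony",
    "simulate_colony_set",
    "simulate_species_set",
    "simulate_skew_gradient",
    "DEFAULT_K_GRID",
    "DEFAULT_NINE_SPECIES_NEWICK",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the colony generator.

    Defaults mirror a mid-range genotyped colony: a 10-locus panel with
    8 alleles per locus, ~100 sampled workers and ~18 patrilines, a few
    percent missing genotypes, and mild paternity skew.
    """

    n_loci: int = 10
    alleles_per_locus: int = 8
    freq_concentration: float = 1.0
    k_mates: int = 18
    paternity_concentration: float = 5.0
    n_workers: int = 100
    missing_rate: float = 0.02
    n_colonies: int = 3
    divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_loci, self.alleles_per_locus, self.k_mates,
               self.n_workers, self.n_colonies) < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence theta must be in [0, 1)")
        if self.paternity_concentration <= 0:
            raise ValueError("paternity_concentration must be > 0")
        if self.freq_concentration <= 0:
            raise ValueError("freq_concentration must be > 0")


@dataclass
class ColonyTruth:
    """Ground truth behind one simulated colony."""

    queen: DiploidGenotype
    males: list[Haplotype]
    paternity: np.ndarray          # true proportions p_i, sum 1
    assignment: np.ndarray         # worker -> father index
    patriline_counts: np.ndarray   # realized worker counts per father

    def parents(self, colony_id: str, panel: list[Locus]) -> ParentSet:
        return ParentSet(colony_id=colony_id, panel=panel,
                         queen=self.queen, males=list(self.males))


def _panel(config: SimulationConfig) -> list[Locus]:
    # allele lengths spaced by 2 bp from 100, per locus offset by 50
    return [
        Locus(
            f"L{i + 1}",
            frozenset(100 + 50 * i + 2 * j for j in range(config.alleles_per_locus)),
        )
        for i in range(config.n_loci)
    ]


def _freq_table(panel: list[Locus], probs: np.ndarray) -> AlleleFrequencyTable:
    loci = [l.name for l in panel]
    freqs = {}
    counts = {}
    for i, locus in enumerate(panel):
        alleles = sorted(locus.alleles)
        p = probs[i] / probs[i].sum()
        freqs[locus.name] = {a: float(pv) for a, pv in zip(alleles, p)}
        counts[locus.name] = dict(freqs[locus.name])
    return AlleleFrequencyTable(loci=loci, counts=counts, freqs=freqs)


def simulate_frequencies(
    config: SimulationConfig, n_subpops: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[AlleleFrequencyTable, list[AlleleFrequencyTable]]:
    """Global and per-subpopulation allele frequency tables.

    Global per-locus frequencies are symmetric-Dirichlet draws; each
    subpopulation draws from Dirichlet(p_global * (1 - theta)/theta)
    (Balding–Nichols), so the expected differentiation among
    subpopulations is approximately theta.  theta = 0 returns identical
    copies of the global table.
    """
    n_subpops = config.n_colonies if n_subpops is None else n_subpops
    rng = np.random.default_rng(config.seed) if rng is None else rng
    panel = _panel(config)
    A = config.alleles_per_locus
    global_probs = rng.dirichlet(np.full(A, config.freq_concentration),
                                 size=config.n_loci)
    theta = config.divergence
    sub_tables = []
    if theta == 0.0:
        sub_probs = [global_probs.copy() for _ in range(n_subpops)]
    else:
        c = (1.0 - theta) / theta
        sub_probs = []
        for _ in range(n_subpops):
            probs = np.empty_like(global_probs)
            for i in range(config.n_loci):
                probs[i] = rng.dirichlet(np.maximum(global_probs[i] * c, 1e-12))
            sub_probs.append(probs)
    for probs in sub_probs:
        sub_tables.append(_freq_table(panel, probs))
    return _freq_table(panel, global_probs), sub_tables


def _draw_haplotype(freqs: AlleleFrequencyTable, panel: list[Locus],
                    rng: np.random.Generator) -> Haplotype:
    out = []
    for locus in panel:
        alleles = sorted(freqs.freqs[locus.name])
        p = np.array([freqs.freqs[locus.name][a] for a in alleles])
        out.append(int(rng.choice(alleles, p=p / p.sum())))
    return tuple(out)


def simulate_colony(
    freqs: AlleleFrequencyTable,
    config: SimulationConfig,
    seed: int,
    colony_id: str = "sim1",
    species_id: str = "sim",
    panel: Optional[list[Locus]] = None,
) -> tuple[ColonySample, ColonyTruth]:
    """One colony: queen + k haploid mates + multinomial worker sample."""
    rng = np.random.default_rng(seed)
    panel = _panel(config) if panel is None else panel
    queen_a = _draw_haplotype(freqs, panel, rng)
    queen_b = _draw_haplotype(freqs, panel, rng)
    queen: DiploidGenotype = tuple(
        (min(a, b), max(a, b)) for a, b in zip(queen_a, queen_b)
    )
    males = [_draw_haplotype(freqs, panel, rng) for _ in range(config.k_mates)]
    p = rng.dirichlet(np.full(config.k_mates, config.paternity_concentration))
    assignment = rng.choice(config.k_mates, size=config.n_workers, p=p)
    counts = np.bincount(assignment, minlength=config.k_mates)

    workers: list[DiploidGenotype] = []
    for w in range(config.n_workers):
        father = males[assignment[w]]
        geno = []
        for loc in range(len(panel)):
            maternal = queen[loc][rng.integers(2)]
            pair = (maternal, father[loc])
            geno.append((min(pair), max(pair)))
        workers.append(tuple(geno))
    if config.missing_rate > 0:
        mask = rng.random((config.n_workers, len(panel))) < config.missing_rate
        workers = [
            tuple(None if mask[w, loc] else workers[w][loc]
                  for loc in range(len(panel)))
            for w in range(config.n_workers)
        ]
    sample = ColonySample(
        colony_id=colony_id, species_id=species_id, location="sim",
        panel=panel, workers=workers,
    )
    truth = ColonyTruth(
        queen=queen, males=males, paternity=p,
        assignment=assignment, patriline_counts=counts,
    )
    return sample, truth


def simulate_colony_set(
    config: SimulationConfig,
) -> tuple[list[ColonySample], list[ColonyTruth], AlleleFrequencyTable]:
    """Simulate ``n_colonies`` colonies, one subpopulation each.

    Colony seeds are split from the master seed with a seed sequence, so
    increasing ``n_colonies`` reproduces earlier colonies exactly.
    """
    master = np.random.SeedSequence(config.seed)
    freq_seed, *colony_seeds = master.spawn(config.n_colonies + 1)
    global_freqs, sub_freqs = simulate_frequencies(
        config, rng=np.random.default_rng(freq_seed)
    )
    samples, truths = [], []
    for i in range(config.n_colonies):
        seed = int(colony_seeds[i].generate_state(1)[0] % (2**31))
        s, t = simulate_colony(
            sub_freqs[i], config, seed=seed, colony_id=f"sim{i + 1}",
        )
        samples.append(s)
        truths.append(t)
    return samples, truths, global_freqs


# ---------------------------------------------------------------------------
# Cross-species comparative fixtures
# ---------------------------------------------------------------------------

# default 9-species grid spanning the observed patriline range (5-26)
DEFAULT_K_GRID = (5, 7, 9, 12, 14, 16, 18, 22, 26)
DEFAULT_NINE_SPECIES_NEWICK = (
    "((((sp0:1,sp1:1):1,(sp2:1,sp3:1):1):1,((sp4:1,sp5:1):1,sp6:2):1):1,"
    "(sp7:2,sp8:2):2);"
)


def simulate_skew_gradient(
    seed: int,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    alpha_scale: float = 0.05,
    n_colonies: int = 3,
    n_workers: int = 100,
):
    """Paternity counts for a species set where queens equalize paternity
    increasingly with mate number.

    Each species mates with k males and allocates paternity by a
    symmetric Dirichlet with concentration alpha_scale * k^2, so skew
    declines steeply with k (the equalization mechanism); per species,
    ``n_colonies`` colonies of ``n_workers`` workers are multinomially
    sampled.  Returns {species: [counts per colony]} with zero-count
    patrilines dropped (they are unobserved); species labels are
    ``sp0``..  and match ``DEFAULT_NINE_SPECIES_NEWICK`` tips when the
    default grid is used.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[np.ndarray]] = {}
    for i, k in enumerate(k_grid):
        alpha = alpha_scale * k * k
        colonies = []
        for _ in range(n_colonies):
            p = rng.dirichlet(np.full(k, alpha))
            counts = rng.multinomial(n_workers, p)
            colonies.append(counts[counts > 0])
        out[f"sp{i}"] = colonies
    return out


# ---------------------------------------------------------------------------
# Brownian-motion traits on a phylogeny
# ---------------------------------------------------------------------------


def simulate_species_set(
    tree,
    slope: float,
    intercept: float,
    noise_var: float,
    seed: int,
    x_var: float = 1.0,
    x_root: float = 0.0,
):
    """Brownian predictor plus linear response on a phylogeny.

    ``tree`` is an ``antpolyandry.comparative.PhyloTree``.  The
    predictor evolves by Brownian motion with rate ``x_var``; the
    response is intercept + slope * x + eps, eps ~ MVN(0, noise_var * V)
    with V the Brownian covariance of the tree.  Returns a pandas
    DataFrame with columns species, x, y.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    V = tree.covariance_matrix()
    tips = tree.tip_labels
    n = len(tips)
    if n < 3:
        raise ValueError("need at least 3 tips")
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    x = x_root + np.sqrt(x_var) * (L @ rng.standard_normal(n))
    eps = (np.sqrt(noise_var) * (L @ rng.standard_normal(n))
           if noise_var > 0 else np.zeros(n))
    y = intercept + slope * x + eps
    return pd.DataFrame({"species": tips, "x": x, "y": y})
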