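"""Heterozygosities, F-statistics and regression relatedness.

Population structure of a polyandrous ant population is summarized by
Nei's observed and expected heterozygosities (H_O from one randomly
chosen worker per patriline to dampen the family structure of the
sample, H_S from the deduced parents), the inbreeding coefficient
F_IS = 1 - H_O/H_S, Weir–Cockerham theta (F_ST) treating colonies as
subpopulations, and Queller–Goodnight regression relatedness among
workers (r_ww), between queens and their mates (r_qm) and among mates
(r_mm).  Uncertainty throughout is the delete-one-locus jackknife, and
tests follow the single-sample t convention with df = loci - 1.

Haploid males enter allele counts as single gene copies by default; the
homozygote-diploid convention used by legacy diploid software is
available as a reproduction flag where relevant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .genotypes import AlleleFrequencyTable, ColonySample, ParentSet
from .inference import PaternityPartition

__all__ = [
    "PopGenSummary",
    "RelatednessSummary",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "inbreeding_coefficient",
    "fst_weir_cockerham",
    "qg_pairwise",
    "qg_relatedness",
    "worker_pairs",
    "queen_mate_pairs",
    "mate_pairs",
]

# An individual, for relatedness/F_ST purposes, is a tuple over loci of
# allele tuples: (a, b) for diploids, (a,) for haploid males, None missing.
Individual = tuple[Optional[tuple[int, ...]], ...]


@dataclass
class PopGenSummary:
    """A statistic with per-locus values, jackknife SE and a t-test."""

    statistic: str
    value: float
    per_locus: dict[str, float]
    se: Optional[float]
    t: Optional[float]
    df: Optional[int]
    p: Optional[float]
    one_tailed: bool = False


@dataclass
class RelatednessSummary:
    """Queller–Goodnight relatedness for one pair class."""

    pair_class: str
    value: float
    se: Optional[float]
    n_pairs: int
    per_locus_num: dict[str, float] = field(repr=False, default_factory=dict)
    per_locus_den: dict[str, float] = field(repr=False, default_factory=dict)

    def t_test(self, reference: float = 0.0, one_tailed: bool = False
               ) -> tuple[Optional[float], Optional[int], Optional[float]]:
        """Single-sample t of the jackknife pseudovalue mean vs a reference."""
        if self.se is None or self.se == 0:
            return None, None, None
        df = len(self.per_locus_num) - 1
        t = (self.value - reference) / self.se
        if one_tailed:
            p = float(stats.t.sf(t, df))
        else:
            p = float(2.0 * stats.t.sf(abs(t), df))
        return float(t), df, p


def _jackknife_ratio(nums: np.ndarray, dens: np.ndarray
                     ) -> tuple[float, Optional[float]]:
    """Ratio-of-sums estimate with delete-one-locus jackknife SE."""
    total = nums.sum() / dens.sum()
    L = nums.size
    if L < 2:
        return float(total), None
    loo = (nums.sum() - nums) / (dens.sum() - dens)
    se = np.sqrt((L - 1) / L * np.sum((loo - loo.mean()) ** 2))
    return float(total), float(se)


# ---------------------------------------------------------------------------
# Heterozygosities and F_IS
# ---------------------------------------------------------------------------


def observed_heterozygosity(
    colony: ColonySample,
    partition: PaternityPartition,
    seed: int = 0,
    n_redraws: int = 1,
) -> PopGenSummary:
    """Observed heterozygosity from one random worker per patriline.

    Sampling one worker per patriline removes most of the family
    structure of a colony sample (full sisters share the paternal
    allele).  With ``n_redraws`` > 1 the per-locus values are averaged
    over independent redraws.
    """
    rng = np.random.default_rng(seed)
    members: dict[int, list[int]] = {}
    for w, g in partition.assignment.items():
        members.setdefault(g, []).append(w)
    locus_names = [l.name for l in colony.panel]
    acc = {name: [] for name in locus_names}
    for _ in range(max(1, n_redraws)):
        chosen = [members[g][rng.integers(len(members[g]))] for g in sorted(members)]
        for i, name in enumerate(locus_names):
            genos = [colony.workers[w][i] for w in chosen]
            genos = [g for g in genos if g is not None]
            if not genos:
                continue
            het = sum(a != b for a, b in genos) / len(genos)
            acc[name].append(het)
    per_locus = {}
    for name in locus_names:
        if acc[name]:
            per_locus[name] = float(np.mean(acc[name]))
        else:
            warnings.warn(f"locus {name}: untyped in all sampled workers, dropped")
    values = np.array(list(per_locus.values()))
    return PopGenSummary(
        statistic="H_O",
        value=float(values.mean()),
        per_locus=per_locus,
        se=None, t=None, df=None, p=None,
    )


def expected_heterozygosity(
    parents: Sequence[ParentSet], weighting: str = "gene_copy"
) -> PopGenSummary:
    """Nei's unbiased expected heterozygosity from the deduced parents.

    Per locus, H_S = (2N/(2N-1)) * (1 - sum p_a^2) with N the
    diploid-equivalent number of gene copies under the chosen
    weighting; monomorphic loci give 0.
    """
    from .genotypes import allele_frequencies

    table = allele_frequencies(parents, weighting=weighting)
    per_locus = {}
    for locus in table.loci:
        copies = sum(table.counts[locus].values())
        n_dip = copies / 2.0
        if copies < 2:
            per_locus[locus] = 0.0
            continue
        gd = 1.0 - table.homozygosity(locus)
        per_locus[locus] = (2.0 * n_dip / (2.0 * n_dip - 1.0)) * gd
    values = np.array(list(per_locus.values()))
    return PopGenSummary(
        statistic="H_S",
        value=float(values.mean()),
        per_locus=per_locus,
        se=None, t=None, df=None, p=None,
    )


def inbreeding_coefficient(
    h_obs: PopGenSummary, h_exp: PopGenSummary
) -> PopGenSummary:
    """F_IS = 1 - H_O/H_S per locus, averaged with jackknife SE and t-test.

    Loci monomorphic in the parents (H_S = 0) are omitted.  The summary
    value is the mean of per-locus F_IS (see the ratio-of-means
    alternative in the docs); the t-test is two-sided against zero.
    """
    per_locus = {}
    for locus, hs in h_exp.per_locus.items():
        if hs <= 0 or locus not in h_obs.per_locus:
            continue
        per_locus[locus] = 1.0 - h_obs.per_locus[locus] / hs
    if not per_locus:
        raise ValueError("no polymorphic loci shared between H_O and H_S")
    values = np.array(list(per_locus.values()))
    L = values.size
    if L >= 2:
        se = float(values.std(ddof=1) / np.sqrt(L))
        t = float(values.mean() / se) if se > 0 else None
        p = float(2.0 * stats.t.sf(abs(t), L - 1)) if t is not None else None
    else:
        se = t = p = None
    return PopGenSummary(
        statistic="F_IS",
        value=float(values.mean()),
        per_locus=per_locus,
        se=se, t=t, df=L - 1 if L >= 2 else None, p=p,
    )


# ---------------------------------------------------------------------------
# Weir–Cockerham theta (F_ST)
# ---------------------------------------------------------------------------


def _wc_components(pop_genotypes: list[list[tuple[int, ...]]]
                   ) -> tuple[float, float]:
    """Weir–Cockerham variance components (a, a+b+c) for one locus.

    ``pop_genotypes``: per population, the typed individuals as allele
    tuples — (a, b) diploid or (a,) haploid.  Haploids contribute one
    gene copy and no heterozygosity term; sample sizes enter as
    diploid-equivalents (gene copies / 2).
    """
    r = len(pop_genotypes)
    copies = np.array([sum(len(g) for g in pop) for pop in pop_genotypes],
                      dtype=float)
    if np.any(copies <= 0) or r < 2:
        return 0.0, 0.0
    n = copies / 2.0  # diploid-equivalent sample sizes
    alleles = sorted({a for pop in pop_genotypes for g in pop for a in g})
    if len(alleles) < 2:
        return 0.0, 0.0
    nbar = n.mean()
    nc = (r * nbar - np.sum(n ** 2) / (r * nbar)) / (r - 1.0)
    a_sum = 0.0
    abc_sum = 0.0
    for allele in alleles:
        p_i = np.array([
            sum(g.count(allele) for g in pop) / c
            for pop, c in zip(pop_genotypes, copies)
        ])
        h_i = np.array([
            sum(1 for g in pop if len(g) == 2 and g[0] != g[1] and allele in g) / ni
            for pop, ni in zip(pop_genotypes, n)
        ])
        pbar = np.sum(n * p_i) / (r * nbar)
        s2 = np.sum(n * (p_i - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = np.sum(n * h_i) / (r * nbar)
        if nbar <= 1:
            continue
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        abc_sum += a + b + c
    return a_sum, abc_sum


def fst_weir_cockerham(
    populations: Sequence[Sequence[Individual]],
    locus_names: Sequence[str],
    one_tailed: bool = True,
) -> PopGenSummary:
    """Multi-locus Weir–Cockerham theta over subpopulations.

    ``populations``: per subpopulation (e.g. colony), individuals as
    per-locus allele tuples.  Theta is the ratio of summed
    among-population variance components to total components over loci
    and alleles; the SE is a delete-one-locus jackknife and the default
    test is one-tailed for theta > 0 with df = loci - 1.
    """
    if len(populations) < 2:
        raise ValueError("need >= 2 subpopulations")
    L = len(locus_names)
    a_by_locus = np.zeros(L)
    abc_by_locus = np.zeros(L)
    for li in range(L):
        pops = []
        for pop in populations:
            pops.append([ind[li] for ind in pop if ind[li] is not None])
        a, abc = _wc_components(pops)
        a_by_locus[li] = a
        abc_by_locus[li] = abc
    informative = abc_by_locus != 0.0
    if not np.any(informative):
        raise ValueError("all loci monomorphic: theta undefined")
    a_by_locus = a_by_locus[informative]
    abc_by_locus = abc_by_locus[informative]
    names = [n for n, keep in zip(locus_names, informative) if keep]
    per_locus = {
        n: float(a / abc) for n, a, abc in zip(names, a_by_locus, abc_by_locus)
    }
    theta, se = _jackknife_ratio(a_by_locus, abc_by_locus)
    df = len(names) - 1
    if se is not None and se > 0:
        t = theta / se
        p = float(stats.t.sf(t, df)) if one_tailed \
            else float(2.0 * stats.t.sf(abs(t), df))
    else:
        t = p = None
    return PopGenSummary(
        statistic="F_ST", value=theta, per_locus=per_locus,
        se=se, t=t if t is None else float(t), df=df, p=p,
        one_tailed=one_tailed,
    )


# ---------------------------------------------------------------------------
# Queller–Goodnight regression relatedness
# ---------------------------------------------------------------------------


def _position_freq(genotype: tuple[int, ...], allele: int) -> float:
    return genotype.count(allele) / len(genotype)


def qg_pairwise(
    x: Individual,
    y: Individual,
    freqs: AlleleFrequencyTable,
    locus_names: Sequence[str],
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-locus numerator/denominator sums of symmetrized QG relatedness.

    For focal individual X with allele positions {a}, the locus terms are
    num = sum_a (P_Y(a) - p_a) and den = sum_a (P_X(a) - p_a), where
    P_Z(a) is the frequency of allele a within Z's genotype; the
    symmetrized estimate sums both focal directions.  Haploid genotypes
    have one position.  Loci untyped in either individual, or absent
    from the reference frequencies, are skipped.
    """
    nums: dict[str, float] = {}
    dens: dict[str, float] = {}
    for li, name in enumerate(locus_names):
        gx, gy = x[li], y[li]
        if gx is None or gy is None or name not in freqs.freqs:
            continue
        table = freqs.freqs[name]
        num = den = 0.0
        for focal, other in ((gx, gy), (gy, gx)):
            for a in focal:
                p = table.get(a, 0.0)
                num += _position_freq(other, a) - p
                den += _position_freq(focal, a) - p
        nums[name] = num
        dens[name] = den
    return nums, dens


def qg_relatedness(
    pairs: Sequence[tuple[Individual, Individual]],
    freqs: AlleleFrequencyTable,
    locus_names: Sequence[str],
    pair_class: str = "pairs",
) -> RelatednessSummary:
    """Average QG relatedness over designated pairs (ratio of sums over
    pairs and loci) with delete-one-locus jackknife SE."""
    num_tot = {name: 0.0 for name in locus_names}
    den_tot = {name: 0.0 for name in locus_names}
    used_pairs = 0
    for x, y in pairs:
        nums, dens = qg_pairwise(x, y, freqs, locus_names)
        if not nums:
            warnings.warn("pair with no shared typed loci skipped")
            continue
        used_pairs += 1
        for name in nums:
            num_tot[name] += nums[name]
            den_tot[name] += dens[name]
    names = [n for n in locus_names if den_tot[n] != 0.0]
    if not names:
        raise ValueError("no informative loci across pairs")
    nums = np.array([num_tot[n] for n in names])
    dens = np.array([den_tot[n] for n in names])
    value, se = _jackknife_ratio(nums, dens)
    return RelatednessSummary(
        pair_class=pair_class, value=value, se=se, n_pairs=used_pairs,
        per_locus_num={n: float(v) for n, v in zip(names, nums)},
        per_locus_den={n: float(v) for n, v in zip(names, dens)},
    )


# -- pair builders ----------------------------------------------------------


def _worker_individual(genotype) -> Individual:
    return tuple(None if g is None else tuple(g) for g in genotype)


def _male_individual(haplotype) -> Individual:
    return tuple(None if a is None else (a,) for a in haplotype)


def worker_pairs(colony: ColonySample, max_pairs: Optional[int] = None,
                 seed: int = 0) -> list[tuple[Individual, Individual]]:
    """All (optionally subsampled) within-colony worker pairs."""
    inds = [_worker_individual(w) for w in colony.workers]
    pairs = [(inds[i], inds[j]) for i in range(len(inds))
             for j in range(i + 1, len(inds))]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    return pairs


def queen_mate_pairs(parents: ParentSet) -> list[tuple[Individual, Individual]]:
    queen = _worker_individual(parents.queen)
    return [(queen, _male_individual(m)) for m in parents.males]


def mate_pairs(parents: ParentSet) -> list[tuple[Individual, Individual]]:
    males = [_male_individual(m) for m in parents.males]
    return [(males[i], males[j]) for i in range(len(males))
            for j in range(i + 1, len(males))]
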