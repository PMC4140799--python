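"""Queen and patriline reconstruction from worker genotypes.

In haplodiploids every worker carries one maternal and one paternal
allele per locus, and males are haploid, so a colony headed by a single
queen lets both parental genotypes be deduced directly from a worker
sample: the queen must contribute one allele to every worker at every
locus, and whatever remains is the father's.  Where a worker shares
both alleles with a heterozygous queen the paternal allele is ambiguous
(either queen allele), and workers are grouped into the minimum number
of patrilines consistent with single paternal haplotypes (parsimony) —
ambiguity can never create extra fathers, only merge them.

The observed patriline count k_obs from such a partition underestimates
the true mating frequency only through (a) unsampled rare patrilines
(corrected downstream via the Poisson zero class) and (b) the
non-detection error: the chance two distinct males share one multilocus
haplotype, which is the product over loci of the allele-frequency
homozygosity and is tiny for reasonably polymorphic panels.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genotypes import (
    AlleleFrequencyTable,
    ColonySample,
    DiploidGenotype,
    Haplotype,
)

__all__ = [
    "QueenCandidate",
    "PaternityPartition",
    "EmptyColonyError",
    "MultiQueenError",
    "InconsistentWorkerError",
    "filter_workers",
    "infer_queen",
    "assign_patrilines",
    "non_detection_error",
]


class EmptyColonyError(ValueError):
    """No workers left after filtering."""


class MultiQueenError(ValueError):
    """No single queen explains the workers within the foreign-worker cap."""


class InconsistentWorkerError(ValueError):
    """A worker cannot be an offspring of the supplied queen."""


@dataclass
class QueenCandidate:
    """A queen genotype hypothesis.

    ``support`` is the candidate's Hardy–Weinberg genotype probability
    under the reference allele frequencies, normalized over the surviving
    candidates; ``unexplained`` lists workers incompatible with it
    (putative foreign workers, e.g. drifted in after colony fission).
    """

    genotype: DiploidGenotype
    support: float
    n_unexplained: int
    unexplained: list[int] = field(default_factory=list)
    k_implied: Optional[int] = None


@dataclass
class PaternityPartition:
    """Queen, patriline haplotypes and worker assignment for one colony."""

    colony_id: str
    queen: DiploidGenotype
    patrilines: list[Haplotype]
    # per patriline, per locus: frozenset of alleles still compatible
    # (None = unconstrained because all members were untyped there)
    profiles: list[tuple[Optional[frozenset[int]], ...]]
    assignment: dict[int, int]          # worker index -> patriline index
    counts: list[int]
    excluded_workers: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.assignment)

    @property
    def k_obs(self) -> int:
        return len(self.patrilines)

    def validate(self, colony: ColonySample) -> None:
        """Check Mendelian consistency of every assigned worker."""
        if sum(self.counts) != self.n:
            raise AssertionError("patriline counts do not sum to n")
        for w, g in self.assignment.items():
            sets = _paternal_allele_sets(colony.workers[w], self.queen)
            for loc, (s, prof) in enumerate(zip(sets, self.profiles[g])):
                if s is None or prof is None:
                    continue
                if not (s & prof):
                    raise AssertionError(
                        f"worker {w} incompatible with patriline {g} at locus {loc}"
                    )


def filter_workers(
    colony: ColonySample, min_loci: int = 3
) -> tuple[ColonySample, list[tuple[int, str]]]:
    """Drop workers typed at fewer than ``min_loci`` loci.

    Returns the filtered colony and the excluded (index, reason) list;
    indices refer to the input colony.
    """
    if not colony.panel:
        raise ValueError("empty locus panel")
    keep, excluded = [], []
    for i in range(colony.n_workers):
        n_typed = colony.n_typed_loci(i)
        if n_typed >= min_loci:
            keep.append(i)
        else:
            excluded.append((i, f"only {n_typed} typed loci (< {min_loci})"))
    if not keep:
        raise EmptyColonyError(
            f"colony {colony.colony_id}: all {colony.n_workers} workers excluded"
        )
    filtered = ColonySample(
        colony_id=colony.colony_id,
        species_id=colony.species_id,
        location=colony.location,
        panel=colony.panel,
        workers=[colony.workers[i] for i in keep],
        worker_ids=[colony.worker_ids[i] for i in keep],
    )
    return filtered, excluded


# ---------------------------------------------------------------------------
# Queen inference
# ---------------------------------------------------------------------------


def _locus_candidates(
    colony: ColonySample, locus_index: int, max_foreign: int
) -> list[tuple[tuple[int, int], frozenset[int]]]:
    """Candidate queen allele pairs at one locus.

    Returns (pair, workers-not-explained) for every unordered pair of
    observed alleles (including homozygous pairs) leaving at most
    ``max_foreign`` typed workers without a queen allele.
    """
    observed: set[int] = set()
    typed: list[tuple[int, set[int]]] = []
    for w in range(colony.n_workers):
        pair = colony.workers[w][locus_index]
        if pair is None:
            continue
        observed.update(pair)
        typed.append((w, set(pair)))
    if not observed:
        return [((0, 0), frozenset())]  # untyped locus: unconstrained
    out = []
    alleles = sorted(observed)
    for a, b in itertools.combinations_with_replacement(alleles, 2):
        bad = frozenset(w for w, alleles_w in typed
                        if a not in alleles_w and b not in alleles_w)
        if len(bad) <= max_foreign:
            out.append(((a, b), bad))
    return out


def _locus_log_support(
    colony: ColonySample,
    locus_index: int,
    qpair: tuple[int, int],
    freqs: Optional[AlleleFrequencyTable],
) -> float:
    """Single-locus screen score of a queen allele pair.

    Log of (Hardy–Weinberg prior) x (product over typed workers of the
    locus likelihood), where the worker likelihood sums, over compatible
    (maternal, paternal) resolutions, the maternal segregation
    probability (1/2 for a heterozygous queen, 1 for a homozygous one)
    times the population frequency of the paternal allele.  The
    segregation factor is what separates a true homozygous queen from a
    spurious heterozygote whose second allele no worker ever inherited.
    Without ``freqs`` the paternal frequency is dropped and only the
    segregation structure discriminates.  Workers the pair cannot
    explain contribute nothing (they are handled by the foreign-worker
    penalty).
    """
    if qpair == (0, 0):
        return 0.0
    locus = colony.panel[locus_index]
    table = freqs.freqs.get(locus.name) if freqs is not None else None
    logp = 0.0
    if table is not None:
        pa = table.get(qpair[0], 1e-6)
        pb = table.get(qpair[1], 1e-6)
        prior = pa * pa if qpair[0] == qpair[1] else 2.0 * pa * pb
        logp += math.log(max(prior, 1e-300))
    maternal = set(qpair)
    seg = 0.5 if qpair[0] != qpair[1] else 1.0
    for w in range(colony.n_workers):
        pair = colony.workers[w][locus_index]
        if pair is None:
            continue
        like = 0.0
        for m in maternal:
            for paternal in pair:
                other = pair[1] if paternal == pair[0] else pair[0]
                if other != m:
                    continue
                pf = table.get(paternal, 1e-6) if table is not None else 1.0
                like += seg * pf
                if pair[0] == pair[1]:
                    break  # homozygous worker: one resolution per maternal
        if like > 0.0:
            logp += math.log(like)
    return logp


def _k_best_combinations(
    scored_locus: list[list[tuple[float, tuple[int, int], frozenset[int]]]],
    max_foreign: int,
    max_results: int,
    pop_budget: int = 20_000,
):
    """Best-first search over the product of per-locus candidate lists.

    Yields up to ``max_results`` whole-genotype combinations in
    descending screen score whose union of unexplained workers stays
    within ``max_foreign``.
    """
    import heapq

    L = len(scored_locus)
    start = (0,) * L

    def total(idx: tuple[int, ...]) -> float:
        return sum(scored_locus[l][i][0] for l, i in enumerate(idx))

    heap = [(-total(start), start)]
    seen = {start}
    results = []
    pops = 0
    while heap and len(results) < max_results and pops < pop_budget:
        neg, idx = heapq.heappop(heap)
        pops += 1
        bad: frozenset[int] = frozenset()
        ok = True
        for l, i in enumerate(idx):
            bad = bad | scored_locus[l][i][2]
            if len(bad) > max_foreign:
                ok = False
                break
        if ok:
            pairs = tuple(scored_locus[l][i][1] for l, i in enumerate(idx))
            results.append((-neg, pairs, bad))
        for l in range(L):
            if idx[l] + 1 < len(scored_locus[l]):
                nxt = idx[:l] + (idx[l] + 1,) + idx[l + 1:]
                if nxt not in seen:
                    seen.add(nxt)
                    heapq.heappush(heap, (-total(nxt), nxt))
    return results


def infer_queen(
    colony: ColonySample,
    freqs: Optional[AlleleFrequencyTable] = None,
    max_foreign: int = 2,
    max_candidates: int = 200,
    rank_patrilines_top: int = 10,
) -> list[QueenCandidate]:
    """Enumerate and rank single-queen genotype hypotheses.

    A candidate queen must supply one allele to every typed worker at
    every locus, allowing up to ``max_foreign`` workers to be set aside
    as putative foreigners (the union over loci of workers the candidate
    cannot explain).  Candidates are ranked by fewer unexplained
    workers, then fewer implied patrilines (parsimony, evaluated for the
    leading candidates), then higher Hardy–Weinberg genotype probability
    under ``freqs``.
    """
    if colony.n_workers < 2:
        raise ValueError("need at least 2 workers to infer a queen")
    per_locus = [
        _locus_candidates(colony, i, max_foreign) for i in range(len(colony.panel))
    ]
    if any(not c for c in per_locus):
        raise MultiQueenError(
            f"colony {colony.colony_id}: some locus has no queen pair leaving "
            f"<= {max_foreign} unexplained workers"
        )
    # screen scores factorize across loci (given no unexplained workers),
    # so the leading whole-genotype candidates come from a best-first
    # search over the product of per-locus candidate lists
    foreign_penalty = -50.0
    scored_locus: list[list[tuple[float, tuple[int, int], frozenset[int]]]] = []
    for li, cands_l in enumerate(per_locus):
        scored = []
        for pair, bad in cands_l:
            s = _locus_log_support(colony, li, pair, freqs)
            scored.append((s + foreign_penalty * len(bad), pair, bad))
        scored.sort(key=lambda t: -t[0])
        scored_locus.append(scored)

    results = _k_best_combinations(scored_locus, max_foreign, max_candidates)
    if not results:
        raise MultiQueenError(
            f"colony {colony.colony_id}: no single queen explains all but "
            f"{max_foreign} workers"
        )

    candidates = []
    for score, pairs, bad in results:
        g = tuple(None if pair == (0, 0) else pair for pair in pairs)
        candidates.append(
            QueenCandidate(
                genotype=g,
                support=score,  # provisional: replaced after refinement
                n_unexplained=len(bad),
                unexplained=sorted(bad),
            )
        )
    candidates.sort(key=lambda c: (c.n_unexplained, -c.support))
    # refine the leading candidates at partition level: parsimony count and
    # a likelihood that charges each paternal allele once per patriline
    # (the worker-level screen above charges it per worker, over-penalizing
    # a rare allele whose father sired many workers)
    scored = []
    for cand in candidates[:rank_patrilines_top]:
        keep = [w for w in range(colony.n_workers) if w not in cand.unexplained]
        sub = ColonySample(
            colony_id=colony.colony_id, species_id=colony.species_id,
            location=colony.location, panel=colony.panel,
            workers=[colony.workers[w] for w in keep],
            worker_ids=[colony.worker_ids[w] for w in keep],
        )
        try:
            part = assign_patrilines(sub, cand.genotype, freqs)
        except InconsistentWorkerError:  # pragma: no cover - defensive
            cand.k_implied = None
            scored.append((cand, -math.inf))
            continue
        cand.k_implied = part.k_obs
        scored.append((cand, _partition_log_likelihood(cand.genotype, part,
                                                       sub, freqs)))
    big = 10 ** 9
    loglik = {id(c): ll for c, ll in scored}
    candidates.sort(
        key=lambda c: (
            c.n_unexplained,
            c.k_implied if c.k_implied is not None else big,
            -loglik.get(id(c), -math.inf),
            c.genotype,
        )
    )
    # support: softmax of the partition-level log-likelihoods over the
    # refined candidates; unrefined long-shot candidates get support 0
    finite = [ll for _, ll in scored if ll > -math.inf]
    ref = max(finite) if finite else 0.0
    weights = {id(c): math.exp(ll - ref) if ll > -math.inf else 0.0
               for c, ll in scored}
    total = sum(weights.values())
    for c in candidates:
        c.support = weights.get(id(c), 0.0) / total if total > 0 else 0.0
    return candidates


def _partition_log_likelihood(
    queen: DiploidGenotype,
    partition: "PaternityPartition",
    colony: ColonySample,
    freqs: Optional[AlleleFrequencyTable],
) -> float:
    """Log-likelihood of (queen, partition): Hardy–Weinberg prior of the
    queen, each patriline haplotype's population probability (best
    ambiguity resolution), and a 1/2 maternal segregation factor per
    worker per typed locus at which the queen is heterozygous."""
    logp = 0.0
    for locus, qpair in zip(colony.panel, queen):
        if qpair is None:
            continue
        if freqs is not None and locus.name in freqs.freqs:
            table = freqs.freqs[locus.name]
            pa = table.get(qpair[0], 1e-6)
            pb = table.get(qpair[1], 1e-6)
            prior = pa * pa if qpair[0] == qpair[1] else 2.0 * pa * pb
            logp += math.log(max(prior, 1e-300))
    for profile in partition.profiles:
        logp += _profile_logprob(profile, colony.panel, freqs)
    log_half = math.log(0.5)
    for w in partition.assignment:
        for li, qpair in enumerate(queen):
            if qpair is None or qpair[0] == qpair[1]:
                continue
            if colony.workers[w][li] is not None:
                logp += log_half
    return logp


# ---------------------------------------------------------------------------
# Patriline assignment (parsimony)
# ---------------------------------------------------------------------------


def _paternal_allele_sets(
    worker: DiploidGenotype, queen: DiploidGenotype
) -> tuple[Optional[frozenset[int]], ...]:
    """Per-locus set of possible paternal alleles, None where untyped.

    At a typed locus the maternal allele must be one of the queen's, so
    the paternal allele is whichever worker allele leaves a queen allele
    behind; if the worker matches a heterozygous queen exactly, both
    resolutions are possible.
    """
    out: list[Optional[frozenset[int]]] = []
    for pair, qpair in zip(worker, queen):
        if pair is None:
            out.append(None)
            continue
        if qpair is None:
            # queen untyped at this locus: any worker allele could be paternal
            out.append(frozenset(pair))
            continue
        qset = set(qpair)
        a, b = pair
        possible = set()
        if b in qset:
            possible.add(a)
        if a in qset:
            possible.add(b)
        if not possible:
            out.append(frozenset())
        else:
            out.append(frozenset(possible))
    return tuple(out)


def _merge(profile, sets):
    """Intersect a patriline profile with a worker's allele sets.

    Returns the merged profile or None if incompatible at some locus.
    """
    merged = []
    for prof, s in zip(profile, sets):
        if s is None:
            merged.append(prof)
        elif prof is None:
            merged.append(s)
        else:
            inter = prof & s
            if not inter:
                return None
            merged.append(inter)
    return tuple(merged)


def _profile_logprob(profile, panel, freqs: Optional[AlleleFrequencyTable]) -> float:
    if freqs is None:
        return 0.0
    logp = 0.0
    for locus, prof in zip(panel, profile):
        if prof is None or locus.name not in freqs.freqs:
            continue
        table = freqs.freqs[locus.name]
        best = max(table.get(a, 1e-6) for a in prof)
        logp += math.log(max(best, 1e-300))
    return logp


def assign_patrilines(
    colony: ColonySample,
    queen: DiploidGenotype,
    freqs: Optional[AlleleFrequencyTable] = None,
    exact_cap: int = 25,
    max_solutions: int = 200,
) -> PaternityPartition:
    """Group workers into the minimum number of patrilines.

    Workers whose paternal haplotype is fully determined (typed and
    unambiguous at every locus) are grouped by haplotype identity;
    workers with ambiguous or missing loci are then placed by exact
    branch-and-bound over their possible resolutions when at most
    ``exact_cap`` such workers exist, and by a greedy merge otherwise.
    Ambiguous/missing workers join a compatible patriline rather than
    founding their own, so missingness cannot inflate k_obs.  Ties
    between equally parsimonious partitions are broken by the larger
    product of best-resolution haplotype probabilities under ``freqs``,
    then lexicographically by assignment — the result is deterministic.
    """
    n = colony.n_workers
    allele_sets = []
    for w in range(n):
        sets = _paternal_allele_sets(colony.workers[w], queen)
        for loc, s in enumerate(sets):
            if s is not None and not s:
                raise InconsistentWorkerError(
                    f"worker {colony.worker_ids[w]} (index {w}) carries no queen "
                    f"allele at locus {colony.panel[loc].name}"
                )
        allele_sets.append(sets)

    rigid: dict[tuple, list[int]] = {}
    flexible: list[int] = []
    for w in range(n):
        sets = allele_sets[w]
        if all(s is not None and len(s) == 1 for s in sets):
            key = tuple(next(iter(s)) for s in sets)
            rigid.setdefault(key, []).append(w)
        else:
            flexible.append(w)

    base_profiles = []
    base_members: list[list[int]] = []
    for key in sorted(rigid):
        base_profiles.append(tuple(frozenset({a}) for a in key))
        base_members.append(list(rigid[key]))

    # most-constrained flexible workers first: fewer feasible groups early
    def flexibility(w: int) -> tuple:
        sets = allele_sets[w]
        wild = sum(s is None for s in sets)
        amb = sum(1 for s in sets if s is not None and len(s) > 1)
        return (wild + amb, w)

    flexible.sort(key=flexibility)

    if len(flexible) <= exact_cap:
        best = _exact_place(base_profiles, base_members, flexible, allele_sets,
                            colony, freqs, max_solutions)
    else:
        best = _greedy_place(base_profiles, base_members, flexible, allele_sets,
                             colony, freqs)
    profiles, members = best

    # deterministic patriline order: descending size, then profile repr
    def rep(profile) -> tuple:
        return tuple(
            (-1,) if s is None else tuple(sorted(s)) for s in profile
        )

    idx = sorted(range(len(profiles)),
                 key=lambda g: (-len(members[g]), rep(profiles[g])))
    profiles = [profiles[g] for g in idx]
    members = [members[g] for g in idx]

    haplotypes: list[Haplotype] = []
    for prof in profiles:
        hap = []
        for locus, s in zip(colony.panel, prof):
            if s is None:
                hap.append(None)
            elif freqs is not None and locus.name in freqs.freqs:
                table = freqs.freqs[locus.name]
                hap.append(max(sorted(s), key=lambda a: table.get(a, 0.0)))
            else:
                hap.append(min(s))
        haplotypes.append(tuple(hap))

    assignment = {}
    for g, group in enumerate(members):
        for w in group:
            assignment[w] = g
    return PaternityPartition(
        colony_id=colony.colony_id,
        queen=queen,
        patrilines=haplotypes,
        profiles=profiles,
        assignment=assignment,
        counts=[len(m) for m in members],
    )


def _exact_place(base_profiles, base_members, flexible, allele_sets, colony,
                 freqs, max_solutions, node_budget: int = 500_000):
    """Branch-and-bound: place flexible workers minimizing new patrilines.

    The search is exact within ``node_budget`` expansions; if the budget
    is exhausted the best partition found so far is returned (and the
    greedy fallback is used if none was completed).
    """
    best_k = [len(base_profiles) + len(flexible) + 1]
    solutions: list[tuple[int, list, list]] = []
    nodes = [0]

    def dfs(i, profiles, members, n_groups):
        nodes[0] += 1
        if nodes[0] > node_budget or n_groups > best_k[0]:
            return
        if i == len(flexible):
            if n_groups < best_k[0]:
                best_k[0] = n_groups
                solutions.clear()
            if n_groups == best_k[0] and len(solutions) < max_solutions:
                solutions.append(
                    (n_groups, [p for p in profiles], [list(m) for m in members])
                )
            return
        w = flexible[i]
        sets = allele_sets[w]
        for g in range(len(profiles)):
            merged = _merge(profiles[g], sets)
            if merged is not None:
                old = profiles[g]
                profiles[g] = merged
                members[g].append(w)
                dfs(i + 1, profiles, members, n_groups)
                members[g].pop()
                profiles[g] = old
        # open a new patriline (counts toward n_groups)
        if n_groups + 1 <= best_k[0]:
            profiles.append(tuple(s for s in sets))
            members.append([w])
            dfs(i + 1, profiles, members, n_groups + 1)
            members.pop()
            profiles.pop()

    dfs(0, list(base_profiles), [list(m) for m in base_members],
        len(base_profiles))
    if not solutions:  # budget exhausted before any complete partition
        return _greedy_place(base_profiles, base_members, flexible,
                             allele_sets, colony, freqs)

    def score(sol):
        _, profiles, members = sol
        logp = sum(_profile_logprob(p, colony.panel, freqs) for p in profiles)
        assign = [0] * colony.n_workers
        for g, group in enumerate(members):
            for w in group:
                assign[w] = g
        return (-logp, tuple(assign))

    solutions.sort(key=score)
    _, profiles, members = solutions[0]
    return profiles, members


def _greedy_place(base_profiles, base_members, flexible, allele_sets, colony,
                  freqs):
    """Greedy merge for large instances: join the best compatible group."""
    profiles = list(base_profiles)
    members = [list(m) for m in base_members]
    for w in flexible:
        sets = allele_sets[w]
        best_g, best_key = None, None
        for g in range(len(profiles)):
            merged = _merge(profiles[g], sets)
            if merged is None:
                continue
            key = (-len(members[g]),
                   -_profile_logprob(merged, colony.panel, freqs), g)
            if best_key is None or key < best_key:
                best_key, best_g = key, (g, merged)
        if best_g is None:
            profiles.append(tuple(s for s in sets))
            members.append([w])
        else:
            g, merged = best_g
            profiles[g] = merged
            members[g].append(w)
    return profiles, members


# ---------------------------------------------------------------------------
# Non-detection error
# ---------------------------------------------------------------------------


def non_detection_error(
    freqs: AlleleFrequencyTable, loci_used: Optional[Sequence[str]] = None
) -> float:
    """Probability two random haploid males share the whole multilocus
    haplotype: product over loci of the allele homozygosity sum p_a^2."""
    loci = list(freqs.loci) if loci_used is None else list(loci_used)
    if not loci:
        raise ValueError("no loci supplied")
    prob = 1.0
    used = 0
    for locus in loci:
        if locus not in freqs.freqs:
            warnings.warn(f"locus {locus}: no frequencies, excluded from "
                          "non-detection error")
            continue
        prob *= freqs.homozygosity(locus)
        used += 1
    if used == 0:
        raise ValueError("no loci with known frequencies")
    return prob
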