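"""Cross-species comparative analyses.

The central cross-species question — do queens equalize paternity more
strongly the more males they mate with? — is addressed by regressing a
paternity-skew index on paternity frequency across species while
accounting for phylogenetic non-independence: under Brownian motion the
species means have covariance proportional to shared root-to-ancestor
branch length, and the regression is fitted by maximum likelihood in
that covariance (PGLS).  Because the S-index is computed from k_obs, a
negative association is expected a priori; the observed slope is
therefore compared against a Monte-Carlo interval of slopes obtained by
refitting the model with random null S-values drawn from each species'
uniform-allocation simulations.  Heterogeneity of the paternity
distributions themselves is quantified by the chi-square (inertia)
decomposition of a patriline-rank-by-species contingency table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy import stats

__all__ = [
    "PhyloTree",
    "SpeciesRecord",
    "GLSFit",
    "CAResult",
    "pgls",
    "transform_for_regression",
    "inverse_transform",
    "slope_null_interval",
    "correspondence_analysis",
    "paternity_rank_table",
]


class PhyloTree:
    """A species phylogeny with branch lengths (Newick-backed).

    Wraps a dendropy tree and exposes the Brownian-motion trait
    covariance matrix: V[i, j] is the branch length shared between the
    root-to-tip paths of tips i and j.
    """

    def __init__(self, tree: dendropy.Tree,
                 equal_branch_lengths: bool = False) -> None:
        self._tree = tree
        if equal_branch_lengths:
            for edge in tree.preorder_edge_iter():
                if edge.tail_node is not None:
                    edge.length = 1.0
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is not None and edge.length is None:
                raise ValueError("tree has missing branch lengths "
                                 "(use equal_branch_lengths=True)")
            if edge.tail_node is not None and edge.length < 0:
                raise ValueError("negative branch length")
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        self.tip_labels: list[str] = labels

    @classmethod
    def from_newick(cls, newick: str,
                    equal_branch_lengths: bool = False) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:
            raise ValueError(f"bad newick string: {exc}") from exc
        return cls(tree, equal_branch_lengths=equal_branch_lengths)

    @classmethod
    def from_file(cls, path, equal_branch_lengths: bool = False) -> "PhyloTree":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree, equal_branch_lengths=equal_branch_lengths)

    @classmethod
    def star(cls, labels: Sequence[str], branch_length: float = 1.0) -> "PhyloTree":
        newick = "(" + ",".join(f"{l}:{branch_length}" for l in labels) + ");"
        return cls.from_newick(newick)

    def covariance_matrix(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        order = list(self.tip_labels) if order is None else list(order)
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        missing = [l for l in order if l not in taxa]
        if missing:
            raise ValueError(f"tips not in tree: {missing}")
        depth: dict[str, float] = {}
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depth[leaf.taxon.label] = d
        n = len(order)
        V = np.zeros((n, n))
        for i in range(n):
            V[i, i] = depth[order[i]]
            for j in range(i + 1, n):
                dij = pdm.patristic_distance(taxa[order[i]], taxa[order[j]])
                V[i, j] = V[j, i] = 0.5 * (depth[order[i]] + depth[order[j]] - dij)
        return V


@dataclass
class SpeciesRecord:
    """Per-species comparative record (one tip of the tree)."""

    species_id: str
    k_obs: float
    k_est: Optional[float] = None
    B: Optional[float] = None
    S: Optional[float] = None
    colony_size: Optional[float] = None


@dataclass
class GLSFit:
    """Maximum-likelihood PGLS fit with a likelihood-ratio slope test."""

    slope: float
    intercept: float
    sigma2: float
    r_squared: float
    loglik_full: float
    loglik_null: float
    lrt_chi2: float
    p_value: float
    df: int = 1
    n: int = 0


def _gls_ml(y: np.ndarray, X: np.ndarray, V: np.ndarray
            ) -> tuple[np.ndarray, float, float, np.ndarray]:
    """ML fit of y = X beta + eps, eps ~ MVN(0, sigma2 * V).

    Returns (beta, sigma2_ML, loglik, whitened residuals).
    """
    n = y.size
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        raise ValueError("phylogenetic covariance matrix is singular "
                         "(duplicate zero-length tips?)")
    L = np.linalg.cholesky(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = 0.0
        loglik = math.inf
    else:
        loglik = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdetV + n)
    return beta, sigma2, loglik, resid


def pgls(
    y: Sequence[float],
    x: Sequence[float],
    tree: PhyloTree,
    species: Optional[Sequence[str]] = None,
) -> GLSFit:
    """Phylogenetic GLS regression of y on x under Brownian motion.

    Fits intercept and slope by maximum likelihood with residual
    covariance sigma2 * V(tree); the slope is tested by a likelihood
    ratio against the intercept-only model (chi-square, df = 1).  R^2 is
    computed in the V-whitened space, so on a star tree with equal
    branch lengths everything reduces to ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 species")
    species = list(tree.tip_labels) if species is None else list(species)
    V = tree.covariance_matrix(order=species)
    X_full = np.column_stack([np.ones(n), x])
    X_null = np.ones((n, 1))
    beta, sigma2, ll_full, resid = _gls_ml(y, X_full, V)
    beta0, sigma2_0, ll_null, resid0 = _gls_ml(y, X_null, V)
    if math.isinf(ll_full):
        # perfect fit: zero residual variance edge case
        lrt = math.inf if not math.isinf(ll_null) else 0.0
        p = 0.0 if lrt > 0 else 1.0
        r2 = 1.0
    else:
        lrt = max(0.0, 2.0 * (ll_full - ll_null))
        p = float(stats.chi2.sf(lrt, df=1))
        tss = float(resid0 @ resid0)
        rss = float(resid @ resid)
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return GLSFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        sigma2=float(sigma2),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        loglik_full=float(ll_full),
        loglik_null=float(ll_null),
        lrt_chi2=float(lrt),
        p_value=float(p),
        n=n,
    )


def transform_for_regression(values: Sequence[float], kind: str) -> np.ndarray:
    """Normalizing transforms: skew -> log10(x + 1) (zero-safe),
    colony size -> log10(x)."""
    v = np.asarray(values, dtype=float)
    if kind == "skew":
        if np.any(v < 0):
            raise ValueError("negative skew: clamp upstream before transforming")
        return np.log10(v + 1.0)
    if kind == "colony_size":
        if np.any(v <= 0):
            raise ValueError("colony size must be positive")
        return np.log10(v)
    raise ValueError(f"unknown transform kind {kind!r}")


def inverse_transform(values: Sequence[float], kind: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if kind == "skew":
        return 10.0 ** v - 1.0
    if kind == "colony_size":
        return 10.0 ** v
    raise ValueError(f"unknown transform kind {kind!r}")


def slope_null_interval(
    records: Sequence[SpeciesRecord],
    tree: PhyloTree,
    null_s_draws: dict[str, np.ndarray],
    n_runs: int = 100,
    seed: int = 0,
    transform: bool = True,
) -> tuple[float, float, np.ndarray]:
    """Randomized-slope 95% interval for the PGLS of S on k_obs.

    Each run substitutes one random uniform-allocation null S-value per
    species (negatives treated as zero skew), refits the PGLS, and
    collects the slope; returns the 2.5th/97.5th percentiles and the
    slopes.  An observed slope below the lower limit is steeper than
    the S-on-k_obs association already expected from sampling alone.
    """
    rng = np.random.default_rng(seed)
    species = [r.species_id for r in records]
    missing = [s for s in species if s not in null_s_draws]
    if missing:
        raise ValueError(f"no null S draws for species: {missing}")
    x = np.array([r.k_obs for r in records], dtype=float)
    slopes = np.empty(n_runs)
    for run in range(n_runs):
        s_vals = []
        for sp in species:
            draws = null_s_draws[sp]
            if run == 0 and draws.size < n_runs:
                warnings.warn(
                    f"species {sp}: only {draws.size} null draws for "
                    f"{n_runs} runs; sampling with replacement"
                )
            s_vals.append(max(0.0, float(draws[rng.integers(draws.size)])))
        yv = np.asarray(s_vals)
        if transform:
            yv = transform_for_regression(yv, "skew")
        fit = pgls(yv, x, tree, species=species)
        slopes[run] = fit.slope
    low, high = np.percentile(slopes, [2.5, 97.5], method="linear")
    return float(low), float(high), slopes


# ---------------------------------------------------------------------------
# Correspondence analysis (chi-square / inertia decomposition)
# ---------------------------------------------------------------------------


@dataclass
class CAResult:
    """Chi-square heterogeneity of paternity distributions among groups."""

    table: np.ndarray
    row_labels: list[str]
    column_labels: list[str]
    chi2: float
    df: int
    p_value: float
    relative_inertia_columns: dict[str, float]
    relative_inertia_rows: dict[str, float]


def paternity_rank_table(
    counts_by_group: dict[str, Sequence[int]]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Patriline-rank x group contingency table.

    Within each group (species or colony) patriline worker counts are
    sorted in descending order, so row r holds each group's r-th largest
    patriline; shorter groups contribute zeros below their k_obs.
    """
    groups = list(counts_by_group)
    ranked = {g: sorted(counts_by_group[g], reverse=True) for g in groups}
    n_rows = max(len(v) for v in ranked.values())
    table = np.zeros((n_rows, len(groups)))
    for j, g in enumerate(groups):
        for i, c in enumerate(ranked[g]):
            table[i, j] = c
    rows = [f"rank{i + 1}" for i in range(n_rows)]
    return table, rows, groups


def correspondence_analysis(
    table: np.ndarray,
    row_labels: Optional[Sequence[str]] = None,
    column_labels: Optional[Sequence[str]] = None,
) -> CAResult:
    """Chi-square decomposition of a nonnegative contingency table.

    Total chi-square against independence expectations, df =
    (rows-1)(columns-1), and the relative inertia of each column (and
    row): its share of the total chi-square.  Zero-margin rows/columns
    are dropped with a warning.
    """
    T = np.asarray(table, dtype=float)
    if np.any(T < 0):
        raise ValueError("contingency table must be nonnegative")
    nr, nc = T.shape
    row_labels = [f"r{i}" for i in range(nr)] if row_labels is None else list(row_labels)
    column_labels = [f"c{j}" for j in range(nc)] if column_labels is None else list(column_labels)
    keep_r = T.sum(axis=1) > 0
    keep_c = T.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("zero-margin rows/columns dropped from the table")
        T = T[keep_r][:, keep_c]
        row_labels = [l for l, k in zip(row_labels, keep_r) if k]
        column_labels = [l for l, k in zip(column_labels, keep_c) if k]
    if T.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    total = T.sum()
    expected = np.outer(T.sum(axis=1), T.sum(axis=0)) / total
    cells = (T - expected) ** 2 / expected
    chi2 = float(cells.sum())
    df = (T.shape[0] - 1) * (T.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    if chi2 > 0:
        col_inertia = {l: float(c) for l, c in
                       zip(column_labels, cells.sum(axis=0) / chi2)}
        row_inertia = {l: float(c) for l, c in
                       zip(row_labels, cells.sum(axis=1) / chi2)}
    else:
        col_inertia = {l: 0.0 for l in column_labels}
        row_inertia = {l: 0.0 for l in row_labels}
    return CAResult(
        table=T, row_labels=list(row_labels), column_labels=list(column_labels),
        chi2=chi2, df=df, p_value=p,
        relative_inertia_columns=col_inertia,
        relative_inertia_rows=row_inertia,
    )
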