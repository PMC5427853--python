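"""Ordination and distance primitives.

Correspondence analysis of a site-by-species table, row-weighted PCA of
environmental tables, Gower trait distances, patristic phylogenetic
distances, principal coordinate analysis with the Cailliez correction for
non-Euclidean distance matrices, and UPGMA trait dendrograms.  These are
the building blocks that the extended RLQ analysis composes.

Distance matrices are carried as :class:`skbio.DistanceMatrix`, which
enforces symmetry, hollowness and labelled ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .errors import DegenerateInputError, InvalidArgumentError, ValidationError

#: relative tolerance for classifying eigenvalues as zero/negative
EIG_RTOL = 1e-8


@dataclass
class OrdinationResult:
    """Shared container for CA / PCA / PCoA decompositions.

    eigenvalues are non-increasing; ``row_scores`` and ``col_scores`` are
    principal coordinates labelled by the input ids; weights are the metric
    each set of scores is orthogonal under.
    """

    eigenvalues: np.ndarray
    row_scores: pd.DataFrame
    col_scores: pd.DataFrame | None
    row_weights: pd.Series
    col_weights: pd.Series | None
    total_inertia: float
    method: str
    extras: dict = field(default_factory=dict)

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = np.clip(self.eigenvalues, 0.0, None)
        tot = pos.sum()
        return pos / tot if tot > 0 else pos


def _fix_signs(U: np.ndarray, *others: np.ndarray):
    """Sign convention: in each column of U the largest-|entry| is positive.

    The same flip is propagated to paired matrices so transition formulas
    keep holding.
    """
    if U.size == 0:
        return (U, *others)
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    flipped = [U * signs]
    for M in others:
        flipped.append(M * signs if M is not None else None)
    return tuple(flipped)


# ---------------------------------------------------------------------------
# correspondence analysis
# ---------------------------------------------------------------------------

def correspondence_analysis(L: pd.DataFrame) -> OrdinationResult:
    """Correspondence analysis of a non-negative site-by-species table.

    Eigen-decomposes the chi-square standardized table; row and column
    weights are the marginal relative frequencies and total inertia equals
    Pearson chi-square divided by the grand total.
    """
    N = np.asarray(L, dtype=float)
    if (N < 0).any():
        raise ValidationError("correspondence analysis requires a non-negative table")
    row_sums = N.sum(axis=1)
    col_sums = N.sum(axis=0)
    for axis_name, sums, labels in (
        ("row", row_sums, L.index),
        ("column", col_sums, L.columns),
    ):
        bad = np.where(sums == 0)[0]
        if bad.size:
            names = ", ".join(str(labels[i]) for i in bad[:5])
            raise DegenerateInputError(
                f"zero {axis_name} margin in table: {names}"
            )
    total = N.sum()
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    V = Vt.T
    # drop numerically-null axes
    keep = s > EIG_RTOL * max(s[0], 1e-300) if s.size else np.zeros(0, bool)
    U, s, V = U[:, keep], s[keep], V[:, keep]
    U, V = _fix_signs(U, V)
    eig = s**2
    # principal coordinates
    F = (U * s) / np.sqrt(r)[:, None]
    G = (V * s) / np.sqrt(c)[:, None]
    axes = [f"CA{k + 1}" for k in range(len(s))]
    return OrdinationResult(
        eigenvalues=eig,
        row_scores=pd.DataFrame(F, index=L.index, columns=axes),
        col_scores=pd.DataFrame(G, index=L.columns, columns=axes),
        row_weights=pd.Series(r, index=L.index),
        col_weights=pd.Series(c, index=L.columns),
        total_inertia=float((S**2).sum()),
        method="CA",
    )


# ---------------------------------------------------------------------------
# weighted PCA
# ---------------------------------------------------------------------------

def weighted_standardize(X: pd.DataFrame, w: np.ndarray) -> pd.DataFrame:
    """Center and scale columns to weighted mean 0 / variance 1.

    Raises on zero-variance columns, naming them.
    """
    w = np.asarray(w, float)
    w = w / w.sum()
    mu = w @ X.values
    centered = X.values - mu
    var = w @ centered**2
    zero = np.where(var <= 0)[0]
    if zero.size:
        names = ", ".join(str(X.columns[i]) for i in zero)
        raise DegenerateInputError(f"zero-variance variable(s): {names}")
    return pd.DataFrame(centered / np.sqrt(var), index=X.index, columns=X.columns)


def pca(X: pd.DataFrame, row_weights: np.ndarray | None = None) -> OrdinationResult:
    """Row-weighted PCA of standardized variables (correlation-matrix PCA
    when weights are uniform).  Eigenvalues sum to the number of variables.
    """
    if X.shape[1] < 2:
        raise InvalidArgumentError("PCA needs at least 2 variables")
    n = X.shape[0]
    w = np.full(n, 1.0 / n) if row_weights is None else np.asarray(row_weights, float)
    w = w / w.sum()
    Z = weighted_standardize(X, w)
    C = (Z.values * w[:, None]).T @ Z.values
    eig, V = np.linalg.eigh(C)
    order = np.argsort(eig)[::-1]
    eig, V = eig[order], V[:, order]
    eig = np.clip(eig, 0.0, None)
    (V,) = _fix_signs(V)
    scores = Z.values @ V
    axes = [f"PC{k + 1}" for k in range(V.shape[1])]
    return OrdinationResult(
        eigenvalues=eig,
        row_scores=pd.DataFrame(scores, index=X.index, columns=axes),
        col_scores=pd.DataFrame(V, index=X.columns, columns=axes),
        row_weights=pd.Series(w, index=X.index),
        col_weights=pd.Series(np.ones(X.shape[1]), index=X.columns),
        total_inertia=float(eig.sum()),
        method="PCA",
        extras={"standardized": Z},
    )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def gower_distance(traits: pd.DataFrame) -> DistanceMatrix:
    """Gower distance between species over quantitative traits.

    Mean over traits of |x_i - x_j| / range, skipping pairs where either
    value is missing; values lie in [0, 1].
    """
    if traits.shape[1] < 1:
        raise InvalidArgumentError("need at least one trait column")
    X = traits.values.astype(float)
    n = X.shape[0]
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for j, col in enumerate(traits.columns):
        x = X[:, j]
        ok = ~np.isnan(x)
        vals = x[ok]
        if vals.size == 0:
            continue
        rng = vals.max() - vals.min()
        if rng <= 0:
            raise DegenerateInputError(
                f"trait {col!r} has zero range among non-missing values"
            )
        d = np.abs(x[:, None] - x[None, :]) / rng
        both = ok[:, None] & ok[None, :]
        num[both] += d[both]
        cnt += both
    np.fill_diagonal(cnt, 1.0)  # diagonal is 0 by definition
    np.fill_diagonal(num, 0.0)
    empty = np.argwhere(cnt == 0)
    if empty.size:
        i, j = empty[0]
        raise ValidationError(
            f"species pair ({traits.index[i]!r}, {traits.index[j]!r}) shares "
            "no non-missing trait"
        )
    D = num / cnt
    D = (D + D.T) / 2.0
    return DistanceMatrix(D, ids=[str(i) for i in traits.index])


def patristic_distance(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distances of a phylogeny."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            head = edge.head_node.taxon.label if edge.head_node.taxon else "<internal>"
            raise ValidationError(f"missing branch length on edge above {head!r}")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(D, ids=labels)


# ---------------------------------------------------------------------------
# PCoA with Cailliez correction
# ---------------------------------------------------------------------------

def _gower_centered(D: np.ndarray, power: int = 2) -> np.ndarray:
    A = -0.5 * D**power if power == 2 else -0.5 * D
    n = A.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    return H @ A @ H


def cailliez_constant(D: np.ndarray) -> float:
    """Smallest constant c such that D + c (off-diagonal) is Euclidean.

    Largest real eigenvalue of the 2n-by-2n companion problem
    [[0, 2*Delta1], [-I, -4*Delta2]] with Delta1/Delta2 the doubly-centered
    -D^2/2 and -D/2 matrices.
    """
    n = D.shape[0]
    d1 = _gower_centered(D, power=2)
    d2 = _gower_centered(D, power=1)
    M = np.block([[np.zeros((n, n)), 2.0 * d1], [-np.eye(n), -4.0 * d2]])
    ev = np.linalg.eigvals(M)
    real = ev.real[np.abs(ev.imag) < 1e-8 * (1 + np.abs(ev.real))]
    return float(max(real.max(), 0.0))


def pcoa(D: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis.

    Gower double-centering plus eigendecomposition; when negative
    eigenvalues exceed tolerance the Cailliez constant is added to the
    off-diagonal distances and the decomposition is redone (flagged in
    ``extras``).  Returned coordinates reproduce the (corrected) distances.
    """
    ids = list(D.ids)
    Dm = D.data.astype(float)
    corrected = False
    c = 0.0
    B = _gower_centered(Dm)
    eig, V = np.linalg.eigh(B)
    tol = EIG_RTOL * max(np.abs(eig).max(), 1e-300)
    if eig.min() < -tol:
        c = cailliez_constant(Dm)
        Dm = Dm + c
        np.fill_diagonal(Dm, 0.0)
        corrected = True
        B = _gower_centered(Dm)
        eig, V = np.linalg.eigh(B)
        tol = EIG_RTOL * max(np.abs(eig).max(), 1e-300)
    order = np.argsort(eig)[::-1]
    eig, V = eig[order], V[:, order]
    keep = eig > tol
    (Vk,) = _fix_signs(V[:, keep])
    coords = Vk * np.sqrt(eig[keep])
    n = len(ids)
    axes = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return OrdinationResult(
        eigenvalues=eig,
        row_scores=pd.DataFrame(coords, index=ids, columns=axes),
        col_scores=None,
        row_weights=pd.Series(np.full(n, 1.0 / n), index=ids),
        col_weights=None,
        total_inertia=float(eig[keep].sum()),
        method="PCoA",
        extras={"cailliez_corrected": corrected, "cailliez_constant": c,
                "corrected_distances": Dm if corrected else None},
    )


# ---------------------------------------------------------------------------
# UPGMA dendrogram
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """UPGMA tree over species; ultrametric by construction.

    ``linkage`` is a scipy hierarchical-clustering linkage matrix whose
    merge distances are cophenetic distances (node *heights* are half of
    them).
    """

    linkage: np.ndarray
    labels: list[str]

    def cophenetic(self) -> DistanceMatrix:
        coph = hierarchy.cophenet(self.linkage)
        return DistanceMatrix(squareform(coph), ids=self.labels)

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def build(node) -> tuple[str, float]:
            # returns (subtree string, node height = depth below its parent ref)
            if node.is_leaf():
                return self.labels[node.id], 0.0
            ls, lh = build(node.left)
            rs, rh = build(node.right)
            h = node.dist / 2.0  # ultrametric height of this node
            return f"({ls}:{h - lh:.10g},{rs}:{h - rh:.10g})", h

        s, _ = build(root)
        return s + ";"


def upgma_dendrogram(D: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) dendrogram of a distance matrix."""
    if D.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 species for a dendrogram")
    Z = hierarchy.linkage(squareform(D.data, checks=False), method="average")
    return Dendrogram(linkage=Z, labels=list(D.ids))
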