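"""Spatial machinery: quadrat grids at multiple scales, lattice neighbour
graphs, Moran's I permutation tests, Moran's eigenvector maps (the spatial
basis S), environment aggregation across scales, and an intercept-only
simultaneous-autoregressive (SAR) error model for spatially corrected
tests of a mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy import stats

from .errors import (
    DegenerateInputError,
    DisconnectedGraphError,
    FitError,
    InvalidArgumentError,
)

_TOL = 1e-9


def _divisions(length: float, scale: float, dim_name: str) -> int:
    n = length / scale
    if abs(n - round(n)) > _TOL or round(n) < 1:
        raise InvalidArgumentError(
            f"quadrat side {scale} m does not divide plot {dim_name} {length} m"
        )
    return int(round(n))


@dataclass
class QuadratGrid:
    """Square quadrats tiling a rectangular plot.

    Quadrat ids are row-major from the plot origin: id = iy * n_x + ix,
    labelled ``q<index>``.
    """

    plot_width: float
    plot_height: float
    scale: float
    n_x: int = field(init=False)
    n_y: int = field(init=False)

    def __post_init__(self):
        self.n_x = _divisions(self.plot_width, self.scale, "width")
        self.n_y = _divisions(self.plot_height, self.scale, "height")

    @property
    def n_quadrats(self) -> int:
        return self.n_x * self.n_y

    @property
    def quadrat_ids(self) -> list[str]:
        return [f"q{i:04d}" for i in range(self.n_quadrats)]

    @property
    def centroids(self) -> np.ndarray:
        ix = np.arange(self.n_x)
        iy = np.arange(self.n_y)
        gx, gy = np.meshgrid(ix, iy)  # row-major: y outer, x inner
        cx = (gx.ravel() + 0.5) * self.scale
        cy = (gy.ravel() + 0.5) * self.scale
        return np.column_stack([cx, cy])

    def quadrat_index(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Half-open assignment [x, x+s); stems are pre-validated in
        [0, width) x [0, height) so no clipping is needed."""
        ix = np.floor(np.asarray(x) / self.scale).astype(int)
        iy = np.floor(np.asarray(y) / self.scale).astype(int)
        return iy * self.n_x + ix


@dataclass
class NeighborGraph:
    """Binary contiguity over quadrats plus its row-standardized weights."""

    adjacency: np.ndarray
    ids: list[str]
    style: str = "queen"

    def __post_init__(self):
        A = self.adjacency
        if not np.allclose(A, A.T):
            raise InvalidArgumentError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise InvalidArgumentError("adjacency must have a zero diagonal")

    @classmethod
    def from_grid(cls, grid: QuadratGrid, style: str = "queen") -> "NeighborGraph":
        nx, ny = grid.n_x, grid.n_y
        n = nx * ny
        A = np.zeros((n, n))
        if style == "rook":
            offsets = [(1, 0), (0, 1)]
        elif style == "queen":
            offsets = [(1, 0), (0, 1), (1, 1), (1, -1)]
        else:
            raise InvalidArgumentError(f"unknown neighbour style {style!r}")
        for iy in range(ny):
            for ix in range(nx):
                i = iy * nx + ix
                for dx, dy in offsets:
                    jx, jy = ix + dx, iy + dy
                    if 0 <= jx < nx and 0 <= jy < ny:
                        j = jy * nx + jx
                        A[i, j] = A[j, i] = 1.0
        return cls(adjacency=A, ids=grid.quadrat_ids, style=style)

    @property
    def row_standardized(self) -> np.ndarray:
        rs = self.adjacency.sum(axis=1)
        W = self.adjacency.copy()
        nz = rs > 0
        W[nz] = W[nz] / rs[nz, None]
        return W

    def assert_connected(self):
        ncomp, labels = connected_components(
            csr_matrix(self.adjacency), directed=False
        )
        if ncomp > 1:
            sizes = np.bincount(labels)
            raise DisconnectedGraphError(
                f"neighbour graph has {ncomp} components with sizes "
                f"{sizes.tolist()}"
            )


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def partition(stem_map, scale: float) -> tuple[QuadratGrid, pd.DataFrame]:
    """Quadrat grid at the given scale plus the site-by-species abundance
    table L; the grand total of L equals the stem count."""
    grid = QuadratGrid(stem_map.plot_width, stem_map.plot_height, scale)
    df = stem_map.data
    q = grid.quadrat_index(df["x"].values, df["y"].values)
    species = pd.Categorical(df["species"])
    counts = pd.crosstab(
        pd.Categorical(q, categories=range(grid.n_quadrats)), species, dropna=False
    )
    counts.index = grid.quadrat_ids
    counts.columns = list(counts.columns)
    return grid, counts.astype(float)


def aggregate_to_scale(
    values: pd.DataFrame, fine_grid: QuadratGrid, coarse_grid: QuadratGrid
) -> pd.DataFrame:
    """Mean of constituent fine-scale quadrat values per coarse quadrat
    (how environmental fields generated at 10 m are carried to 20/50/100 m).
    """
    if coarse_grid.scale % fine_grid.scale > _TOL:
        raise InvalidArgumentError(
            "coarse scale must be a multiple of the fine scale"
        )
    cent = fine_grid.centroids
    parent = coarse_grid.quadrat_index(cent[:, 0], cent[:, 1])
    out = (
        pd.DataFrame(values.values, index=parent, columns=values.columns)
        .groupby(level=0)
        .mean()
    )
    out.index = [coarse_grid.quadrat_ids[i] for i in out.index]
    return out.reindex(coarse_grid.quadrat_ids)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    I: float
    expected: float
    p: float
    n_perm: int


def morans_i(
    values: np.ndarray,
    graph: NeighborGraph,
    n_perm: int = 999,
    seed: int = 0,
    weights: str = "row",
) -> MoranResult:
    """Moran's I with a two-sided permutation test.

    ``weights``: "row" uses the row-standardized matrix (default),
    "binary" the raw adjacency.
    """
    v = np.asarray(values, float)
    n = len(v)
    if n < 3:
        raise InvalidArgumentError("need at least 3 quadrats")
    if np.ptp(v) == 0:
        raise DegenerateInputError("values are constant; Moran's I undefined")
    W = graph.row_standardized if weights == "row" else graph.adjacency
    Ws = csr_matrix(W)
    wsum = W.sum()

    def stat(z: np.ndarray) -> float:
        return float(n / wsum * (z @ (Ws @ z)) / (z @ z))

    z = v - v.mean()
    obs = stat(z)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        if abs(stat(zp) - expected) >= abs(obs - expected) - 1e-15:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return MoranResult(I=obs, expected=expected, p=p, n_perm=n_perm)


def moran_table(
    env: pd.DataFrame, graph: NeighborGraph, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Moran's I and permutation p for every environmental variable
    (one row per variable; the per-scale screening table)."""
    rows = []
    for k, col in enumerate(env.columns):
        res = morans_i(env[col].values, graph, n_perm=n_perm, seed=seed + k)
        rows.append({"variable": col, "I": res.I, "expected": res.expected,
                     "p": res.p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Moran's eigenvector maps
# ---------------------------------------------------------------------------

@dataclass
class MEMBasis:
    vectors: pd.DataFrame  # quadrats x retained eigenvectors, orthonormal
    eigenvalues: np.ndarray


def mem_basis(
    grid_or_graph, style: str = "queen", keep: str = "positive"
) -> MEMBasis:
    """Moran's eigenvector maps: eigenvectors of the doubly-centered
    binary adjacency.

    ``keep="positive"`` (default) retains positive-eigenvalue vectors —
    positive spatial autocorrelation structures; ``keep="nonzero"`` returns
    the full non-trivial basis.  Columns are orthonormal and orthogonal to
    the constant vector.
    """
    graph = (
        grid_or_graph
        if isinstance(grid_or_graph, NeighborGraph)
        else NeighborGraph.from_grid(grid_or_graph, style=style)
    )
    graph.assert_connected()
    A = graph.adjacency
    n = A.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    eig, V = np.linalg.eigh(H @ A @ H)
    order = np.argsort(eig)[::-1]
    eig, V = eig[order], V[:, order]
    tol = 1e-8 * max(np.abs(eig).max(), 1e-300)
    if keep == "positive":
        mask = eig > tol
    elif keep == "nonzero":
        mask = np.abs(eig) > tol
    else:
        raise InvalidArgumentError(f"unknown retention mode {keep!r}")
    V = V[:, mask]
    # deterministic sign: largest-|entry| positive
    if V.size:
        idx = np.argmax(np.abs(V), axis=0)
        s = np.sign(V[idx, np.arange(V.shape[1])])
        s[s == 0] = 1
        V = V * s
    cols = [f"MEM{k + 1}" for k in range(V.shape[1])]
    return MEMBasis(
        vectors=pd.DataFrame(V, index=graph.ids, columns=cols),
        eigenvalues=eig[mask],
    )


# ---------------------------------------------------------------------------
# SAR error model
# ---------------------------------------------------------------------------

@dataclass
class SARFit:
    rho: float
    intercept: float
    intercept_se: float
    intercept_p: float
    sigma2: float
    loglik: float


def fit_sar_error(values: np.ndarray, W: np.ndarray) -> SARFit:
    """Intercept-only SAR error model, y = mu + u with u = rho W u + eps,
    fit by profile maximum likelihood.

    The log-determinant uses the eigenvalues of W (real because W is a
    row-standardization of a symmetric binary matrix).  The intercept
    p-value is the spatially corrected two-sided test of mean = 0.
    """
    y = np.asarray(values, float)
    n = len(y)
    if n < 10:
        raise InvalidArgumentError("SAR fit needs at least 10 observations")
    W = np.asarray(W, float)
    rs = W.sum(axis=1)
    # eigenvalues via the symmetric similar matrix D^{-1/2} A D^{-1/2}
    lam = np.linalg.eigvals(W)
    lam = np.sort(lam.real)
    lo = 1.0 / lam[0] if lam[0] < 0 else -1.0 + 1e-6
    hi = 1.0 / lam[-1] if lam[-1] > 0 else 1.0 - 1e-6
    lo, hi = lo + 1e-6, hi - 1e-6
    one = np.ones(n)
    Wy, Wone = W @ y, W @ one

    def profile(rho: float) -> tuple[float, float, float]:
        ys, xs = y - rho * Wy, one - rho * Wone
        denom = xs @ xs
        mu = (xs @ ys) / denom
        resid = ys - mu * xs
        sigma2 = (resid @ resid) / n
        logdet = np.sum(np.log(np.abs(1.0 - rho * lam)))
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
        return ll, mu, sigma2

    res = minimize_scalar(
        lambda r: -profile(r)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise FitError(f"SAR profile likelihood failed: {res.message}")
    rho = float(res.x)
    ll, mu, sigma2 = profile(rho)
    xs = one - rho * Wone
    se = float(np.sqrt(sigma2 * n / (n - 2) / (xs @ xs)))
    t = mu / se
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return SARFit(
        rho=rho, intercept=float(mu), intercept_se=se, intercept_p=p,
        sigma2=float(sigma2), loglik=float(ll),
    )
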