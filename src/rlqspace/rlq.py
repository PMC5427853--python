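"""RLQ co-inertia analysis and its five-matrix extension.

``rlq_core`` is the classic three-table RLQ: singular value decomposition
of the cross-covariance between site attributes (R) and species attributes
(Q) mediated by the correspondence-analysis standardization of the
abundance table L.  ``extended_rlq`` concatenates environment with the
spatial (MEM) basis on the site side and trait-PCoA with phylogeny-PCoA
axes on the species side, each block rescaled to unit total inertia, so a
single pair of axes maximizes the joint environment/space x trait/phylogeny
covariance through L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidArgumentError
from .io import FiveMatrixBundle
from .ordination import pcoa, _fix_signs


@dataclass
class RLQResult:
    eigenvalues: np.ndarray  # non-increasing, >= 0
    site_scores: pd.DataFrame  # sites x axes
    species_scores: pd.DataFrame  # species x axes
    row_loadings: pd.DataFrame  # site-side variables x axes
    col_loadings: pd.DataFrame  # species-side variables x axes
    total_coinertia: float
    row_weights: pd.Series
    col_weights: pd.Series
    env_axis_correlations: pd.DataFrame | None = None
    spatial_axis_correlations: pd.DataFrame | None = None
    trait_axis_correlations: pd.DataFrame | None = None
    phylo_axis_correlations: pd.DataFrame | None = None
    site_score_components: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    @property
    def pct_variance(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues


# ---------------------------------------------------------------------------
# weighting helpers
# ---------------------------------------------------------------------------

def ca_weights(L: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CA row/column weights of L plus the CA-standardized table
    L0 = P/(r c^T) - 1."""
    N = L.values.astype(float)
    if (N < 0).any():
        raise InvalidArgumentError("L must be non-negative")
    total = N.sum()
    if total <= 0:
        raise DegenerateInputError("L is entirely zero")
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise DegenerateInputError("L has zero row or column margins")
    L0 = P / np.outer(r, c) - 1.0
    return r, c, L0


def weighted_center(X: np.ndarray, w: np.ndarray, scale: bool) -> np.ndarray:
    """Center (and optionally scale) columns under weights w; constant
    columns become zero rather than raising, so degenerate blocks vanish."""
    w = w / w.sum()
    Xc = X - w @ X
    if scale:
        sd = np.sqrt(w @ Xc**2)
        nz = sd > 0
        Xc[:, nz] = Xc[:, nz] / sd[nz]
        Xc[:, ~nz] = 0.0
    return Xc


def weighted_corr(x: np.ndarray, Y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation of x with each column of Y."""
    w = w / w.sum()
    xc = x - w @ x
    Yc = Y - w @ Y
    sx = np.sqrt(w @ xc**2)
    sy = np.sqrt(w @ Yc**2)
    cov = (w * xc) @ Yc
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (sx * sy)
    return np.where((sx > 0) & (sy > 0), r, 0.0)


# ---------------------------------------------------------------------------
# core RLQ
# ---------------------------------------------------------------------------

def rlq_core(
    R: pd.DataFrame,
    L: pd.DataFrame,
    Q: pd.DataFrame,
    scale_columns: bool = True,
    n_axes: int | None = None,
) -> RLQResult:
    """Classic RLQ: SVD of R~^T D_r L0 D_c Q~.

    R rows must match L rows, Q rows must match L columns.  R and Q are
    centered (and by default scaled) under the CA row/column weights of L.
    Eigenvalues are squared singular values; total co-inertia is their sum
    over the full rank.
    """
    if list(R.index) != list(L.index):
        raise InvalidArgumentError("R rows must match L rows (sites)")
    if list(Q.index) != list(L.columns):
        raise InvalidArgumentError("Q rows must match L columns (species)")
    r, c, L0 = ca_weights(L)
    Rt = weighted_center(R.values.astype(float), r, scale_columns)
    Qt = weighted_center(Q.values.astype(float), c, scale_columns)
    cross = Rt.T @ (r[:, None] * L0 * c[None, :]) @ Qt
    U, s, Vt = np.linalg.svd(cross, full_matrices=False)
    V = Vt.T
    total = float((s**2).sum())
    rank = int((s > 1e-12 * max(s[0], 1e-300)).sum()) if s.size else 0
    k = rank if n_axes is None else min(n_axes, len(s))
    U, V = U[:, :k], V[:, :k]
    U, V = _fix_signs(U, V)
    axes = [f"AxR{i + 1}" for i in range(k)]
    site_scores = Rt @ U
    species_scores = Qt @ V
    return RLQResult(
        eigenvalues=s**2,
        site_scores=pd.DataFrame(site_scores, index=L.index, columns=axes),
        species_scores=pd.DataFrame(species_scores, index=L.columns, columns=axes),
        row_loadings=pd.DataFrame(U, index=R.columns, columns=axes),
        col_loadings=pd.DataFrame(V, index=Q.columns, columns=axes),
        total_coinertia=total,
        row_weights=pd.Series(r, index=L.index),
        col_weights=pd.Series(c, index=L.columns),
        extras={"singular_values": s, "R_std": Rt, "Q_std": Qt},
    )


def total_coinertia(R: pd.DataFrame, L: pd.DataFrame, Q: pd.DataFrame,
                    scale_columns: bool = True) -> float:
    """Frobenius norm squared of the RLQ cross matrix (no SVD); used by
    permutation tests."""
    r, c, L0 = ca_weights(L)
    Rt = weighted_center(R.values.astype(float), r, scale_columns)
    Qt = weighted_center(Q.values.astype(float), c, scale_columns)
    cross = Rt.T @ (r[:, None] * L0 * c[None, :]) @ Qt
    return float((cross**2).sum())


# ---------------------------------------------------------------------------
# block preparation for the extension
# ---------------------------------------------------------------------------

def _unit_inertia_block(X: np.ndarray, w: np.ndarray, standardize: bool) -> np.ndarray:
    """Center columns under w (optionally scale each to unit variance),
    then rescale the whole block so its weighted total inertia is 1."""
    Xc = weighted_center(X, w, scale=standardize)
    inertia = float((w / w.sum()) @ (Xc**2) @ np.ones(Xc.shape[1]))
    if inertia <= 0:
        return np.zeros_like(Xc)
    return Xc / np.sqrt(inertia)


def pcoa_axes(D, var_threshold: float = 0.95, max_axes: int | None = None) -> pd.DataFrame:
    """PCoA axes of a distance matrix retaining the smallest number of
    axes reaching ``var_threshold`` of the positive (corrected) inertia."""
    res = pcoa(D)
    coords = res.row_scores
    prop = res.proportion_explained[: coords.shape[1]]
    cum = np.cumsum(prop)
    k = int(np.searchsorted(cum, var_threshold) + 1)
    k = min(k, coords.shape[1])
    if max_axes is not None:
        k = min(k, max_axes)
    return coords.iloc[:, :k]


def extended_rlq(
    bundle: FiveMatrixBundle,
    n_axes: int = 4,
    pcoa_var_threshold: float = 0.95,
    trait_table: pd.DataFrame | None = None,
) -> RLQResult:
    """Five-matrix RLQ: site side [standardized E | MEM basis], species
    side [trait-PCoA axes | phylogeny-PCoA axes], each block at unit total
    inertia, analysed with ``rlq_core``.

    Reports per-variable correlations of every environmental variable,
    spatial basis vector, trait (if ``trait_table`` is given, else the
    trait-PCoA axes) and phylogeny-PCoA axis with each RLQ axis, and the
    decomposition of site scores into their environment and space parts.
    """
    L = bundle.L
    r, c, _ = ca_weights(L)

    E = bundle.E.values.astype(float)
    S = bundle.S.values.astype(float)
    Taxes = pcoa_axes(bundle.T, pcoa_var_threshold)
    Paxes = pcoa_axes(bundle.P, pcoa_var_threshold)
    # order PCoA axis rows by L's species order
    Taxes = Taxes.loc[bundle.species_ids]
    Paxes = Paxes.loc[bundle.species_ids]

    Eb = _unit_inertia_block(E, r, standardize=True)
    Sb = _unit_inertia_block(S, r, standardize=False)
    Tb = _unit_inertia_block(Taxes.values, c, standardize=False)
    Pb = _unit_inertia_block(Paxes.values, c, standardize=False)

    e_cols = [f"E:{v}" for v in bundle.E.columns]
    s_cols = [f"S:{v}" for v in bundle.S.columns]
    t_cols = [f"T:{v}" for v in Taxes.columns]
    p_cols = [f"P:{v}" for v in Paxes.columns]
    R = pd.DataFrame(np.hstack([Eb, Sb]), index=L.index, columns=e_cols + s_cols)
    Q = pd.DataFrame(np.hstack([Tb, Pb]), index=L.columns, columns=t_cols + p_cols)

    res = rlq_core(R, L, Q, scale_columns=False, n_axes=n_axes)
    k = res.site_scores.shape[1]
    axes = list(res.site_scores.columns)

    site = res.site_scores.values
    spp = res.species_scores.values

    def corr_table(raw: pd.DataFrame, scores: np.ndarray, w: np.ndarray):
        M = np.column_stack(
            [weighted_corr(scores[:, a], raw.values.astype(float), w) for a in range(k)]
        ) if k else np.zeros((raw.shape[1], 0))
        # note: weighted_corr(x, Y, w) returns per-column-of-Y; transpose shape
        return pd.DataFrame(M, index=raw.columns, columns=axes)

    res.env_axis_correlations = corr_table(bundle.E, site, r)
    res.spatial_axis_correlations = corr_table(bundle.S, site, r)
    if trait_table is not None:
        tt = trait_table.loc[bundle.species_ids]
        res.trait_axis_correlations = corr_table(tt, spp, c)
    else:
        res.trait_axis_correlations = corr_table(Taxes, spp, c)
    res.phylo_axis_correlations = corr_table(Paxes, spp, c)

    # site-score decomposition into environment and space combinations
    nE = len(e_cols)
    U = res.row_loadings.values
    res.site_score_components = {
        "environment": pd.DataFrame(
            Eb @ U[:nE], index=L.index, columns=axes
        ),
        "space": pd.DataFrame(Sb @ U[nE:], index=L.index, columns=axes),
    }
    res.extras.update(
        {"trait_axes": Taxes, "phylo_axes": Paxes, "R_table": R, "Q_table": Q}
    )
    return res


def axis_summary(result: RLQResult, axis: int = 0) -> dict:
    """Per-variable correlation tables and signed per-site scores for one
    axis (the map/figure surface).  Correlations are bounded in [-1, 1];
    flipping the axis sign flips every entry."""
    if axis >= result.site_scores.shape[1]:
        raise InvalidArgumentError(
            f"axis {axis} not available ({result.site_scores.shape[1]} axes)"
        )
    col = result.site_scores.columns[axis]
    tables = {}
    for name, tab in (
        ("environment", result.env_axis_correlations),
        ("spatial", result.spatial_axis_correlations),
        ("traits", result.trait_axis_correlations),
        ("phylogeny", result.phylo_axis_correlations),
    ):
        if tab is not None:
            t = tab[[col]].copy()
            t.columns = ["correlation"]
            tables[name] = t.sort_values("correlation", key=np.abs, ascending=False)
    scores = result.site_scores[col]
    site_table = pd.DataFrame(
        {"score": scores, "sign": np.where(scores >= 0, "positive", "negative")}
    )
    return {"correlations": tables, "site_scores": site_table, "axis": col}
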