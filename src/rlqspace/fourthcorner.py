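"""Fourth-corner statistics and permutation tests.

The fourth-corner statistic links one site-side variable with one
species-side variable through the abundance table L: it is the Pearson
correlation computed on the individual-level inflated table, equivalently
the CA-weighted cross product of the standardized variables.  Null model 2
permutes the rows of L (breaks the environment-species link), null model 4
permutes its columns (breaks the trait link); the combined test takes the
maximum of the two p-values, which stays conservative when either link is
absent.  Global matrix-pair tests report the observed total co-inertia
(Obs), its standardized effect size (SES) against the pooled null, and the
combined P — the Table-1-shaped output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidArgumentError
from .io import FiveMatrixBundle
from .rlq import _unit_inertia_block, ca_weights, weighted_center, pcoa_axes

MODELS = (2, 4)


def _standardize(x: np.ndarray, w: np.ndarray, what: str) -> np.ndarray:
    w = w / w.sum()
    xc = x - w @ x
    sd = np.sqrt(w @ xc**2)
    if sd <= 0:
        raise DegenerateInputError(f"{what} has zero variance after weighting")
    return xc / sd


def fourth_corner_stat(
    r_var: np.ndarray, q_var: np.ndarray, L: pd.DataFrame | np.ndarray
) -> float:
    """Abundance-weighted correlation of a site variable with a species
    variable through L."""
    N = np.asarray(L, float)
    if (N < 0).any():
        raise InvalidArgumentError("L must be non-negative")
    total = N.sum()
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    rs = _standardize(np.asarray(r_var, float), r, "site variable")
    qs = _standardize(np.asarray(q_var, float), c, "species variable")
    return float(rs @ P @ qs)


def stat_matrix(R: pd.DataFrame, Q: pd.DataFrame, L: pd.DataFrame) -> np.ndarray:
    """All pairwise fourth-corner statistics at once (site variables x
    species variables); degenerate variables yield 0 rather than raising,
    as permuted tables can produce them transiently."""
    N = np.asarray(L, float)
    total = N.sum()
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Rt = weighted_center(np.asarray(R, float), r, scale=True)
    Qt = weighted_center(np.asarray(Q, float), c, scale=True)
    L0 = P / np.outer(r, c) - 1.0
    return Rt.T @ (r[:, None] * L0 * c[None, :]) @ Qt


@dataclass
class PermutationTest:
    obs: float | np.ndarray
    p: float | np.ndarray
    null: np.ndarray
    model: int


def permute_test(stat_fn, L: pd.DataFrame, model: int, n_perm: int = 999,
                 seed: int = 0):
    """Generic permutation test on a statistic of L.

    ``model`` 2 permutes rows of L (sites), 4 permutes columns (species);
    two-sided p = (#{|stat_null| >= |stat_obs|} + 1) / (n_perm + 1) applied
    elementwise when the statistic is an array.
    """
    if n_perm < 99:
        raise InvalidArgumentError("n_perm must be at least 99")
    if model not in MODELS:
        raise InvalidArgumentError(f"unknown null model {model}")
    rng = np.random.default_rng(seed)
    obs = np.asarray(stat_fn(L), float)
    exceed = np.zeros_like(obs)
    null = np.empty((n_perm,) + obs.shape)
    n_sites, n_species = L.shape
    for b in range(n_perm):
        if model == 2:
            perm = rng.permutation(n_sites)
            Lp = L.iloc[perm].set_axis(L.index)
        else:
            perm = rng.permutation(n_species)
            Lp = L.iloc[:, perm].set_axis(L.columns, axis=1)
        st = np.asarray(stat_fn(Lp), float)
        null[b] = st
        exceed += np.abs(st) >= np.abs(obs) - 1e-15
    p = (exceed + 1.0) / (n_perm + 1.0)
    return PermutationTest(
        obs=obs if obs.shape else float(obs),
        p=p if p.shape else float(p),
        null=null,
        model=model,
    )


def fourth_corner_table(
    R: pd.DataFrame,
    Q: pd.DataFrame,
    L: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-pair fourth-corner statistics with model-2, model-4 and
    combined p-values plus a Holm adjustment of the combined p across the
    variable grid."""
    fn = lambda Lp: stat_matrix(R, Q, Lp)
    t2 = permute_test(fn, L, model=2, n_perm=n_perm, seed=seed)
    t4 = permute_test(fn, L, model=4, n_perm=n_perm, seed=seed + 1)
    obs = np.asarray(t2.obs)
    p2, p4 = np.asarray(t2.p), np.asarray(t4.p)
    p_comb = np.maximum(p2, p4)
    rows = []
    for i, rv in enumerate(R.columns):
        for j, qv in enumerate(Q.columns):
            rows.append(
                {
                    "site_variable": rv,
                    "species_variable": qv,
                    "stat": obs[i, j],
                    "p_model2": p2[i, j],
                    "p_model4": p4[i, j],
                    "p_combined": p_comb[i, j],
                }
            )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_combined"].values)
    return out


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# global matrix-pair tests (Table-1 shape)
# ---------------------------------------------------------------------------

PAIRS = ("R and Q", "E and T", "E and P", "S and T", "S and P")


@dataclass
class GlobalTestResult:
    pair: str
    obs: float
    ses: float
    p: float
    p_model2: float
    p_model4: float
    n_perm: int


def _blocks(bundle: FiveMatrixBundle, pcoa_var_threshold: float = 0.95):
    Taxes = pcoa_axes(bundle.T, pcoa_var_threshold).loc[bundle.species_ids]
    Paxes = pcoa_axes(bundle.P, pcoa_var_threshold).loc[bundle.species_ids]
    return {
        "E": bundle.E,
        "S": bundle.S,
        "T": Taxes,
        "P": Paxes,
    }


def block_coinertia(
    site_blocks: list[tuple[pd.DataFrame, bool]],
    species_blocks: list[tuple[pd.DataFrame, bool]],
    L: pd.DataFrame,
) -> float:
    """Total co-inertia between concatenated site-side and species-side
    blocks through L, with the RLQ block preparation: each (table,
    standardize) block is centered under the CA weights (per-variable
    scaled when ``standardize``) and rescaled to unit total inertia, so
    ordination axes keep their inertia weighting and no block dominates a
    priori."""
    r, c, L0 = ca_weights(L)
    R = np.hstack(
        [_unit_inertia_block(np.asarray(X, float), r, standardize=std)
         for X, std in site_blocks]
    )
    Q = np.hstack(
        [_unit_inertia_block(np.asarray(X, float), c, standardize=std)
         for X, std in species_blocks]
    )
    cross = R.T @ (r[:, None] * L0 * c[None, :]) @ Q
    return float((cross**2).sum())


def global_association(
    bundle: FiveMatrixBundle,
    side_pair: str,
    n_perm: int = 999,
    seed: int = 0,
    pcoa_var_threshold: float = 0.95,
) -> GlobalTestResult:
    """Global fourth-corner test of one matrix pair through L.

    ``side_pair`` is one of "E and T", "E and P", "S and T", "S and P" or
    "R and Q" (both site blocks against both species blocks).  Obs is the
    total co-inertia (sum of squared pairwise statistics); SES uses the
    pooled model-2 + model-4 null; P = max(p_model2, p_model4).
    """
    if side_pair not in PAIRS:
        raise InvalidArgumentError(
            f"side_pair must be one of {PAIRS}, got {side_pair!r}"
        )
    blocks = _blocks(bundle, pcoa_var_threshold)
    std = {"E": True, "S": False, "T": False, "P": False}
    if side_pair == "R and Q":
        site = [(blocks["E"], True), (blocks["S"], False)]
        species = [(blocks["T"], False), (blocks["P"], False)]
    else:
        left, right = side_pair.split(" and ")
        site = [(blocks[left], std[left])]
        species = [(blocks[right], std[right])]

    fn = lambda Lp: block_coinertia(site, species, Lp)
    t2 = permute_test(fn, bundle.L, model=2, n_perm=n_perm, seed=seed)
    t4 = permute_test(fn, bundle.L, model=4, n_perm=n_perm, seed=seed + 1)
    # co-inertia is non-negative: one-sided upper-tail p
    p2 = (np.sum(t2.null >= t2.obs - 1e-15) + 1.0) / (n_perm + 1.0)
    p4 = (np.sum(t4.null >= t4.obs - 1e-15) + 1.0) / (n_perm + 1.0)
    pooled = np.concatenate([t2.null, t4.null])
    sd = pooled.std(ddof=1)
    ses = float((t2.obs - pooled.mean()) / sd) if sd > 0 else 0.0
    return GlobalTestResult(
        pair=side_pair,
        obs=float(t2.obs),
        ses=ses,
        p=float(max(p2, p4)),
        p_model2=float(p2),
        p_model4=float(p4),
        n_perm=n_perm,
    )


def global_table(
    bundle: FiveMatrixBundle,
    scale: float,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """All five matrix-pair tests at one scale; one row per pair with
    columns scale, pair, Obs, SES, P (the Table-1 schema)."""
    rows = []
    for k, pair in enumerate(PAIRS):
        res = global_association(bundle, pair, n_perm=n_perm, seed=seed + 10 * k)
        rows.append(
            {
                "scale": scale,
                "pair": pair,
                "Obs": res.obs,
                "SES": res.ses,
                "P": res.p,
                "p_model2": res.p_model2,
                "p_model4": res.p_model4,
            }
        )
    return pd.DataFrame(rows)
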