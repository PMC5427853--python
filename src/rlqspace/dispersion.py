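"""Phylogenetic and functional dispersion statistics.

Abundance-weighted mean pairwise distance (MPD) per quadrat, a pool-wide
tip-shuffle null model (one label permutation per iteration applied to the
whole species pool, preserving abundance, frequency and occurrence), and
the sign-flipped standardized effect sizes

    NRI      = -1 * (MPD_obs - mean(MPD_null)) / sd(MPD_null)
    S.E.S.PW = -1 * (PW_obs  - mean(PW_null))  / sd(PW_null)

so positive values mean clustering and negative values overdispersion.
NRI uses patristic distances of the phylogeny; S.E.S. PW uses cophenetic
distances of the UPGMA trait dendrogram.  Axis-side summaries split
quadrats by the sign of their RLQ axis-1 score and test each side's mean
index against zero (Student's t, optionally SAR-corrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .errors import InvalidArgumentError
from .spatial import NeighborGraph, fit_sar_error


def _align(L: pd.DataFrame, D: DistanceMatrix) -> np.ndarray:
    ids = list(L.columns)
    missing = set(ids) - set(D.ids)
    if missing:
        raise InvalidArgumentError(
            f"species missing from distance matrix: {sorted(missing)[:5]}"
        )
    return D.filter(ids).data


def mpd(abundances: np.ndarray, D: np.ndarray) -> float:
    """Abundance-weighted mean pairwise distance for one quadrat;
    conspecific pairs are excluded.  NaN when fewer than 2 species are
    present."""
    f = np.asarray(abundances, float)
    tot = f.sum()
    if (f > 0).sum() < 2:
        return float("nan")
    f = f / tot
    num = f @ D @ f  # diagonal of D is zero, so i = j terms vanish
    den = 1.0 - (f**2).sum()
    return float(num / den)


def mpd_profile(L: pd.DataFrame, D: DistanceMatrix) -> pd.Series:
    """MPD for every quadrat at once (NaN where < 2 species occur)."""
    Dm = _align(L, D)
    F = L.values.astype(float)
    tot = F.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(tot > 0, F / tot, 0.0)
    num = np.einsum("qi,ij,qj->q", F, Dm, F)
    den = 1.0 - (F**2).sum(axis=1)
    vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    vals = np.where((L.values > 0).sum(axis=1) >= 2, vals, np.nan)
    return pd.Series(vals, index=L.index, name="MPD")


@dataclass
class NullMoments:
    mean: pd.Series
    sd: pd.Series
    n_iter: int


def tip_shuffle_null(
    L: pd.DataFrame, D: DistanceMatrix, n_iter: int = 999, seed: int = 0
) -> NullMoments:
    """Null MPD moments per quadrat from pool-wide tip-label shuffles.

    Each iteration applies a single permutation of species labels to the
    distance matrix (equivalently to the tree/dendrogram tips) and
    recomputes MPD for every quadrat; L itself is never touched.
    """
    if n_iter < 99:
        raise InvalidArgumentError("n_iter must be at least 99")
    Dm = _align(L, D)
    F = L.values.astype(float)
    tot = F.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(tot > 0, F / tot, 0.0)
    den = 1.0 - (F**2).sum(axis=1)
    ok = (L.values > 0).sum(axis=1) >= 2
    rng = np.random.default_rng(seed)
    n_species = Dm.shape[0]
    draws = np.empty((n_iter, L.shape[0]))
    for b in range(n_iter):
        perm = rng.permutation(n_species)
        Dp = Dm[np.ix_(perm, perm)]
        num = np.einsum("qi,ij,qj->q", F, Dp, F)
        draws[b] = np.where(ok & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)
    return NullMoments(
        mean=pd.Series(draws.mean(axis=0), index=L.index),
        sd=pd.Series(draws.std(axis=0, ddof=1), index=L.index),
        n_iter=n_iter,
    )


def standardized_effect(
    obs, mean_null, sd_null
) -> tuple[np.ndarray, np.ndarray]:
    """-1 * (obs - mean_null) / sd_null, with index 0 and a degeneracy
    flag wherever sd_null = 0 (shuffle-invariant distances)."""
    obs = np.asarray(obs, float)
    mean_null = np.asarray(mean_null, float)
    sd_null = np.asarray(sd_null, float)
    if (sd_null < 0).any():
        raise InvalidArgumentError("sd_null must be non-negative")
    # tolerance absorbs float noise of shuffle-invariant (star-tree) nulls
    degenerate = sd_null <= 1e-12 * np.maximum(1.0, np.abs(mean_null))
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = -1.0 * (obs - mean_null) / sd_null
    idx = np.where(degenerate, 0.0, idx)
    return idx, degenerate


def nri(mpd_obs, mean_null, sd_null):
    """Net relatedness index (phylogenetic MPD version)."""
    return standardized_effect(mpd_obs, mean_null, sd_null)


def ses_pw(pw_obs, mean_null, sd_null):
    """Standardized effect size of the dendrogram-based trait distance."""
    return standardized_effect(pw_obs, mean_null, sd_null)


@dataclass
class DispersionResult:
    per_quadrat: pd.DataFrame  # MPD_obs, PW_obs, null moments, NRI, SES_PW
    n_iter: int
    n_undefined: int  # quadrats with < 2 species (excluded from aggregates)


def dispersion_analysis(
    L: pd.DataFrame,
    phylo_distances: DistanceMatrix,
    trait_distances: DistanceMatrix,
    n_iter: int = 999,
    seed: int = 0,
) -> DispersionResult:
    """NRI and S.E.S. PW for every quadrat against tip-shuffle nulls.

    ``phylo_distances`` are patristic distances; ``trait_distances`` the
    cophenetic distances of the trait dendrogram.
    """
    out = pd.DataFrame(index=L.index)
    out["MPD_obs"] = mpd_profile(L, phylo_distances)
    out["PW_obs"] = mpd_profile(L, trait_distances)
    null_p = tip_shuffle_null(L, phylo_distances, n_iter=n_iter, seed=seed)
    null_t = tip_shuffle_null(L, trait_distances, n_iter=n_iter, seed=seed + 1)
    out["MPD_null_mean"], out["MPD_null_sd"] = null_p.mean, null_p.sd
    out["PW_null_mean"], out["PW_null_sd"] = null_t.mean, null_t.sd
    nri_vals, nri_flag = nri(out["MPD_obs"], null_p.mean, null_p.sd)
    pw_vals, pw_flag = ses_pw(out["PW_obs"], null_t.mean, null_t.sd)
    out["NRI"] = nri_vals
    out["SES_PW"] = pw_vals
    out["degenerate_null"] = nri_flag | pw_flag
    n_undef = int(out["MPD_obs"].isna().sum())
    return DispersionResult(per_quadrat=out, n_iter=n_iter, n_undefined=n_undef)


def axis_side_summary(
    indices: pd.Series,
    site_scores: pd.Series,
    scale: float,
    graph: NeighborGraph | None = None,
) -> pd.DataFrame:
    """Mean dispersion index per RLQ axis side with one-sample t-tests.

    Quadrats are split by the sign of their axis-1 site score; each side's
    mean index is tested against zero with a two-sided Student's t-test
    and, when a neighbour graph is supplied, with the intercept test of a
    SAR error model on that side's sub-lattice.  Sides with fewer than 3
    defined quadrats are reported as undefined.
    """
    indices, site_scores = indices.align(site_scores, join="inner")
    rows = []
    for side, mask in (
        ("positive", site_scores >= 0),
        ("negative", site_scores < 0),
    ):
        vals = indices[mask].dropna()
        row = {"scale": scale, "side": side, "n": len(vals)}
        if len(vals) < 3 or np.allclose(vals.std(ddof=1), 0.0):
            row.update({"mean": vals.mean() if len(vals) else np.nan,
                        "t": np.nan, "p": np.nan, "sar_rho": np.nan,
                        "sar_p": np.nan})
            rows.append(row)
            continue
        t, p = stats.ttest_1samp(vals, 0.0)
        row.update({"mean": float(vals.mean()), "t": float(t), "p": float(p)})
        if graph is not None:
            pos = [graph.ids.index(q) for q in vals.index]
            A = graph.adjacency[np.ix_(pos, pos)]
            sub = NeighborGraph(adjacency=A, ids=list(vals.index),
                                style=graph.style)
            try:
                fit = fit_sar_error(vals.values, sub.row_standardized)
                row.update({"sar_rho": fit.rho, "sar_p": fit.intercept_p})
            except Exception:
                row.update({"sar_rho": np.nan, "sar_p": np.nan})
        else:
            row.update({"sar_rho": np.nan, "sar_p": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def dispersion_table(
    result: DispersionResult,
    site_scores: pd.Series,
    scale: float,
    graph: NeighborGraph | None = None,
) -> pd.DataFrame:
    """Table-2-shaped aggregate: one row per axis side with mean S.E.S. PW
    and mean NRI plus their tests."""
    nri_sum = axis_side_summary(
        result.per_quadrat["NRI"], site_scores, scale, graph
    ).add_prefix("NRI_").rename(columns={"NRI_scale": "scale", "NRI_side": "side",
                                         "NRI_n": "n_NRI"})
    pw_sum = axis_side_summary(
        result.per_quadrat["SES_PW"], site_scores, scale, graph
    ).add_prefix("SES_PW_").rename(columns={"SES_PW_scale": "scale",
                                            "SES_PW_side": "side",
                                            "SES_PW_n": "n_SES_PW"})
    return pw_sum.merge(nri_sum, on=["scale", "side"])
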