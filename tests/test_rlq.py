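"""RLQ core and the five-matrix extension against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from rlqspace.errors import InvalidArgumentError
from rlqspace.io import align_bundle
from rlqspace.ordination import correspondence_analysis, gower_distance, \
    patristic_distance, upgma_dendrogram
from rlqspace.rlq import (
    axis_summary,
    ca_weights,
    extended_rlq,
    rlq_core,
    total_coinertia,
    weighted_center,
)
from rlqspace.spatial import mem_basis, partition
from conftest import random_abundance_table


def brute_force_cross(R, L, Q, scale=True):
    """Independent dense construction of the RLQ cross-covariance matrix."""
    N = L.values.astype(float)
    P = N / N.sum()
    r, c = P.sum(1), P.sum(0)
    Rt = weighted_center(R.values.astype(float), r, scale)
    Qt = weighted_center(Q.values.astype(float), c, scale)
    L0 = P / np.outer(r, c) - 1.0
    return Rt.T @ np.diag(r) @ L0 @ np.diag(c) @ Qt


class TestRLQCore:
    def test_eigenvalues_match_dense_svd_oracle(self, rng):
        L = random_abundance_table(rng, 6, 5)
        R = pd.DataFrame(rng.normal(size=(6, 3)), index=L.index)
        Q = pd.DataFrame(rng.normal(size=(5, 2)), index=L.columns)
        res = rlq_core(R, L, Q)
        cross = brute_force_cross(R, L, Q)
        expected = np.sort(np.linalg.svd(cross, compute_uv=False))[::-1] ** 2
        np.testing.assert_allclose(res.eigenvalues, expected, atol=1e-9)

    def test_ca_scores_as_R_and_Q_recover_ca_eigenvalues(self, rng):
        # with R = CA row scores and Q = CA column scores, RLQ picks up the
        # CA structure: first eigenvalue equals first CA eigenvalue cubed
        # (scores carry one factor of sqrt(lambda) each, the cross product
        # a third); verified against the brute-force SVD as the oracle
        L = random_abundance_table(rng, 5, 4)
        ca = correspondence_analysis(L)
        R, Q = ca.row_scores, ca.col_scores
        res = rlq_core(R, L, Q, scale_columns=False)
        cross = brute_force_cross(R, L, Q, scale=False)
        expected = np.sort(np.linalg.svd(cross, compute_uv=False))[::-1] ** 2
        np.testing.assert_allclose(
            res.eigenvalues[: len(expected)], expected, atol=1e-9
        )
        assert res.eigenvalues[0] == pytest.approx(ca.eigenvalues[0] ** 3, abs=1e-9)

    def test_constant_column_contributes_nothing(self, rng):
        L = random_abundance_table(rng, 5, 4)
        R = pd.DataFrame({"const": np.ones(5)}, index=L.index)
        Q = pd.DataFrame(rng.normal(size=(4, 2)), index=L.columns)
        res = rlq_core(R, L, Q)
        assert np.all(res.eigenvalues < 1e-15)

    def test_total_coinertia_invariant_under_rotation_of_R(self, rng):
        L = random_abundance_table(rng, 6, 5)
        R = pd.DataFrame(rng.normal(size=(6, 3)), index=L.index)
        Q = pd.DataFrame(rng.normal(size=(5, 3)), index=L.columns)
        t0 = total_coinertia(R, L, Q, scale_columns=False)
        O = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        R2 = pd.DataFrame(R.values @ O, index=L.index)
        t1 = total_coinertia(R2, L, Q, scale_columns=False)
        assert t1 == pytest.approx(t0, rel=1e-9)

    def test_first_axis_beats_random_unit_probes(self, rng):
        L = random_abundance_table(rng, 6, 5)
        R = pd.DataFrame(rng.normal(size=(6, 3)), index=L.index)
        Q = pd.DataFrame(rng.normal(size=(5, 3)), index=L.columns)
        res = rlq_core(R, L, Q, scale_columns=False)
        cross = brute_force_cross(R, L, Q, scale=False)
        best = np.sqrt(res.eigenvalues[0])
        for _ in range(199):
            u = rng.normal(size=3)
            v = rng.normal(size=3)
            u, v = u / np.linalg.norm(u), v / np.linalg.norm(v)
            assert abs(u @ cross @ v) <= best + 1e-12

    def test_dimension_mismatch_raises(self, rng):
        L = random_abundance_table(rng, 5, 4)
        R = pd.DataFrame(rng.normal(size=(4, 2)))
        Q = pd.DataFrame(rng.normal(size=(4, 2)), index=L.columns)
        with pytest.raises(InvalidArgumentError, match="R rows"):
            rlq_core(R, L, Q)


def _bundle_from(ds, scale=20.0):
    from rlqspace.io import natural_log_transform

    grid, L = partition(ds.stem_map, scale)
    from rlqspace.spatial import aggregate_to_scale

    env = aggregate_to_scale(ds.env.values, ds.env.grid, grid)
    env_t, _ = natural_log_transform(env)
    traits_t, _ = natural_log_transform(ds.traits)
    mem = mem_basis(grid)
    T = gower_distance(traits_t)
    P = patristic_distance(ds.phylogeny)
    return align_bundle(L, env_t, mem.vectors, T, P), traits_t


class TestExtendedRLQ:
    def test_zero_S_and_P_blocks_reduce_to_three_table_rlq(self, filtering_dataset):
        bundle, _ = _bundle_from(filtering_dataset)
        res = extended_rlq(bundle, n_axes=2)
        # degenerate blocks: zero spatial and phylo inputs vanish after
        # centering, so eigenvalues coincide with E x T-axes alone
        import rlqspace.rlq as rlqmod

        zeroS = bundle.S * 0.0
        from rlqspace.io import FiveMatrixBundle

        b2 = FiveMatrixBundle(L=bundle.L, E=bundle.E, S=zeroS, T=bundle.T,
                              P=bundle.P)
        res2 = extended_rlq(b2, n_axes=2)
        Taxes = rlqmod.pcoa_axes(bundle.T, 0.95).loc[bundle.species_ids]
        r, c, _ = ca_weights(bundle.L)
        Eb = rlqmod._unit_inertia_block(bundle.E.values, r, standardize=True)
        Tb = rlqmod._unit_inertia_block(Taxes.values, c, standardize=False)
        Pb = rlqmod.pcoa_axes(bundle.P, 0.95).loc[bundle.species_ids]
        Pb = rlqmod._unit_inertia_block(Pb.values, c, standardize=False)
        R3 = pd.DataFrame(Eb, index=bundle.L.index)
        Q3 = pd.DataFrame(np.hstack([Tb, Pb]), index=bundle.L.columns)
        res3 = rlq_core(R3, bundle.L, Q3, scale_columns=False, n_axes=2)
        np.testing.assert_allclose(
            res2.eigenvalues[:2], res3.eigenvalues[:2], atol=1e-9
        )

    def test_filtering_recovers_niche_pair_on_axis1(self, filtering_dataset):
        bundle, traits_t = _bundle_from(filtering_dataset)
        res = extended_rlq(bundle, n_axes=2, trait_table=traits_t)
        tcorr = res.trait_axis_correlations.iloc[:, 0]
        ecorr = res.env_axis_correlations.iloc[:, 0]
        niche_t = filtering_dataset.truth["niche_trait"]
        niche_e = filtering_dataset.truth["niche_env"]
        assert abs(tcorr[niche_t]) > 0.7
        # matched niche: trait and env correlations share their sign
        assert np.sign(tcorr[niche_t]) == np.sign(ecorr[niche_e])
        # the niche pair tops both |r| tables
        assert tcorr.abs().idxmax() == niche_t
        assert ecorr.abs().idxmax() == niche_e

    def test_neutral_axis1_within_permutation_envelope(self, neutral_dataset):
        bundle, _ = _bundle_from(neutral_dataset)
        res = extended_rlq(bundle, n_axes=1)
        obs = res.pct_variance[0]
        rng = np.random.default_rng(0)
        null = []
        from rlqspace.io import FiveMatrixBundle

        for _ in range(99):
            perm = rng.permutation(len(bundle.L))
            Lp = bundle.L.iloc[perm].set_axis(bundle.L.index)
            # keep margins aligned: permuting rows of L against fixed E/S
            bp = FiveMatrixBundle(L=Lp, E=bundle.E, S=bundle.S, T=bundle.T,
                                  P=bundle.P)
            null.append(extended_rlq(bp, n_axes=1).pct_variance[0])
        lo, hi = np.quantile(null, [0.005, 1.0])
        assert obs <= hi + 0.05  # inside the upper envelope

    def test_axis_summary_sign_symmetry(self, filtering_dataset):
        bundle, traits_t = _bundle_from(filtering_dataset)
        res = extended_rlq(bundle, n_axes=1, trait_table=traits_t)
        summ = axis_summary(res, axis=0)
        for tab in summ["correlations"].values():
            assert (tab["correlation"].abs() <= 1.0 + 1e-12).all()
        # flip the axis: correlations and site-score signs flip
        res.site_scores.iloc[:, 0] *= -1
        for name in ("env_axis_correlations", "spatial_axis_correlations",
                     "trait_axis_correlations", "phylo_axis_correlations"):
            setattr(res, name, getattr(res, name) * -1)
        summ2 = axis_summary(res, axis=0)
        np.testing.assert_allclose(
            summ2["site_scores"]["score"].values,
            -summ["site_scores"]["score"].values,
        )
        assert (
            summ2["correlations"]["environment"]["correlation"].values
            == -summ["correlations"]["environment"]["correlation"].values
        ).all()

    def test_requesting_axis_beyond_rank_raises(self, filtering_dataset):
        bundle, _ = _bundle_from(filtering_dataset)
        res = extended_rlq(bundle, n_axes=2)
        with pytest.raises(InvalidArgumentError):
            axis_summary(res, axis=10)
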