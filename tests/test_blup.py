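"""Mixed-model equations against dense GLS oracles and shrinkage limits."""

import numpy as np
import pandas as pd
import pytest

from pigbv import (
    VarianceComponents,
    a_inverse,
    additive_relationship_matrix,
    run_blup_scenario,
    simulate_pedigree,
    solve_mme_multi,
    solve_mme_single,
)
from pigbv.blup import ModelError, _incidence, build_fixed_design

from conftest import random_pedigree


def _single_gls_oracle(A, X, Z, y, s2a, s2e):
    V = Z @ A @ Z.T * s2a + np.eye(len(y)) * s2e
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = s2a * A @ Z.T @ Vi @ (y - X @ b)
    return u


def _random_instance(n_rec, seed):
    rng = np.random.default_rng(seed)
    ped = random_pedigree(n_rec + 50, seed=seed)
    ids = ped.ids
    rec_ids = list(rng.choice(ids, size=n_rec, replace=False))
    df = pd.DataFrame(
        {
            "cohort": rng.integers(0, 4, n_rec),
            "batch": rng.integers(0, 3, n_rec),
            "y": rng.normal(20, 3, n_rec),
        },
        index=rec_ids,
    )
    return ped, ids, df


class TestSingleTrait:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_gls_oracle(self, seed):
        ped, ids, df = _random_instance(150, seed)
        A = additive_relationship_matrix(ped).values
        Ainv = a_inverse(ped)
        s2a, s2e = 2.0, 3.5
        est = solve_mme_single(df, "y", Ainv, ids, s2a, s2e)
        X = build_fixed_design(df).matrix
        Z = _incidence(list(df.index), ids).toarray()
        u = _single_gls_oracle(A, X, Z, df["y"].to_numpy(), s2a, s2e)
        np.testing.assert_allclose(est.ebv["y"].to_numpy(), u, atol=1e-8)

    def test_infinite_shrinkage_limit(self):
        ped, ids, df = _random_instance(60, 4)
        est = solve_mme_single(df, "y", a_inverse(ped), ids, 1e-10, 1.0)
        assert np.abs(est.ebv["y"]).max() < 1e-6

    def test_single_record_regression_identity(self):
        # unrelated animals, one record each, intercept only:
        # EBV_i = h2 * (y_i - mean prediction)
        rng = np.random.default_rng(5)
        ped = random_pedigree(40, seed=0, p_unknown=1.0)  # founders only
        y = rng.normal(0, 1, 40)
        df = pd.DataFrame({"y": y}, index=ped.ids)
        h2 = 0.4
        est = solve_mme_single(df, "y", a_inverse(ped), ped.ids, h2, 1 - h2)
        mu = est.fixed["y"][("intercept", "")]
        np.testing.assert_allclose(est.ebv["y"].to_numpy(), h2 * (y - mu), atol=1e-10)

    def test_ebv_weighted_mean_zero_with_intercept_only(self):
        ped, ids, df = _random_instance(80, 6)
        df = df.drop(columns=["cohort", "batch"])
        Ainv = a_inverse(ped)
        est = solve_mme_single(df, "y", Ainv, ids, 1.0, 2.0)
        # summing the u-block MME rows: 1' (Z'Z u + Z'X b + lam Ainv u) = 1'Z'y
        # with intercept fit, the Ainv-weighted EBV total vanishes
        w = np.asarray(Ainv.sum(axis=0)).ravel()
        assert abs(w @ est.ebv["y"].to_numpy()) < 1e-6

    def test_nonpositive_variance_rejected(self):
        ped, ids, df = _random_instance(20, 7)
        with pytest.raises(ModelError):
            solve_mme_single(df, "y", a_inverse(ped), ids, -1.0, 1.0)


def _multi_gls_oracle(A, pos, df, traits, G0, R0):
    obs = [(a, k) for k, t in enumerate(traits) for a in df.index[df[t].notna()]]
    N = len(obs)
    V = np.zeros((N, N))
    for i, (ai, ki) in enumerate(obs):
        for j, (aj, kj) in enumerate(obs):
            V[i, j] = G0[ki, kj] * A[pos[ai], pos[aj]] + (
                R0[ki, kj] if ai == aj else 0.0
            )
    y = np.array([df.loc[a, traits[k]] for a, k in obs], dtype=float)
    designs = []
    for k, t in enumerate(traits):
        sub = df[df[t].notna()]
        designs.append((build_fixed_design(sub), list(sub.index)))
    p_tot = sum(d.matrix.shape[1] for d, _ in designs)
    X = np.zeros((N, p_tot))
    off = 0
    for k, (d, sids) in enumerate(designs):
        for i, (a, kk) in enumerate(obs):
            if kk == k:
                X[i, off:off + d.matrix.shape[1]] = d.matrix[sids.index(a)]
        off += d.matrix.shape[1]
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ b
    n = A.shape[0]
    U = np.zeros((n, len(traits)))
    for k in range(len(traits)):
        C = np.zeros((n, N))
        for j, (aj, kj) in enumerate(obs):
            C[:, j] = G0[k, kj] * A[:, pos[aj]]
        U[:, k] = C @ Vi @ resid
    return U


class TestMultiTrait:
    def test_diagonal_covariances_separable(self):
        rng = np.random.default_rng(8)
        ped = random_pedigree(120, seed=8)
        ids = ped.ids
        df = pd.DataFrame(
            {
                "cohort": rng.integers(0, 3, 90),
                "t1": rng.normal(0, 1, 90),
                "t2": rng.normal(0, 1, 90),
            },
            index=list(rng.choice(ids, 90, replace=False)),
        )
        df.loc[df.index[:20], "t2"] = np.nan
        vc = VarianceComponents(["t1", "t2"], np.diag([2.0, 1.0]), np.diag([3.0, 2.0]))
        Ainv = a_inverse(ped)
        est = solve_mme_multi(df, vc, Ainv, ids)
        e1 = solve_mme_single(df, "t1", Ainv, ids, 2.0, 3.0)
        e2 = solve_mme_single(df, "t2", Ainv, ids, 1.0, 2.0)
        np.testing.assert_allclose(est.ebv["t1"], e1.ebv["t1"], atol=1e-8)
        np.testing.assert_allclose(est.ebv["t2"], e2.ebv["t2"], atol=1e-8)

    @pytest.mark.parametrize("seed,missing", [(10, False), (11, True)])
    def test_matches_stacked_gls_oracle(self, seed, missing):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(130, seed=seed)
        ids = ped.ids
        pos = {a: i for i, a in enumerate(ids)}
        n_rec = 100
        rec_ids = list(rng.choice(ids, n_rec, replace=False))
        df = pd.DataFrame(
            {
                "cohort": rng.integers(0, 3, n_rec),
                "batch": rng.integers(0, 2, n_rec),
                "t1": rng.normal(5, 2, n_rec),
                "t2": rng.normal(-2, 1, n_rec),
            },
            index=rec_ids,
        )
        if missing:
            df.loc[df.index[rng.random(n_rec) < 0.3], "t1"] = np.nan
            df.loc[df.index[rng.random(n_rec) < 0.2], "t2"] = np.nan
            df = df[df[["t1", "t2"]].notna().any(axis=1)]
        G0 = np.array([[2.0, 0.7], [0.7, 1.5]])
        R0 = np.array([[3.0, 0.4], [0.4, 2.0]])
        vc = VarianceComponents(["t1", "t2"], G0, R0)
        est = solve_mme_multi(df, vc, a_inverse(ped), ids)
        A = additive_relationship_matrix(ped).values
        U = _multi_gls_oracle(A, pos, df, ["t1", "t2"], G0, R0)
        np.testing.assert_allclose(est.ebv[["t1", "t2"]].to_numpy(), U, atol=1e-8)

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(ModelError, match="positive definite"):
            VarianceComponents(["a", "b"], np.array([[1, 2], [2, 1]]), np.eye(2))

    def test_correlated_secondary_trait_moves_ebv(self, small_bundle):
        """Testing animals have BW/BF but no quality records in training:
        their quality EBVs shift under the multitrait model only when the
        genetic correlation is nonzero."""
        arch = small_bundle.architecture
        Ainv = a_inverse(small_bundle.pedigree)
        vc = VarianceComponents.from_architecture(arch, arch.traits)
        test_ids = small_bundle.testing_ids
        u = run_blup_scenario(small_bundle, "IMF", ("U", "NL"), vc, Ainv)
        m = run_blup_scenario(small_bundle, "IMF", ("M", "NL"), vc, Ainv)
        assert np.abs(m.ebv.loc[test_ids, "IMF"] - u.ebv.loc[test_ids, "IMF"]).max() > 1e-3

        # zero out the genetic correlation with BW/BF: EBVs of recordless
        # animals match the univariate ones
        vc0 = VarianceComponents.from_architecture(arch, arch.traits)
        i = vc0.traits.index("IMF")
        for t in ("BW", "BF"):
            j = vc0.traits.index(t)
            vc0.G0[i, j] = vc0.G0[j, i] = 0.0
            vc0.R0[i, j] = vc0.R0[j, i] = 0.0
        m0 = run_blup_scenario(small_bundle, "IMF", ("M", "NL"), vc0, Ainv)
        u0 = run_blup_scenario(small_bundle, "IMF", ("U", "NL"), vc0, Ainv)
        np.testing.assert_allclose(
            m0.ebv.loc[test_ids, "IMF"], u0.ebv.loc[test_ids, "IMF"], atol=1e-8
        )


class TestScenarios:
    def test_littermate_flag_changes_only_littermate_records(self, small_bundle):
        from pigbv.blup import scenario_records

        nl = scenario_records(small_bundle, "MUFA", False, False)
        l = scenario_records(small_bundle, "MUFA", True, False)
        extra = set(l[l["MUFA"].notna()].index) - set(nl[nl["MUFA"].notna()].index)
        assert extra == set(small_bundle.littermate_ids)

    def test_no_records_gives_prior_mean_zero(self, small_bundle):
        arch = small_bundle.architecture
        vc = VarianceComponents.from_architecture(arch, arch.traits)
        Ainv = a_inverse(small_bundle.pedigree)
        empty = small_bundle.phenotypes.copy()
        empty["MUFA"] = np.nan
        import dataclasses

        b = dataclasses.replace(small_bundle, phenotypes=empty)
        est = run_blup_scenario(b, "MUFA", ("U", "NL"), vc, Ainv)
        assert (est.ebv["MUFA"] == 0).all()

    def test_invalid_flags_rejected(self, small_bundle):
        arch = small_bundle.architecture
        vc = VarianceComponents.from_architecture(arch, arch.traits)
        with pytest.raises(ModelError):
            run_blup_scenario(small_bundle, "MUFA", ("X", "L"), vc, None)
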