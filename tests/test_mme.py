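"""Mixed-model equations: GLS oracle, solvers, structural identities."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla

from samblup.mme import (EBVTable, ModelError, ModelSpec, build_mme,
                         predict_index_inputs, solve_mme)
from samblup.params import VarianceComponentsAM
from samblup.pedigree import Pedigree


@pytest.fixture(scope="module")
def toy_system(ref_vc):
    sire = np.array([0, 0, 0, 0, 1, 1, 3, 3, 1, 3])
    dam = np.array([0, 0, 0, 0, 2, 2, 4, 4, 4, 2])
    ped = Pedigree(sire, dam)
    rng = np.random.default_rng(42)
    y = rng.normal(size=(10, 2)) * [0.8, 3.0]
    data = pd.DataFrame({
        "animal": np.arange(1, 11),
        "batch": [0] * 5 + [1] * 5,
        "pen": [0] * 5 + [1] * 5,
        "litter": [0, 0, 1, 1, 2, 2, 0, 1, 2, 0],
        "adg": y[:, 0], "bf": y[:, 1],
    })
    vc = ref_vc.subset_traits([0, 1])
    return ped, data, vc, y


def dense_gls_solution(ped, data, vc, y):
    """Conditional-expectation oracle from the full phenotypic covariance."""
    n, T = 10, 2
    A = ped.A()
    Xp = np.zeros((n, 1)); Xp[5:, 0] = 1.0   # batch, first level zeroed
    Zp = np.zeros((n, 2)); Zp[np.arange(n), data.pen] = 1
    Zl = np.zeros((n, 3)); Zl[np.arange(n), data.litter] = 1
    Zd = np.eye(n)
    Zs = np.zeros((n, n))
    for p in (0, 1):
        mem = np.flatnonzero(data.pen == p)
        for r in mem:
            Zs[r, mem[mem != r]] = 1
    Xb = np.kron(np.eye(T), Xp)
    Zg = np.zeros((T * n, 4 * n))
    for c, (e, t) in enumerate([("d", 0), ("d", 1), ("s", 0), ("s", 1)]):
        Zg[t * n:(t + 1) * n, c * n:(c + 1) * n] = Zd if e == "d" else Zs
    Z = np.hstack([np.kron(np.eye(T), Zp), np.kron(np.eye(T), Zl), Zg])
    G = sla.block_diag(np.kron(vc.P0, np.eye(2)), np.kron(vc.L0, np.eye(3)),
                       np.kron(vc.G0, A))
    V = Z @ G @ Z.T + np.kron(vc.R0, np.eye(n))
    Vi = np.linalg.inv(V)
    ys = y.T.reshape(-1)
    bhat = np.linalg.solve(Xb.T @ Vi @ Xb, Xb.T @ Vi @ ys)
    uhat = G @ Z.T @ Vi @ (ys - Xb @ bhat)
    return bhat, uhat


class TestBuildMme:
    def test_matches_dense_gls_oracle(self, toy_system):
        ped, data, vc, y = toy_system
        spec = ModelSpec(kind="sam", traits=("adg", "bf"), fixed_factors=("batch",))
        sys = build_mme(data, ped, spec, vc)
        sol, rep = solve_mme(sys, method="direct")
        assert rep.rel_residual < 1e-10
        bhat, uhat = dense_gls_solution(ped, data, vc, y)
        T, m, n = 2, sys.m, 10
        mme_b = np.array([sol[t * m + sys.slices["fixed"].start] for t in range(T)])
        assert np.allclose(mme_b, bhat, atol=1e-8)
        mine = np.concatenate(
            [sol[sys.block("pen", t)] for t in range(T)]
            + [sol[sys.block("litter", t)] for t in range(T)]
            + [sol[sys.block("d", 0)], sol[sys.block("d", 1)],
               sol[sys.block("s", 0)], sol[sys.block("s", 1)]])
        oracle = np.concatenate([uhat[:4], uhat[4:10], uhat[10:]])
        assert np.abs(mine - oracle).max() < 1e-8

    def test_ols_reduction_without_random_terms(self):
        # single trait, residual only: MME = OLS normal equations
        rng = np.random.default_rng(0)
        n = 40
        ped = Pedigree(np.zeros(n, dtype=int), np.zeros(n, dtype=int))
        x = rng.normal(size=n)
        y = 2.0 + 0.5 * x + rng.normal(size=n)
        data = pd.DataFrame({"animal": np.arange(1, n + 1), "batch": 0,
                             "pen": 0, "litter": 0, "x": x, "y": y})
        spec = ModelSpec(kind="am", traits=("y",), fixed_factors=(),
                         covariates=("x",), random_pen=False, random_litter=False)
        vc = VarianceComponentsAM(G0=np.array([[1e6]]), P0=np.array([[1e-6]]),
                                  L0=np.array([[1e-6]]), R0=np.array([[1.0]]))
        # huge genetic variance ~ unpenalized per-animal effect; instead check
        # the fixed part against lstsq with a small genetic variance
        vc = VarianceComponentsAM(G0=np.array([[1e-8]]), P0=np.array([[1e-6]]),
                                  L0=np.array([[1e-6]]), R0=np.array([[1.0]]))
        sys = build_mme(data, ped, spec, vc)
        sol, _ = solve_mme(sys, method="direct")
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        fslice = sys.slices["fixed"]
        assert sol[fslice][0] == pytest.approx(beta[0], abs=1e-4)
        assert sol[fslice][1] == pytest.approx(beta[1], abs=1e-4)

    def test_sam_with_vanishing_ige_equals_am(self, toy_system, ref_vc):
        ped, data, vc, _ = toy_system
        vs = ref_vc.subset_traits([0, 1])
        G0 = vs.G0.copy()
        G0[2:, :] = 0.0; G0[:, 2:] = 0.0
        G0[2, 2] = G0[3, 3] = 1e-8
        vs.G0 = G0
        sys_sam = build_mme(data, ped, ModelSpec(kind="sam", traits=("adg", "bf")), vs)
        sol_sam, _ = solve_mme(sys_sam, method="direct")
        vam = VarianceComponentsAM(G0=vc.G0[:2, :2], P0=vc.P0, L0=vc.L0, R0=vc.R0)
        sys_am = build_mme(data, ped, ModelSpec(kind="am", traits=("adg", "bf")), vam)
        sol_am, _ = solve_mme(sys_am, method="direct")
        for t in range(2):
            assert np.abs(sol_sam[sys_sam.block("d", t)]
                          - sol_am[sys_am.block("u", t)]).max() < 1e-6

    def test_block_deletion_identity(self, toy_system):
        # removing the s equations of the SAM system (and its genetic prior)
        # leaves exactly the AM system built on the matching components
        ped, data, vc, _ = toy_system
        sys = build_mme(data, ped, ModelSpec(kind="sam", traits=("adg", "bf")), vc)
        vam = VarianceComponentsAM(G0=vc.G0[:2, :2], P0=vc.P0, L0=vc.L0, R0=vc.R0)
        sys_am = build_mme(data, ped, ModelSpec(kind="am", traits=("adg", "bf")), vam)
        C_sam = sys.C.toarray()
        C_am = sys_am.C.toarray()
        Ainv = ped.A_inverse().toarray()
        Ginv_sam = np.linalg.inv(vc.G0)
        Ginv_am = np.linalg.inv(vc.G0[:2, :2])
        keep = np.concatenate([
            np.r_[sys.block("fixed", t), sys.block("pen", t),
                  sys.block("litter", t), sys.block("d", t)] for t in range(2)])
        C_del = C_sam[np.ix_(keep, keep)]
        # swap the genetic priors so both matrices carry the same one
        for i in range(2):
            for j in range(2):
                bi = np.r_[sys_am.block("u", i)]
                bj = np.r_[sys_am.block("u", j)]
                # positions of the d-blocks within the deleted system match
                # the am u-blocks by construction (identical layout)
                C_del[np.ix_(bi, bj)] += (Ginv_am[i, j] - Ginv_sam[i, j]) * Ainv
        assert np.allclose(C_del, C_am, atol=1e-10)

    def test_record_for_unknown_animal_rejected(self, toy_system):
        ped, data, vc, _ = toy_system
        bad = data.copy()
        bad.loc[0, "animal"] = 99
        with pytest.raises(ModelError):
            build_mme(bad, ped, ModelSpec(kind="sam", traits=("adg", "bf")), vc)


class TestSolveMme:
    def test_pcg_matches_direct(self, toy_system):
        ped, data, vc, _ = toy_system
        sys = build_mme(data, ped, ModelSpec(kind="sam", traits=("adg", "bf")), vc)
        x1, _ = solve_mme(sys, method="direct")
        x2, rep = solve_mme(sys, method="pcg", tol=1e-10)
        assert rep.converged
        assert np.abs(x1 - x2).max() < 1e-6

    def test_confounded_batch_level_constrained(self, toy_system):
        # batch confounded with pen: zero-constraint keeps the system solvable
        ped, data, vc, _ = toy_system
        data = data.copy()
        data["batch"] = data["pen"]
        sys = build_mme(data, ped, ModelSpec(kind="sam", traits=("adg", "bf")), vc)
        _, rep = solve_mme(sys, method="direct")
        assert rep.rel_residual < 1e-8


class TestPredictions:
    def test_isolated_founder_predicts_zero(self, toy_system, ref_vc):
        ped, data, vc, _ = toy_system
        from samblup.pedigree import concat_generation
        ped2 = concat_generation(ped, [0], [0])  # animal 11: unrelated founder
        sys = build_mme(data, ped2, ModelSpec(kind="sam", traits=("adg", "bf")), vc)
        sol, _ = solve_mme(sys, method="direct")
        ebv = predict_index_inputs(sol, sys, [11])
        assert np.abs(ebv.dhat).max() < 1e-10
        assert np.abs(ebv.shat).max() < 1e-10

    def test_childless_unrecorded_offspring_gets_parent_average(
            self, toy_system):
        ped, data, vc, _ = toy_system
        from samblup.pedigree import concat_generation
        ped2 = concat_generation(ped, [9], [10])  # 11 = (9, 10), no record
        sys = build_mme(data, ped2, ModelSpec(kind="sam", traits=("adg", "bf")), vc)
        sol, _ = solve_mme(sys, method="direct")
        ebv = predict_index_inputs(sol, sys, [9, 10, 11])
        assert np.allclose(ebv.dhat[2], 0.5 * (ebv.dhat[0] + ebv.dhat[1]),
                           atol=1e-8)

    def test_am_table_has_no_social_columns(self, toy_system):
        ped, data, vc, _ = toy_system
        vam = VarianceComponentsAM(G0=vc.G0[:2, :2], P0=vc.P0, L0=vc.L0, R0=vc.R0)
        sys = build_mme(data, ped, ModelSpec(kind="am", traits=("adg", "bf")), vam)
        sol, _ = solve_mme(sys, method="direct")
        ebv = predict_index_inputs(sol, sys, [1, 2])
        assert ebv.uhat is not None and ebv.shat is None
        frame = ebv.frame()
        assert set(frame.effect) == {"u"}

    def test_candidate_missing_from_pedigree(self, toy_system):
        ped, data, vc, _ = toy_system
        sys = build_mme(data, ped, ModelSpec(kind="sam", traits=("adg", "bf")), vc)
        sol, _ = solve_mme(sys, method="direct")
        with pytest.raises(ModelError):
            predict_index_inputs(sol, sys, [42])


class TestBlupProperties:
    def test_prediction_error_uncorrelated_with_prediction(self, ref_vc):
        # over repeated simulation of a fixed design, cov(uhat - u, uhat) ~ 0
        from samblup.synth import sample_genetic_effects, simulate_phenotypes
        rng = np.random.default_rng(11)
        n = 50
        sire = np.zeros(n, dtype=int); dam = np.zeros(n, dtype=int)
        sire[20:] = rng.integers(1, 10, n - 20)
        dam[20:] = rng.integers(10, 20, n - 20)
        ped = Pedigree(sire, dam)
        vc = ref_vc.subset_traits([0, 1])
        frame = pd.DataFrame({"animal": np.arange(1, n + 1), "batch": 0,
                              "pen": np.arange(n) // 10, "litter": np.arange(n) // 5})
        spec = ModelSpec(kind="sam", traits=("adg", "bf"), fixed_factors=())
        errs, preds = [], []
        for rep in range(120):
            bv = sample_genetic_effects(ped, vc.G0, rng)
            tr = simulate_phenotypes(frame, bv, vc, rng)
            d = frame.copy()
            d["adg"] = tr["adg"].to_numpy()
            d["bf"] = tr["bf"].to_numpy()
            sys = build_mme(d, ped, spec, vc)
            sol, _ = solve_mme(sys, method="direct")
            ebv = predict_index_inputs(sol, sys, frame.animal.to_numpy())
            preds.append(ebv.dhat[:, 0])
            errs.append(ebv.dhat[:, 0] - bv[:, 0])
        preds = np.concatenate(preds); errs = np.concatenate(errs)
        r = np.corrcoef(preds, errs)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(preds) / 10)  # effective n discounted
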