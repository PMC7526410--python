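"""EM-REML: closed-form oracle, likelihood identities, recovery."""

import numpy as np
import pandas as pd
import pytest

from samblup.mme import ModelSpec, build_mme
from samblup.params import VarianceComponentsAM, collapse_to_am
from samblup.pedigree import Pedigree
from samblup.reml import RemlError, reml_fit, restricted_loglik
from samblup.synth import sample_genetic_effects, simulate_phenotypes


def balanced_oneway(q=30, r=10, su2=2.0, se2=5.0, seed=0):
    rng = np.random.default_rng(seed)
    n = q * r
    lit = np.repeat(np.arange(q), r)
    y = np.sqrt(su2) * rng.standard_normal(q)[lit] + np.sqrt(se2) * rng.standard_normal(n)
    data = pd.DataFrame({"animal": np.arange(1, n + 1), "batch": 0, "pen": 0,
                         "litter": lit, "y": y})
    ped = Pedigree(np.zeros(n, dtype=int), np.zeros(n, dtype=int))
    return data, ped, y, q, r


class TestClosedFormOracle:
    def test_balanced_oneway_matches_anova(self):
        data, ped, y, q, r = balanced_oneway()
        ybar_i = y.reshape(q, r).mean(1)
        msb = r * np.sum((ybar_i - y.mean()) ** 2) / (q - 1)
        msw = np.sum((y.reshape(q, r) - ybar_i[:, None]) ** 2) / (q * (r - 1))
        anova_u, anova_e = (msb - msw) / r, msw
        spec = ModelSpec(kind="am", traits=("y",), fixed_factors=(),
                         random_pen=False, random_litter=True)
        start = VarianceComponentsAM(G0=[[0.01]], P0=[[1e-4]], L0=[[1.0]],
                                     R0=[[1.0]])
        res = reml_fit(data, ped, spec, start, max_iter=400, tol=1e-10)
        assert res.converged
        assert res.estimates.L0[0, 0] == pytest.approx(anova_u, abs=1e-6)
        # unrelated single-record animals: genetic confounded with residual,
        # only the sum is identified
        assert (res.estimates.G0[0, 0] + res.estimates.R0[0, 0]
                == pytest.approx(anova_e, abs=1e-6))

    def test_em_trace_monotone(self):
        data, ped, *_ = balanced_oneway(seed=2)
        spec = ModelSpec(kind="am", traits=("y",), fixed_factors=(),
                         random_pen=False, random_litter=True)
        start = VarianceComponentsAM(G0=[[0.5]], P0=[[1e-4]], L0=[[4.0]],
                                     R0=[[2.0]])
        res = reml_fit(data, ped, spec, start, max_iter=60, tol=0)
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs >= -1e-7)


@pytest.fixture(scope="module")
def tiny(ref_vc):
    rng = np.random.default_rng(5)
    n = 8
    ped = Pedigree(np.array([0, 0, 0, 0, 1, 1, 3, 3]),
                   np.array([0, 0, 0, 0, 2, 2, 4, 4]))
    data = pd.DataFrame({"animal": np.arange(1, n + 1), "batch": [0] * 4 + [1] * 4,
                         "pen": [0, 0, 1, 1, 0, 0, 1, 1],
                         "litter": [0, 0, 1, 1, 2, 2, 3, 3],
                         "y": rng.normal(size=n)})
    vc = VarianceComponentsAM(G0=[[0.4]], P0=[[0.2]], L0=[[0.3]], R0=[[1.1]])
    return data, ped, vc


class TestRestrictedLoglik:
    def test_matches_dense_textbook_formula(self, tiny):
        data, ped, vc = tiny
        spec = ModelSpec(kind="am", traits=("y",), fixed_factors=("batch",))
        ll = restricted_loglik(data, ped, spec, vc)
        # textbook: -2l = log|V| + log|X'V^-1X| + y'Py  with V dense
        n = len(data)
        A = ped.A()
        Zp = pd.get_dummies(data.pen).to_numpy(float)
        Zl = pd.get_dummies(data.litter).to_numpy(float)
        X = np.column_stack([(data.batch == 1).to_numpy(float)])
        V = (vc.G0[0, 0] * A + vc.P0[0, 0] * Zp @ Zp.T
             + vc.L0[0, 0] * Zl @ Zl.T + vc.R0[0, 0] * np.eye(n))
        Vi = np.linalg.inv(V)
        y = data.y.to_numpy()
        XVX = X.T @ Vi @ X
        beta = np.linalg.solve(XVX, X.T @ Vi @ y)
        resid = y - X @ beta
        yPy = float(resid @ Vi @ y)
        m2l = np.linalg.slogdet(V)[1] + np.linalg.slogdet(XVX)[1] + yPy
        assert ll == pytest.approx(-0.5 * m2l, abs=1e-8)

    def test_scale_invariance_of_differences(self, tiny):
        data, ped, vc = tiny
        spec = ModelSpec(kind="am", traits=("y",), fixed_factors=("batch",))
        vc2 = VarianceComponentsAM(G0=[[0.6]], P0=[[0.1]], L0=[[0.2]], R0=[[0.9]])
        d1 = restricted_loglik(data, ped, spec, vc) - restricted_loglik(
            data, ped, spec, vc2)
        c = 2.7
        data_s = data.copy()
        data_s["y"] = data.y * np.sqrt(c)

        def scale(v):
            return VarianceComponentsAM(G0=np.asarray(v.G0) * c,
                                        P0=np.asarray(v.P0) * c,
                                        L0=np.asarray(v.L0) * c,
                                        R0=np.asarray(v.R0) * c)
        d2 = restricted_loglik(data_s, ped, spec, scale(vc)) - restricted_loglik(
            data_s, ped, spec, scale(vc2))
        assert d2 == pytest.approx(d1, abs=1e-8)


class TestRecovery:
    def test_am_heritability_recovered_on_simulated_data(self, ref_vc):
        # AM truth from the collapsed SAM at a modest design; the mean h2
        # estimate over replicates should sit near the generating value
        vc_am = collapse_to_am(ref_vc, 8).subset_traits([0, 1])
        rng = np.random.default_rng(17)
        n_founders, n_off = 60, 540
        h2_est = []
        for rep in range(3):
            sire = np.zeros(n_founders + n_off, dtype=int)
            dam = np.zeros_like(sire)
            sire[n_founders:] = rng.integers(1, 20, n_off)
            dam[n_founders:] = rng.integers(20, n_founders, n_off)
            ped = Pedigree(sire, dam)
            frame = pd.DataFrame({
                "animal": np.arange(n_founders + 1, n_founders + n_off + 1),
                "batch": np.arange(n_off) // 90,
                "pen": np.arange(n_off) // 8,
                "litter": rng.integers(0, 90, n_off)})
            k = 2
            from samblup.params import VarianceComponentsSAM2
            gen = VarianceComponentsSAM2(
                G0=np.block([[vc_am.G0, np.zeros((k, k))],
                             [np.zeros((k, k)), np.eye(k) * 1e-8]]),
                P0=vc_am.P0, L0=vc_am.L0, R0=vc_am.R0, trait_idx=(0, 1))
            bv = sample_genetic_effects(ped, gen.G0, rng)
            tr = simulate_phenotypes(frame, bv, gen, rng)
            d = frame.copy()
            d["adg"] = tr["adg"].to_numpy(); d["bf"] = tr["bf"].to_numpy()
            spec = ModelSpec(kind="am", traits=("adg", "bf"),
                             fixed_factors=("batch",))
            res = reml_fit(d, ped, spec, vc_am, max_iter=60, tol=1e-5)
            h2_est.append([res.estimates.h2(t) for t in range(2)])
        h2_est = np.array(h2_est).mean(axis=0)
        truth = [vc_am.h2(t) for t in range(2)]
        assert np.abs(h2_est - truth).max() < 0.15

    def test_estimates_invariant_to_record_order(self):
        data, ped, *_ = balanced_oneway(q=12, r=6, seed=4)
        spec = ModelSpec(kind="am", traits=("y",), fixed_factors=(),
                         random_pen=False, random_litter=True)
        start = VarianceComponentsAM(G0=[[0.2]], P0=[[1e-4]], L0=[[1.0]], R0=[[1.0]])
        r1 = reml_fit(data, ped, spec, start, max_iter=80)
        shuf = data.sample(frac=1.0, random_state=9).reset_index(drop=True)
        r2 = reml_fit(shuf, ped, spec, start, max_iter=80)
        assert np.allclose(r1.estimates.L0, r2.estimates.L0, atol=1e-8)
        assert np.allclose(r1.estimates.R0, r2.estimates.R0, atol=1e-8)

    def test_large_system_uses_stochastic_traces(self):
        # past the dense threshold the fit switches to Hutchinson probing and
        # still lands near the closed-form litter variance
        data, ped, y, q, r = balanced_oneway(q=400, r=10, seed=8)
        ybar_i = y.reshape(q, r).mean(1)
        msb = r * np.sum((ybar_i - y.mean()) ** 2) / (q - 1)
        msw = np.sum((y.reshape(q, r) - ybar_i[:, None]) ** 2) / (q * (r - 1))
        anova_u = (msb - msw) / r
        spec = ModelSpec(kind="am", traits=("y",), fixed_factors=(),
                         random_pen=False, random_litter=True)
        start = VarianceComponentsAM(G0=[[0.01]], P0=[[1e-4]], L0=[[1.5]],
                                     R0=[[4.0]])
        res = reml_fit(data, ped, spec, start, max_iter=40, tol=1e-6, seed=1)
        assert not res.exact
        assert res.estimates.L0[0, 0] == pytest.approx(anova_u, rel=0.1)
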