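"""EM-REML estimation of animal-model variance components.

Fits the multi-trait classical animal model (single additive effect per
trait, plus pen and litter) by expectation-maximisation REML: each iteration
solves the mixed-model equations at the current components and updates every
covariance matrix from the conditional expectations of its effects' cross
products.  EM is slower than average-information updates but each exact step
provably does not decrease the restricted likelihood, which the tests
assert.

The conditional (co)variance corrections need blocks of the inverse
coefficient matrix.  Small systems use a dense inverse (exact EM, provably
monotone); larger systems estimate every trace by Hutchinson probing
(Rademacher probes solved against a sparse LU factorization), which keeps
each EM step at one factorization plus a handful of solves at the cost of a
little Monte Carlo noise in the updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import linalg as spla

from .mme import MMESystem, ModelSpec, build_mme
from .params import VarianceComponentsAM
from .pedigree import Pedigree

MAX_DENSE_EQUATIONS = 3000
N_PROBES = 12


class RemlError(RuntimeError):
    pass


@dataclass
class RemlResult:
    estimates: VarianceComponentsAM
    loglik_trace: list
    iterations: int
    converged: bool
    bent: bool = False
    exact: bool = True


def _bend(M: np.ndarray, floor_frac: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Eigenvalue flooring at floor_frac * trace; returns (matrix, was_bent)."""
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    floor = floor_frac * max(np.trace(M), 1e-300)
    if w.min() > floor:
        return M, False
    w = np.maximum(w, floor)
    return (V * w) @ V.T, True


def _logdet_and_solver(sys: MMESystem, dense: bool):
    if dense:
        C = sys.C.toarray()
        sign, logdetC = np.linalg.slogdet(C)
        if sign <= 0:
            raise RemlError("coefficient matrix is not positive definite")
        Cinv = np.linalg.inv(C)
        return logdetC, (lambda b: Cinv @ b), Cinv
    lu = spla.splu(sys.C.tocsc(), permc_spec="MMD_AT_PLUS_A")
    logdetC = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    return logdetC, lu.solve, None


def restricted_loglik(data, ped: Pedigree, spec: ModelSpec, vc: VarianceComponentsAM,
                      sys: MMESystem | None = None) -> float:
    """Restricted log-likelihood up to a constant, via MME identities.

    -2 l_R = y'Py + log|C| + n_rec log|R0| + n_anim log|G0| + T log|A|
             + n_pen log|P0| + n_litter log|L0|   (+ const),

    invariant to the zero-constraint choice on the fixed part (the
    constrained fixed columns are full rank).  Larger is better.
    """
    if sys is None:
        sys = build_mme(data, ped, spec, vc)
    n_rec = sys.y.shape[0]
    T = sys.n_traits
    logdetC, solve, _ = _logdet_and_solver(
        sys, dense=sys.n_equations <= MAX_DENSE_EQUATIONS)
    sol = solve(sys.rhs)
    yRy = float(np.einsum("it,tj,ij->", sys.y, sys.R0inv, sys.y))
    yPy = yRy - float(sys.rhs @ sol)
    logdet = logdetC + n_rec * np.linalg.slogdet(vc.R0)[1]
    logdet += sys.n_anim * np.linalg.slogdet(vc.G0)[1]
    logdet += T * float(np.sum(np.log(ped.mendelian_variance_coeff())))
    if sys.pen_levels is not None:
        logdet += len(sys.pen_levels) * np.linalg.slogdet(vc.P0)[1]
    if sys.litter_levels is not None:
        logdet += len(sys.litter_levels) * np.linalg.slogdet(vc.L0)[1]
    return -0.5 * (yPy + logdet)


def reml_fit(data, ped: Pedigree, spec: ModelSpec, start: VarianceComponentsAM,
             max_iter: int = 100, tol: float = 1e-6,
             n_probes: int = N_PROBES, seed: int = 0) -> RemlResult:
    """EM-REML for the AM; iterates until relative parameter change < tol.

    ``start`` provides positive-definite starting matrices (inside the
    simulation pipeline the collapsed generating components; otherwise an
    equal split of the phenotypic variance works).  Systems larger than
    ``MAX_DENSE_EQUATIONS`` use stochastic trace estimation with
    ``n_probes`` Rademacher probes (deterministic given ``seed``).
    """
    if spec.kind != "am":
        raise RemlError("REML is implemented for the classical animal model only")
    vc = start
    T = len(spec.traits)
    trace = []
    bent_any = False
    converged = False
    rng = np.random.default_rng(seed)
    exact_mode = True
    it = 0
    for it in range(1, max_iter + 1):
        sys = build_mme(data, ped, spec, vc)
        n_eq = sys.n_equations
        dense = n_eq <= MAX_DENSE_EQUATIONS
        exact_mode = exact_mode and dense
        logdetC, solve, Cinv = _logdet_and_solver(sys, dense)
        sol = solve(sys.rhs)
        trace.append(restricted_loglik_from_parts(sys, ped, vc, logdetC, sol))
        n_anim = sys.n_anim
        Ainv = sys.Ainv
        m = sys.m

        if dense:
            def block_trace(ba, bb, weight):
                blk = Cinv[ba, :][:, bb]
                if weight is None:
                    return float(np.trace(blk))
                return float(weight.multiply(blk.T).sum())
        else:
            Z = np.where(rng.random((n_eq, n_probes)) < 0.5, -1.0, 1.0)
            X = np.column_stack([solve(Z[:, k]) for k in range(n_probes)])

            def block_trace(ba, bb, weight):
                xa = X[ba, :]
                zb = Z[bb, :]
                if weight is None:
                    return float(np.mean(np.sum(zb * xa, axis=0)))
                wx = weight @ xa
                return float(np.mean(np.sum(zb * wx, axis=0)))

        def blk(name, t):
            return sys.block(name, t)

        G = np.empty((T, T))
        for i in range(T):
            ui = sol[blk("u", i)]
            for j in range(i, T):
                uj = sol[blk("u", j)]
                tr = block_trace(blk("u", i), blk("u", j), Ainv)
                G[i, j] = G[j, i] = (ui @ (Ainv @ uj) + tr) / n_anim
        P = L = None
        if sys.pen_levels is not None:
            q = len(sys.pen_levels)
            P = np.empty((T, T))
            for i in range(T):
                pi = sol[blk("pen", i)]
                for j in range(i, T):
                    tr = block_trace(blk("pen", i), blk("pen", j), None)
                    P[i, j] = P[j, i] = (pi @ sol[blk("pen", j)] + tr) / q
        if sys.litter_levels is not None:
            q = len(sys.litter_levels)
            L = np.empty((T, T))
            for i in range(T):
                li = sol[blk("litter", i)]
                for j in range(i, T):
                    tr = block_trace(blk("litter", i), blk("litter", j), None)
                    L[i, j] = L[j, i] = (li @ sol[blk("litter", j)] + tr) / q
        n_rec = sys.y.shape[0]
        WtW = (sys.W.T @ sys.W).tocsr()
        ehat = np.column_stack(
            [sys.y[:, t] - sys.W @ sol[t * m:(t + 1) * m] for t in range(T)])
        R = np.empty((T, T))
        for i in range(T):
            for j in range(i, T):
                tr = block_trace(slice(i * m, (i + 1) * m),
                                 slice(j * m, (j + 1) * m), WtW)
                R[i, j] = R[j, i] = (ehat[:, i] @ ehat[:, j] + tr) / n_rec

        G, b1 = _bend(G)
        R, b2 = _bend(R)
        b3 = b4 = False
        if P is not None:
            P, b3 = _bend(P)
        if L is not None:
            L, b4 = _bend(L)
        bent_any = bent_any or b1 or b2 or b3 or b4
        new = VarianceComponentsAM(
            G0=G, P0=P if P is not None else vc.P0,
            L0=L if L is not None else vc.L0, R0=R)
        theta_old = np.concatenate([np.ravel(M) for M in
                                    (vc.G0, vc.P0, vc.L0, vc.R0)])
        theta_new = np.concatenate([np.ravel(M) for M in
                                    (new.G0, new.P0, new.L0, new.R0)])
        rel = np.linalg.norm(theta_new - theta_old) / max(
            np.linalg.norm(theta_old), 1e-12)
        vc = new
        if rel < tol:
            converged = True
            break
    return RemlResult(estimates=vc, loglik_trace=trace, iterations=it,
                      converged=converged, bent=bent_any, exact=exact_mode)


def restricted_loglik_from_parts(sys: MMESystem, ped: Pedigree,
                                 vc: VarianceComponentsAM, logdetC: float,
                                 sol: np.ndarray) -> float:
    n_rec = sys.y.shape[0]
    T = sys.n_traits
    yRy = float(np.einsum("it,tj,ij->", sys.y, sys.R0inv, sys.y))
    yPy = yRy - float(sys.rhs @ sol)
    logdet = logdetC + n_rec * np.linalg.slogdet(vc.R0)[1]
    logdet += sys.n_anim * np.linalg.slogdet(vc.G0)[1]
    logdet += T * float(np.sum(np.log(ped.mendelian_variance_coeff())))
    if sys.pen_levels is not None:
        logdet += len(sys.pen_levels) * np.linalg.slogdet(vc.P0)[1]
    if sys.litter_levels is not None:
        logdet += len(sys.litter_levels) * np.linalg.slogdet(vc.L0)[1]
    return -0.5 * (yPy + logdet)
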