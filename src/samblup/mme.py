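"""Henderson's mixed-model equations for the social and classical animal model.

For traits evaluated jointly on the same records (the evaluation pair ADG and
BF, or all three traits) the coefficient matrix is

    C = R0^-1 (x) W'W  +  blockdiag(0_fixed, P0^-1 (x) I, L0^-1 (x) I, G0^-1 (x) A^-1)

with W = [X | Zp | Zl | Zd | Zs] the per-trait design (identical across traits
because every record carries all traits), and the genetic block joint over
direct and indirect effects under the SAM.  Every pedigree animal gets
equations whether or not it has records, so predictions propagate through
relationships.  Fixed-effect rank deficiency is resolved by dropping the
first level of each factor (zero constraint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import linalg as spla

from .pedigree import Pedigree


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """What to fit: model kind, traits, fixed part, random terms."""

    kind: str = "sam"                      # 'sam' | 'am'
    traits: tuple = ("adg", "bf")
    fixed_factors: tuple = ("batch",)
    covariates: tuple = ()
    random_pen: bool = True
    random_litter: bool = True

    def __post_init__(self):
        if self.kind not in ("sam", "am"):
            raise ModelError(f"unknown model kind {self.kind!r}")


@dataclass
class MMESystem:
    """Assembled equations plus the index bookkeeping needed to read solutions."""

    C: sparse.csr_matrix
    rhs: np.ndarray
    W: sparse.csr_matrix          # per-trait design, shared across traits
    y: np.ndarray                 # (n_records, n_traits)
    R0inv: np.ndarray
    m: int                        # equations per trait block
    n_traits: int
    slices: dict                  # name -> slice within a trait block
    n_anim: int
    kind: str
    pen_levels: np.ndarray | None
    litter_levels: np.ndarray | None
    fixed_names: list
    animals_in_data: np.ndarray
    Ainv: sparse.csr_matrix

    @property
    def n_equations(self) -> int:
        return self.C.shape[0]

    def block(self, name: str, trait: int) -> slice:
        s = self.slices[name]
        off = trait * self.m
        return slice(off + s.start, off + s.stop)


@dataclass
class SolveReport:
    method: str
    converged: bool
    rel_residual: float
    iterations: int = 0
    residual_history: list = field(default_factory=list)


@dataclass
class EBVTable:
    """Predicted genetic effects per animal and trait (+ optional truths)."""

    animals: np.ndarray
    traits: tuple
    dhat: np.ndarray | None = None   # (n, T) under SAM
    shat: np.ndarray | None = None
    uhat: np.ndarray | None = None   # (n, T) under AM
    d_true: np.ndarray | None = None
    s_true: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        """Long-format table (animal, trait, effect, prediction)."""
        rows = []
        for ti, t in enumerate(self.traits):
            if self.uhat is not None:
                rows.append(pd.DataFrame({"animal": self.animals, "trait": t,
                                          "effect": "u", "prediction": self.uhat[:, ti]}))
            else:
                rows.append(pd.DataFrame({"animal": self.animals, "trait": t,
                                          "effect": "d", "prediction": self.dhat[:, ti]}))
                rows.append(pd.DataFrame({"animal": self.animals, "trait": t,
                                          "effect": "s", "prediction": self.shat[:, ti]}))
        return pd.concat(rows, ignore_index=True)

    def write(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)


def _design(data: pd.DataFrame, ped: Pedigree, spec: ModelSpec):
    """Per-trait design matrix W and the column bookkeeping."""
    n = len(data)
    cols = []
    widths = []
    fixed_names = []
    n_factor_cols = 0
    for f in spec.fixed_factors:
        codes, levels = pd.factorize(data[f], sort=True)
        if len(levels) > 1:
            n_factor_cols += len(levels) - 1
            # zero constraint: first level dropped
            keep = codes > 0
            Xf = sparse.coo_matrix(
                (np.ones(keep.sum()), (np.flatnonzero(keep), codes[keep] - 1)),
                shape=(n, len(levels) - 1),
            )
            cols.append(Xf)
            widths.append(len(levels) - 1)
            fixed_names += [f"{f}:{lv}" for lv in levels[1:]]
    if n_factor_cols == 0:
        # no factor absorbs the mean: fit an explicit intercept
        cols.append(sparse.coo_matrix(np.ones((n, 1))))
        widths.append(1)
        fixed_names.append("intercept")
    for c in spec.covariates:
        v = data[c].to_numpy(dtype=float)
        cols.append(sparse.coo_matrix(v.reshape(-1, 1)))
        widths.append(1)
        fixed_names.append(c)
    n_fixed = sum(widths)

    pen_levels = litter_levels = None
    if spec.random_pen:
        pen_codes, pen_levels = pd.factorize(data["pen"], sort=True)
        cols.append(sparse.coo_matrix((np.ones(n), (np.arange(n), pen_codes)),
                                      shape=(n, len(pen_levels))))
    if spec.random_litter:
        lit_codes, litter_levels = pd.factorize(data["litter"], sort=True)
        cols.append(sparse.coo_matrix((np.ones(n), (np.arange(n), lit_codes)),
                                      shape=(n, len(litter_levels))))

    anim = data["animal"].to_numpy(dtype=np.int64)
    if anim.min() < 1 or anim.max() > ped.n:
        raise ModelError("record refers to an animal missing from the pedigree")
    Zd = sparse.coo_matrix((np.ones(n), (np.arange(n), anim - 1)), shape=(n, ped.n))
    cols.append(Zd)
    if spec.kind == "sam":
        pen_codes_all, pens_all = pd.factorize(data["pen"], sort=True)
        Zpen = sparse.coo_matrix((np.ones(n), (np.arange(n), pen_codes_all)),
                                 shape=(n, len(pens_all)))
        member = sparse.coo_matrix((np.ones(n), (pen_codes_all, anim - 1)),
                                   shape=(len(pens_all), ped.n))
        Zs = (Zpen @ member - Zd).tocoo()  # own record row has 0 for own s
        cols.append(Zs)

    W = sparse.hstack(cols, format="csr")
    off = 0
    slices = {"fixed": slice(0, n_fixed)}
    off = n_fixed
    if spec.random_pen:
        slices["pen"] = slice(off, off + len(pen_levels)); off += len(pen_levels)
    if spec.random_litter:
        slices["litter"] = slice(off, off + len(litter_levels)); off += len(litter_levels)
    if spec.kind == "sam":
        slices["d"] = slice(off, off + ped.n); off += ped.n
        slices["s"] = slice(off, off + ped.n); off += ped.n
    else:
        slices["u"] = slice(off, off + ped.n); off += ped.n
    assert off == W.shape[1]
    return W, slices, pen_levels, litter_levels, fixed_names, anim


def genetic_combos(spec: ModelSpec):
    """Genetic (effect, trait-position) combos in the order G0 is indexed."""
    T = len(spec.traits)
    if spec.kind == "sam":
        return [("d", t) for t in range(T)] + [("s", t) for t in range(T)]
    return [("u", t) for t in range(T)]


def build_mme(data: pd.DataFrame, ped: Pedigree, spec: ModelSpec, vc) -> MMESystem:
    """Assemble Henderson's MME for the given records and model."""
    T = len(spec.traits)
    if vc.R0.shape[0] != T:
        raise ModelError("variance components do not match the trait list")
    if spec.kind == "sam" and vc.G0.shape[0] != 2 * T:
        raise ModelError("SAM needs a joint d,s genetic covariance of dimension 2T")
    if spec.kind == "am" and vc.G0.shape[0] != T:
        raise ModelError("AM needs a TxT genetic covariance")
    try:
        R0inv = np.linalg.inv(vc.R0)
    except np.linalg.LinAlgError as e:
        raise ModelError(f"singular residual covariance: {e}") from None

    W, slices, pen_levels, litter_levels, fixed_names, anim = _design(data, ped, spec)
    m = W.shape[1]
    y = data[list(spec.traits)].to_numpy(dtype=float)

    WtW = (W.T @ W).tocsr()
    C = sparse.kron(R0inv, WtW, format="coo")
    parts = [C]

    def shifted(M, r0, c0, total):
        M = M.tocoo()
        return sparse.coo_matrix((M.data, (M.row + r0, M.col + c0)), shape=(total, total))

    total = T * m
    if spec.random_pen:
        P0inv = np.linalg.inv(vc.P0)
        I = sparse.identity(len(pen_levels), format="coo")
        s = slices["pen"]
        for i in range(T):
            for j in range(T):
                parts.append(shifted(P0inv[i, j] * I, i * m + s.start, j * m + s.start, total))
    if spec.random_litter:
        L0inv = np.linalg.inv(vc.L0)
        I = sparse.identity(len(litter_levels), format="coo")
        s = slices["litter"]
        for i in range(T):
            for j in range(T):
                parts.append(shifted(L0inv[i, j] * I, i * m + s.start, j * m + s.start, total))
    G0inv = np.linalg.inv(vc.G0)
    Ainv = ped.A_inverse()
    combos = genetic_combos(spec)
    for a, (ea, ta) in enumerate(combos):
        for b, (eb, tb) in enumerate(combos):
            if G0inv[a, b] == 0.0:
                continue
            sa, sb = slices[ea], slices[eb]
            parts.append(shifted(G0inv[a, b] * Ainv,
                                 ta * m + sa.start, tb * m + sb.start, total))
    C = sum(parts).tocsr()

    Wty = W.T @ y  # (m, T)
    rhs = (Wty @ R0inv.T).T.reshape(-1)  # trait-major: block t = sum_j R0inv[t,j] W'y_j

    return MMESystem(C=C, rhs=rhs, W=W, y=y, R0inv=R0inv, m=m, n_traits=T,
                     slices=slices, n_anim=ped.n, kind=spec.kind,
                     pen_levels=pen_levels, litter_levels=litter_levels,
                     fixed_names=fixed_names, animals_in_data=anim, Ainv=Ainv)


def solve_mme(sys: MMESystem, method: str = "auto", tol: float = 1e-8,
              max_iter: int = 5000):
    """Solve the MME; returns (solution, SolveReport).

    'direct' uses a sparse LU factorization; 'pcg' Jacobi-preconditioned
    conjugate gradients; 'auto' picks direct for systems up to 200k equations.
    """
    n = sys.n_equations
    if method == "auto":
        # direct factorization fills in badly on pen/pedigree graphs beyond a
        # few tens of thousands of equations; PCG stays cheap and accurate
        method = "direct" if n <= 15_000 else "pcg"
    b = sys.rhs
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return np.zeros(n), SolveReport(method, True, 0.0)
    if method == "direct":
        lu = spla.splu(sys.C.tocsc(), permc_spec="MMD_AT_PLUS_A")
        x = lu.solve(b)
        rel = np.linalg.norm(sys.C @ x - b) / bnorm
        return x, SolveReport(method, rel <= max(tol, 1e-6), rel)
    if method == "pcg":
        d = sys.C.diagonal()
        d[d <= 0] = 1.0
        M = spla.LinearOperator((n, n), matvec=lambda v: v / d)
        hist = []
        x, info = spla.cg(sys.C, b, rtol=tol, atol=0.0, maxiter=max_iter, M=M,
                          callback=lambda xk: hist.append(1.0))
        rel = np.linalg.norm(sys.C @ x - b) / bnorm
        if info != 0:
            raise RuntimeError(
                f"PCG failed to converge after {len(hist)} iterations "
                f"(relative residual {rel:.3g})")
        return x, SolveReport(method, True, rel, iterations=len(hist))
    raise ValueError(f"unknown solver {method!r}")


def predict_index_inputs(sol: np.ndarray, sys: MMESystem, candidates,
                         traits: tuple | None = None) -> EBVTable:
    """Extract genetic predictions for the candidate animals.

    Animals absent from the data but present in the pedigree receive their
    pedigree-propagated predictions (they have equations in the system).
    """
    cand = np.asarray(candidates, dtype=np.int64)
    if cand.min() < 1 or cand.max() > sys.n_anim:
        raise ModelError("candidate not in pedigree")
    T = sys.n_traits
    traits = traits if traits is not None else tuple(range(T))
    idx = cand - 1
    if sys.kind == "sam":
        dhat = np.column_stack([sol[sys.block("d", t)][idx] for t in range(T)])
        shat = np.column_stack([sol[sys.block("s", t)][idx] for t in range(T)])
        return EBVTable(animals=cand, traits=traits, dhat=dhat, shat=shat)
    uhat = np.column_stack([sol[sys.block("u", t)][idx] for t in range(T)])
    return EBVTable(animals=cand, traits=traits, uhat=uhat)
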