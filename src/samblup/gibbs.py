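"""Bayesian estimation of SAM/AM variance components by Gibbs sampling.

Flat (improper uniform) priors on the systematic effects and on all
covariance matrices.  Location effects are updated single-site from their
normal full conditionals using the mixed-model-equation structure; each
covariance matrix is then drawn from its inverted-Wishart full conditional,
whose degrees of freedom under the flat prior are (number of levels -
dimension - 1).  The sampler refuses to run when a factor has too few levels
for that conditional to be proper.

Model comparison uses the deviance information criterion computed from the
conditional (residual) likelihood given the location effects: DIC = Dbar +
pD with pD = Dbar - D(posterior means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

from .mme import ModelSpec, build_mme, genetic_combos
from .params import VarianceComponentsAM, VarianceComponentsSAM2
from .pedigree import Pedigree


class GibbsError(RuntimeError):
    pass


@dataclass
class GibbsConfig:
    """Chain settings; defaults are desk-scale (the study ran 1e6 / 1e5 / 10)."""

    chain_length: int = 50_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.burn_in < self.chain_length:
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValueError("thinning must be >= 1")


@njit(cache=True)
def _sweep(indptr, indices, wdata, colsq, theta, ehat, z,
           R0inv, P0inv, L0inv, G0inv,
           site_kind, site_animal, combo_of_site,
           a_indptr, a_indices, a_data, combo_trait, combo_off):
    """One single-site Gibbs sweep over all location effects (in place).

    site_kind: 0 fixed, 1 pen, 2 litter, 3 genetic.
    combo_of_site: for genetic sites, the row of G0inv this (effect, trait)
    pair indexes, per trait: combo = combo_of_site[k] + trait_stride * t is
    resolved by the caller through combo arrays instead; here genetic sites
    carry their combo index directly for trait 0 and the caller passes
    per-trait combo offsets via combo_of_site laid out (T, m).
    """
    T, m = theta.shape
    K = G0inv.shape[0]
    for k in range(m):
        kind = site_kind[k]
        c0 = indptr[k]
        c1 = indptr[k + 1]
        for t in range(T):
            # data part: w_k' sum_j R0inv[t, j] ehat_j
            r = 0.0
            for p in range(c0, c1):
                rec = indices[p]
                w = wdata[p]
                acc = 0.0
                for j in range(T):
                    acc += R0inv[t, j] * ehat[rec, j]
                r += w * acc
            diag = R0inv[t, t] * colsq[k]
            prior = 0.0
            if kind == 1:
                for j in range(T):
                    prior += P0inv[t, j] * theta[j, k]
                diag += P0inv[t, t]
            elif kind == 2:
                for j in range(T):
                    prior += L0inv[t, j] * theta[j, k]
                diag += L0inv[t, t]
            elif kind == 3:
                a = site_animal[k]
                c = combo_of_site[t, k]
                for cc in range(K):
                    g = G0inv[c, cc]
                    if g == 0.0:
                        continue
                    tt = combo_trait[cc]
                    off = combo_off[cc]
                    s = 0.0
                    for p in range(a_indptr[a], a_indptr[a + 1]):
                        s += a_data[p] * theta[tt, off + a_indices[p]]
                    prior += g * s
                aii = 0.0
                for p in range(a_indptr[a], a_indptr[a + 1]):
                    if a_indices[p] == a:
                        aii = a_data[p]
                        break
                diag += G0inv[c, c] * aii
                # the loop above included the site's own theta; that is the
                # correct full row term (we subtract the full row below)
            old = theta[t, k]
            # full row dot theta = (data part already excludes nothing: r uses
            # ehat which contains old's contribution removed from y) ->
            # conditional mean = old + (r - prior) / diag, where prior holds
            # the prior-row dot theta including the diagonal prior term
            mean = old + (r - prior) / diag
            new = mean + z[t, k] / np.sqrt(diag)
            dlt = new - old
            theta[t, k] = new
            for p in range(c0, c1):
                ehat[indices[p], t] -= wdata[p] * dlt
    return


@dataclass
class Draw:
    """One saved variance-component draw (unvalidated posterior sample).

    Posterior draws may sit arbitrarily close to singular, so they are kept
    raw; convert through the params classes before reuse as generating
    values.
    """

    G0: np.ndarray
    P0: np.ndarray
    L0: np.ndarray
    R0: np.ndarray


@dataclass
class PosteriorSummary:
    """Posterior mean/SD and P(>0) per monitored parameter, plus DIC."""

    table: "object"            # pandas DataFrame
    dic: float
    dbar: float
    pd_eff: float


def posterior_flags(draws: np.ndarray, threshold: float = 0.95) -> np.ndarray:
    """Mark parameters whose posterior mass is on one side of zero."""
    draws = np.atleast_2d(np.asarray(draws, float))
    p = (draws > 0).mean(axis=1)
    return (p > threshold) | (p < 1 - threshold)


def dic_from_deviances(deviances, dev_at_mean: float):
    """DIC = Dbar + pD, pD = Dbar - D(posterior mean)."""
    dbar = float(np.mean(deviances))
    pd_eff = dbar - float(dev_at_mean)
    return dbar + pd_eff, dbar, pd_eff


def _monitor_rows(vc, kind: str, n_for_ratios: int):
    """Named scalar parameters from one draw."""
    import itertools
    rows = {}
    G = vc.G0
    K = G.shape[0]
    for i in range(K):
        rows[f"G0_{i}{i}"] = G[i, i]
    for i, j in itertools.combinations(range(K), 2):
        den = np.sqrt(G[i, i] * G[j, j])
        rows[f"r_G0_{i}{j}"] = G[i, j] / den if den > 0 else 0.0
    for t in range(vc.P0.shape[0]):
        rows[f"P0_{t}{t}"] = vc.P0[t, t]
        rows[f"L0_{t}{t}"] = vc.L0[t, t]
        rows[f"R0_{t}{t}"] = vc.R0[t, t]
    if kind == "sam":
        T = vc.P0.shape[0]
        for t in range(T):
            s2d = G[t, t]
            s2s = G[T + t, T + t]
            sds = G[t, T + t]
            m = n_for_ratios - 1
            phe = s2d + m * s2s + vc.P0[t, t] + vc.L0[t, t] + vc.R0[t, t]
            rows[f"h2_{t}"] = s2d / phe
            rows[f"T2_{t}"] = (s2d + 2 * m * sds + m * m * s2s) / phe
    else:
        for t in range(vc.G0.shape[0]):
            phe = G[t, t] + vc.P0[t, t] + vc.L0[t, t] + vc.R0[t, t]
            rows[f"h2_{t}"] = G[t, t] / phe
    return rows


@dataclass
class GibbsResult:
    draws: list                 # variance-component objects, post burn-in
    summary: PosteriorSummary
    config: GibbsConfig
    kind: str


def gibbs_run(data, ped: Pedigree, spec: ModelSpec, cfg: GibbsConfig,
              start=None, pen_size_for_ratios: int = 8,
              monitor_threshold: float = 0.95) -> GibbsResult:
    """Run the Gibbs sampler; deterministic given cfg.seed.

    ``start`` supplies initial covariance matrices (a VarianceComponentsSAM2 /
    AM matching the model specification); by default an equal split of the observed
    phenotypic variance.
    """
    T = len(spec.traits)
    y = data[list(spec.traits)].to_numpy(dtype=float)
    n_rec = len(data)
    if start is None:
        v = np.var(y, axis=0)
        v = np.where(v > 1e-10, v, 1.0)  # degenerate data: start from unit scale
        if spec.kind == "sam":
            Gd = np.diag(np.concatenate([0.3 * v, 0.01 * v]))
            start = VarianceComponentsSAM2(G0=Gd, P0=np.diag(0.1 * v),
                                           L0=np.diag(0.1 * v), R0=np.diag(0.5 * v),
                                           trait_idx=tuple(range(T)))
        else:
            start = VarianceComponentsAM(G0=np.diag(0.4 * v), P0=np.diag(0.1 * v),
                                         L0=np.diag(0.1 * v), R0=np.diag(0.5 * v))
    sys = build_mme(data, ped, spec, start)
    m = sys.m
    n_anim = sys.n_anim
    combos = genetic_combos(spec)
    K = len(combos)
    # propriety: every IW conditional needs df = q - p - 1 > p - 1
    checks = [("genetic", n_anim, K), ("residual", n_rec, T)]
    if sys.pen_levels is not None:
        checks.append(("pen", len(sys.pen_levels), T))
    if sys.litter_levels is not None:
        checks.append(("litter", len(sys.litter_levels), T))
    for name, q, p in checks:
        if q - p - 1 <= p - 1:
            raise GibbsError(
                f"flat prior gives an improper {name} conditional: "
                f"{q} levels for dimension {p}")

    W = sys.W.tocsc()
    indptr, indices, wdata = W.indptr, W.indices, W.data.astype(np.float64)
    colsq = np.asarray(W.multiply(W).sum(axis=0)).ravel()
    site_kind = np.zeros(m, dtype=np.int64)
    site_animal = np.zeros(m, dtype=np.int64)
    sl = sys.slices
    if "pen" in sl:
        site_kind[sl["pen"]] = 1
    if "litter" in sl:
        site_kind[sl["litter"]] = 2
    combo_of_site = np.zeros((T, m), dtype=np.int64)
    combo_trait = np.array([t for (_e, t) in combos], dtype=np.int64)
    combo_off = np.zeros(K, dtype=np.int64)
    for c, (e, t) in enumerate(combos):
        combo_off[c] = t * m + sl[e].start
    gslices = [("d", "s") if spec.kind == "sam" else ("u",)][0]
    for e in gslices:
        s = sl[e]
        site_kind[s] = 3
        site_animal[s] = np.arange(n_anim)
        for t in range(T):
            c = combos.index((e, t))
            combo_of_site[t, s] = c
    # combo_off above is an absolute offset into the flattened theta; the
    # kernel indexes theta[tt, off + col] with a per-trait 2-d layout, so
    # store per-block starts instead
    for c, (e, t) in enumerate(combos):
        combo_off[c] = sl[e].start

    Ainv = sys.Ainv.tocsr()
    a_indptr, a_indices, a_data = Ainv.indptr, Ainv.indices, Ainv.data

    rng = np.random.default_rng(cfg.seed)
    theta = np.zeros((T, m))
    ehat = y.copy()
    vc = start
    draws = []
    mon = []
    deviances = []
    sum_ehat = np.zeros_like(ehat)
    sum_R0 = np.zeros((T, T))
    n_saved = 0
    has_pen = sys.pen_levels is not None
    has_lit = sys.litter_levels is not None
    ln2pi = np.log(2 * np.pi)

    for it in range(cfg.chain_length):
        R0inv = np.linalg.inv(vc.R0)
        P0inv = np.linalg.inv(vc.P0) if has_pen else np.zeros((T, T))
        L0inv = np.linalg.inv(vc.L0) if has_lit else np.zeros((T, T))
        G0inv = np.linalg.inv(vc.G0)
        z = rng.standard_normal((T, m))
        _sweep(indptr, indices, wdata, colsq, theta, ehat, z,
               R0inv, P0inv, L0inv, G0inv,
               site_kind, site_animal, combo_of_site,
               a_indptr, a_indices, a_data, combo_trait, combo_off)
        # --- covariance full conditionals (inverted Wishart, flat priors)
        M = np.column_stack([theta[combo_trait[c], combo_off[c]:combo_off[c] + n_anim]
                             for c in range(K)])
        Sg = M.T @ (Ainv @ M)
        G_new = stats.invwishart.rvs(df=n_anim - K - 1, scale=Sg, random_state=rng)
        G_new = np.atleast_2d(G_new)
        if has_pen:
            q = len(sys.pen_levels)
            P = theta[:, sl["pen"]].T
            Sp = P.T @ P
            P_new = np.atleast_2d(stats.invwishart.rvs(df=q - T - 1, scale=Sp,
                                                       random_state=rng))
        if has_lit:
            q = len(sys.litter_levels)
            L = theta[:, sl["litter"]].T
            Slit = L.T @ L
            L_new = np.atleast_2d(stats.invwishart.rvs(df=q - T - 1, scale=Slit,
                                                       random_state=rng))
        Sr = ehat.T @ ehat
        R_new = np.atleast_2d(stats.invwishart.rvs(df=n_rec - T - 1, scale=Sr,
                                                   random_state=rng))
        vc = Draw(G0=G_new,
                  P0=P_new if has_pen else np.asarray(vc.P0),
                  L0=L_new if has_lit else np.asarray(vc.L0),
                  R0=R_new)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            draws.append(vc)
            mon.append(_monitor_rows(vc, spec.kind, pen_size_for_ratios))
            Rinv_d = np.linalg.inv(vc.R0)
            _, logdetR = np.linalg.slogdet(vc.R0)
            quad = np.einsum("it,tj,ij->", ehat, Rinv_d, ehat)
            deviances.append(n_rec * (T * ln2pi + logdetR) + quad)
            sum_ehat += ehat
            sum_R0 += vc.R0
            n_saved += 1

    if n_saved == 0:
        raise GibbsError("no saved draws: check chain length / burn-in / thinning")
    import pandas as pd
    monf = pd.DataFrame(mon)
    mean_ehat = sum_ehat / n_saved
    mean_R0 = sum_R0 / n_saved
    Rinv_m = np.linalg.inv(mean_R0)
    _, logdetRm = np.linalg.slogdet(mean_R0)
    dev_mean = n_rec * (T * ln2pi + logdetRm) + np.einsum(
        "it,tj,ij->", mean_ehat, Rinv_m, mean_ehat)
    dic, dbar, pd_eff = dic_from_deviances(deviances, dev_mean)
    p_pos = (monf > 0).mean(axis=0)
    table = pd.DataFrame({
        "mean": monf.mean(axis=0),
        "sd": monf.std(axis=0, ddof=1),
        "p_positive": p_pos,
        "flagged": (p_pos > monitor_threshold) | (p_pos < 1 - monitor_threshold),
    })
    summary = PosteriorSummary(table=table, dic=float(dic), dbar=float(dbar),
                               pd_eff=float(pd_eff))
    return GibbsResult(draws=draws, summary=summary, config=cfg, kind=spec.kind)
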