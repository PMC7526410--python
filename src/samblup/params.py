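"""Variance components for the social animal model (SAM) and animal model (AM).

The SAM genetic covariance matrix ``G0`` is 6x6, ordered (d1, d2, d3, s1, s2,
s3) for traits (ADG, BF, FCR): direct genetic effects first, then indirect
(social) effects.  ``P0``, ``L0`` and ``R0`` are 3x3 pen, litter and residual
covariance matrices on the trait scale (kg/d, mm, kg/kg, squared).

The phenotypic variance convention used throughout is the variance of one
record with n-1 unrelated pen mates,

    sigma2_Phe = sigma2_d + (n-1) sigma2_s + sigma2_pen + sigma2_litter + sigma2_e,

the direct-indirect covariance of the same animal excluded because an animal
does not affect itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRAITS = ("adg", "bf", "fcr")
DEFAULT_PEN_SIZE = 8


class ValidationError(ValueError):
    pass


def _check_cov(M: np.ndarray, name: str, dim: int, min_eig: float = 1e-10) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (dim, dim):
        raise ValidationError(f"{name} must be {dim}x{dim}, got {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValidationError(f"{name} is not symmetric")
    ev = np.linalg.eigvalsh(M)
    if ev.min() <= min_eig:
        raise ValidationError(f"{name} is not positive definite (min eigenvalue {ev.min():.3g})")
    return 0.5 * (M + M.T)


@dataclass
class VarianceComponentsSAM:
    """SAM variance components: G0 (6x6), P0, L0, R0 (3x3 each)."""

    G0: np.ndarray
    P0: np.ndarray
    L0: np.ndarray
    R0: np.ndarray

    def __post_init__(self):
        self.G0 = _check_cov(self.G0, "G0", 6)
        self.P0 = _check_cov(self.P0, "P0", 3)
        self.L0 = _check_cov(self.L0, "L0", 3)
        self.R0 = _check_cov(self.R0, "R0", 3)

    @property
    def n_traits(self) -> int:
        return 3

    def direct_variance(self, trait: int) -> float:
        return float(self.G0[trait, trait])

    def indirect_variance(self, trait: int) -> float:
        return float(self.G0[3 + trait, 3 + trait])

    def ds_covariance(self, trait: int) -> float:
        return float(self.G0[trait, 3 + trait])

    def phenotypic_variance(self, trait: int, n: int = DEFAULT_PEN_SIZE) -> float:
        t = _check_trait(trait)
        return (
            self.direct_variance(t)
            + (n - 1) * self.indirect_variance(t)
            + self.P0[t, t]
            + self.L0[t, t]
            + self.R0[t, t]
        )

    def h2(self, trait: int, n: int = DEFAULT_PEN_SIZE) -> float:
        t = _check_trait(trait)
        return self.direct_variance(t) / self.phenotypic_variance(t, n)

    def T2(self, trait: int, n: int = DEFAULT_PEN_SIZE) -> float:
        """Ratio of total-breeding-value variance to phenotypic variance."""
        t = _check_trait(trait)
        return total_bv_variance(self, t, n) / self.phenotypic_variance(t, n)

    def subset_traits(self, traits) -> "VarianceComponentsSAM2":
        """Restrict to a subset of traits (e.g. the ADG+BF evaluation pair)."""
        t = np.asarray(traits, dtype=int)
        gidx = np.concatenate([t, 3 + t])
        return VarianceComponentsSAM2(
            G0=self.G0[np.ix_(gidx, gidx)],
            P0=self.P0[np.ix_(t, t)],
            L0=self.L0[np.ix_(t, t)],
            R0=self.R0[np.ix_(t, t)],
            trait_idx=tuple(int(x) for x in t),
        )


@dataclass
class VarianceComponentsSAM2:
    """SAM components restricted to k traits: G0 is 2k x 2k, rest k x k."""

    G0: np.ndarray
    P0: np.ndarray
    L0: np.ndarray
    R0: np.ndarray
    trait_idx: tuple = (0, 1)

    def __post_init__(self):
        k = len(self.trait_idx)
        self.G0 = _check_cov(self.G0, "G0", 2 * k)
        self.P0 = _check_cov(self.P0, "P0", k)
        self.L0 = _check_cov(self.L0, "L0", k)
        self.R0 = _check_cov(self.R0, "R0", k)

    @property
    def n_traits(self) -> int:
        return len(self.trait_idx)


@dataclass
class VarianceComponentsAM:
    """Classical animal model: a single additive genetic effect per trait."""

    G0: np.ndarray
    P0: np.ndarray
    L0: np.ndarray
    R0: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.G0).shape[0]
        self.G0 = _check_cov(self.G0, "G0", k)
        self.P0 = _check_cov(self.P0, "P0", k)
        self.L0 = _check_cov(self.L0, "L0", k)
        self.R0 = _check_cov(self.R0, "R0", k)

    @property
    def n_traits(self) -> int:
        return self.G0.shape[0]

    def phenotypic_variance(self, trait: int) -> float:
        t = int(trait)
        return float(self.G0[t, t] + self.P0[t, t] + self.L0[t, t] + self.R0[t, t])

    def h2(self, trait: int) -> float:
        return float(self.G0[trait, trait]) / self.phenotypic_variance(trait)

    def subset_traits(self, traits) -> "VarianceComponentsAM":
        t = np.asarray(traits, dtype=int)
        return VarianceComponentsAM(
            G0=self.G0[np.ix_(t, t)],
            P0=self.P0[np.ix_(t, t)],
            L0=self.L0[np.ix_(t, t)],
            R0=self.R0[np.ix_(t, t)],
        )


def _check_trait(trait: int) -> int:
    t = int(trait)
    if not 0 <= t <= 2:
        raise ValidationError(f"trait index must be 0, 1 or 2, got {trait}")
    return t


# --------------------------------------------------------------- construction
def from_ratios(
    h2,
    phe_var,
    ige_var,
    corr,
    pen_frac=0.05,
    litter_frac=0.05,
    pen_size_n: int = DEFAULT_PEN_SIZE,
) -> VarianceComponentsSAM:
    """Build SAM components from published ratio-scale parameters.

    Parameters
    ----------
    h2 : length-3
        Direct heritabilities per trait (ADG, BF, FCR).
    phe_var : length-3
        Phenotypic variances per trait.
    ige_var : length-3
        Indirect genetic variances per trait (absolute, trait units squared).
    corr : 6x6
        Correlation matrix over (d1, d2, d3, s1, s2, s3).
    pen_frac, litter_frac : scalar or length-3
        Pen and litter variances as fractions of phenotypic variance.
    pen_size_n
        Pen size used to back out the residual variance.
    """
    h2 = np.asarray(h2, float)
    phe = np.asarray(phe_var, float)
    s2s = np.asarray(ige_var, float)
    corr = np.asarray(corr, float)
    if np.any((h2 <= 0) | (h2 >= 1)):
        raise ValidationError("heritabilities must lie in (0, 1)")
    if np.any(np.abs(corr) > 1.0 + 1e-12):
        raise ValidationError("correlations must lie in [-1, 1]")
    pen_frac = np.broadcast_to(np.asarray(pen_frac, float), (3,))
    litter_frac = np.broadcast_to(np.asarray(litter_frac, float), (3,))
    s2d = h2 * phe
    sd = np.sqrt(np.concatenate([s2d, s2s]))
    G0 = corr * np.outer(sd, sd)
    s2p = pen_frac * phe
    s2l = litter_frac * phe
    s2e = phe - s2d - (pen_size_n - 1) * s2s - s2p - s2l
    if np.any(s2e <= 0):
        bad = TRAITS[int(np.argmax(s2e <= 0))]
        raise ValidationError(f"residual variance non-positive for trait {bad}")
    return VarianceComponentsSAM(G0=G0, P0=np.diag(s2p), L0=np.diag(s2l), R0=np.diag(s2e))


def duroc_reference_components(
    pen_frac=0.05, litter_frac=0.05, pen_size_n: int = DEFAULT_PEN_SIZE
) -> VarianceComponentsSAM:
    """Posterior-mean SAM parameters reported for a Duroc fattening line.

    Direct heritabilities 0.31/0.39/0.25 and phenotypic variances
    0.75/11.84/4.44 for ADG, BF and FCR; indirect genetic variances
    4e-3/0.04/0.03; the full direct-indirect genetic correlation structure as
    published.  Pen and litter fractions are not published and default to 5%
    of phenotypic variance each.
    """
    corr = np.eye(6)
    pairs = {
        (0, 3): -0.29, (0, 1): 0.52, (0, 4): -0.19, (0, 2): -0.03, (0, 5): -0.35,
        (3, 1): 0.24, (3, 4): 0.59, (3, 2): 0.70, (3, 5): 0.18,
        (1, 4): -0.09, (1, 2): 0.33, (1, 5): -0.34,
        (4, 2): -0.07, (4, 5): 0.33,
        (2, 5): -0.17,
    }
    for (i, j), v in pairs.items():
        corr[i, j] = corr[j, i] = v
    return from_ratios(
        h2=[0.31, 0.39, 0.25],
        phe_var=[0.75, 11.84, 4.44],
        ige_var=[4e-3, 0.04, 0.03],
        corr=corr,
        pen_frac=pen_frac,
        litter_frac=litter_frac,
        pen_size_n=pen_size_n,
    )


# ----------------------------------------------------------------- transforms
def total_bv_variance(vc: VarianceComponentsSAM, trait: int, n: int = DEFAULT_PEN_SIZE) -> float:
    """Variance of the total breeding value TBV = d + (n-1) s for one trait."""
    t = _check_trait(trait)
    if n < 2:
        raise ValidationError("pen size n must be >= 2")
    m = n - 1
    return vc.direct_variance(t) + 2 * m * vc.ds_covariance(t) + m * m * vc.indirect_variance(t)


def collapse_to_am(vc: VarianceComponentsSAM, n: int = DEFAULT_PEN_SIZE) -> VarianceComponentsAM:
    """Collapse SAM components to an AM by the TBV bilinear form at pen size n.

    The additive covariance between traits i and j is
    cov(d_i + (n-1) s_i, d_j + (n-1) s_j); P0, L0, R0 pass through.
    """
    m = n - 1
    T = np.zeros((3, 6))
    for t in range(3):
        T[t, t] = 1.0
        T[t, 3 + t] = m
    G_am = T @ vc.G0 @ T.T
    return VarianceComponentsAM(G0=G_am, P0=vc.P0.copy(), L0=vc.L0.copy(), R0=vc.R0.copy())


# ------------------------------------------------------------------ draw files
_TRIL6 = np.tril_indices(6)
_TRIL3 = np.tril_indices(3)


@dataclass
class ParameterDraws:
    """Ordered collection of SAM variance-component draws."""

    draws: list = field(default_factory=list)
    seed: int | None = None

    def __len__(self):
        return len(self.draws)

    def __iter__(self):
        return iter(self.draws)

    def __getitem__(self, i):
        return self.draws[i]


def _header() -> list[str]:
    cols = [f"g{i+1}{j+1}" for i, j in zip(*_TRIL6)]
    for name in ("p", "l", "r"):
        cols += [f"{name}{i+1}{j+1}" for i, j in zip(*_TRIL3)]
    return cols


def _to_row(vc: VarianceComponentsSAM) -> np.ndarray:
    return np.concatenate(
        [vc.G0[_TRIL6], vc.P0[_TRIL3], vc.L0[_TRIL3], vc.R0[_TRIL3]]
    )


def _from_row(row: np.ndarray) -> VarianceComponentsSAM:
    def unpack(vals, dim, tril):
        M = np.zeros((dim, dim))
        M[tril] = vals
        M = M + M.T - np.diag(np.diag(M))
        return M

    G0 = unpack(row[:21], 6, _TRIL6)
    P0 = unpack(row[21:27], 3, _TRIL3)
    L0 = unpack(row[27:33], 3, _TRIL3)
    R0 = unpack(row[33:39], 3, _TRIL3)
    return VarianceComponentsSAM(G0=G0, P0=P0, L0=L0, R0=R0)


def write_draws(draws: ParameterDraws, path) -> None:
    """Write draws as delimited text: lower triangles of G0, P0, L0, R0 per row."""
    with open(path, "w") as fh:
        fh.write("\t".join(_header()) + "\n")
        for vc in draws:
            fh.write("\t".join(f"{v:.12g}" for v in _to_row(vc)) + "\n")


def read_draws(path) -> ParameterDraws:
    """Read a draws file; raises with the offending line/draw index on error."""
    draws = []
    with open(path) as fh:
        lines = fh.readlines()
    header_seen = False
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        vals = line.split()
        if len(vals) != 39:
            raise ValidationError(f"line {ln}: expected 39 values, got {len(vals)}")
        try:
            row = np.array([float(v) for v in vals])
        except ValueError as e:
            raise ValidationError(f"line {ln}: {e}") from None
        try:
            draws.append(_from_row(row))
        except ValidationError as e:
            raise ValidationError(f"draw {len(draws)} (line {ln}): {e}") from None
    return ParameterDraws(draws=draws)


def sample_draws(
    vc: VarianceComponentsSAM, n_draws: int, seed: int, rel_sd: float = 0.15
) -> ParameterDraws:
    """Jitter components to emulate draws from a posterior around ``vc``.

    Each covariance matrix is perturbed as a Wishart-style resample with
    effective degrees of freedom chosen so the relative SD of the variances is
    roughly ``rel_sd``.  Used when a file of true posterior draws is not
    supplied.
    """
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_draws:
        mats = []
        ok = True
        for M in (vc.G0, vc.P0, vc.L0, vc.R0):
            p = M.shape[0]
            df = max(int(round(2.0 / rel_sd**2)), p + 2)
            L = np.linalg.cholesky(M / df)
            X = rng.standard_normal((df, p)) @ L.T
            mats.append(X.T @ X)
        try:
            out.append(VarianceComponentsSAM(*mats))
        except ValidationError:
            ok = False
        if not ok:
            continue
    return ParameterDraws(draws=out, seed=seed)
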