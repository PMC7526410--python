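"""Synthetic datasets with the structure of the Duroc feeding-station study.

Emulates ~1144 recorded pigs housed in ~97 mixed-litter pens of 7-15 animals
across 10 batches, litters nested in dams, with ADG/BF/FCR generated under
the social animal model: for each trait

    y_i = fixed + pen + litter + d_i + sum_{j in pen mates of i} s_j + e_i,

where the stacked direct and indirect genetic effects [d, s] are multivariate
normal with covariance G0 (x) A.  Genetic effects are sampled by pedigree
recursion (infinitesimal model): founders from G0, descendants as mid-parent
plus a Mendelian deviation with covariance G0 * (0.5 - 0.25 (F_sire + F_dam)).

The generator reproduces the study's design variables, not its measurement
process: no feeding-station error, no missing records, no selection history
in the base population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .params import VarianceComponentsSAM
from .pedigree import Pedigree

TRAIT_COLS = ("adg", "bf", "fcr")


@dataclass
class StudyDesign:
    """Sizes and covariate ranges of the recorded-population design."""

    n_animals: int = 1144
    n_batches: int = 10
    n_pens: int = 97
    pen_size_range: tuple = (7, 15)
    litter_size_range: tuple = (4, 12)
    dams_per_sire: int = 3
    age_end_mean: float = 177.0
    age_end_sd: float = 9.0


@dataclass
class PhenotypeDataset:
    """Records plus the hidden simulated truth used only for testing.

    ``data`` columns: animal, batch, pen, litter, age_end, n_pen, adg, bf, fcr.
    ``truth`` holds the simulated components per record and trait; ``bv`` the
    per-animal genetic effects for the whole pedigree, ordered as the G0 of
    the generating components (direct blocks first, then indirect).
    """

    data: pd.DataFrame
    bv: np.ndarray
    truth: pd.DataFrame | None = None

    @property
    def n_records(self) -> int:
        return len(self.data)

    def write(self, path, truth_path=None) -> None:
        self.data.to_csv(path, sep="\t", index=False)
        if truth_path is not None and self.truth is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def sample_genetic_effects(ped: Pedigree, G0: np.ndarray, rng: np.random.Generator,
                           start: int = 0, bv: np.ndarray | None = None) -> np.ndarray:
    """Sample [d, s] for every animal by pedigree recursion.

    ``start``/``bv`` allow extending an existing sample when the pedigree has
    grown (the prefix is left untouched).  Returns an (n, k) array with k the
    dimension of ``G0``.
    """
    n, k = ped.n, G0.shape[0]
    F = ped.inbreeding()
    scale = np.ones(n)
    has_s, has_d = ped.sire > 0, ped.dam > 0
    both = has_s & has_d
    # Mendelian-deviation variance scale: 1 for founders (and for animals with
    # an unknown parent the missing side contributes base variance)
    scale[both] = 0.5 - 0.25 * (F[ped.sire[both] - 1] + F[ped.dam[both] - 1])
    one = has_s ^ has_d
    par = np.where(has_s, ped.sire, ped.dam) - 1
    scale[one] = 0.75 - 0.25 * F[par[one]]
    L = np.linalg.cholesky(G0)
    if bv is None:
        bv = np.empty((n, k))
        start = 0
    else:
        bv = np.vstack([bv[:start], np.empty((n - start, k))])
    dev = rng.standard_normal((n - start, k)) @ L.T * np.sqrt(scale[start:])[:, None]
    full_dev = np.zeros((n, k))
    full_dev[start:] = dev
    _recurse_abs(ped.sire, ped.dam, full_dev, bv, start)
    return bv


@njit(cache=True)
def _recurse_abs(sire, dam, dev, bv, start):
    n = sire.shape[0]
    for i in range(start, n):
        s = sire[i] - 1
        d = dam[i] - 1
        for k in range(bv.shape[1]):
            m = 0.0
            if s >= 0:
                m += 0.5 * bv[s, k]
            if d >= 0:
                m += 0.5 * bv[d, k]
            bv[i, k] = m + dev[i, k]


def mendelian_sample(parent_values, F_sire, F_dam, vc: VarianceComponentsSAM,
                     rng: np.random.Generator) -> np.ndarray:
    """One offspring [d, s] 6-vector from parents' values and inbreeding.

    ``parent_values`` is (sire_vec, dam_vec) or None for a founder draw.
    """
    L = np.linalg.cholesky(vc.G0)
    if parent_values is None:
        return L @ rng.standard_normal(6)
    sv, dv = parent_values
    scale = 0.5 - 0.25 * (F_sire + F_dam)
    return 0.5 * (np.asarray(sv) + np.asarray(dv)) + np.sqrt(scale) * (L @ rng.standard_normal(6))


# ----------------------------------------------------------------- structure
def make_study_structure(design: StudyDesign, seed: int):
    """Pedigree and batch/pen/litter layout for the recorded population.

    Returns (pedigree, frame) where the frame has one row per recorded animal
    with its design variables; founders (sires and dams) precede the recorded
    animals in the pedigree and carry no records.
    """
    rng = np.random.default_rng(seed)
    lo, hi = design.pen_size_range
    # pens per batch: spread n_pens as evenly as possible
    pens_per_batch = np.full(design.n_batches, design.n_pens // design.n_batches)
    pens_per_batch[: design.n_pens % design.n_batches] += 1
    # pen sizes: draw in range, then adjust to hit the exact animal total
    sizes = rng.integers(lo, hi + 1, design.n_pens)
    diff = design.n_animals - sizes.sum()
    while diff != 0:
        j = rng.integers(design.n_pens)
        step = 1 if diff > 0 else -1
        if lo <= sizes[j] + step <= hi:
            sizes[j] += step
            diff -= step
    # litters: fill each batch with whole litters in processing order
    mean_ls = 0.5 * (design.litter_size_range[0] + design.litter_size_range[1])
    batch_of_pen = np.repeat(np.arange(design.n_batches), pens_per_batch)
    litters = []  # litter id -> size (possibly truncated by batch boundary)
    rec_batch, rec_pen, rec_litter = [], [], []
    pen_id = 0
    for b in range(design.n_batches):
        batch_total = int(sizes[batch_of_pen == b].sum())
        placed = 0
        while placed < batch_total:
            ls = int(rng.integers(design.litter_size_range[0], design.litter_size_range[1] + 1))
            ls = min(ls, batch_total - placed)
            litters.append(ls)
            lid = len(litters) - 1
            rec_batch += [b] * ls
            rec_litter += [lid] * ls
            placed += ls
        # pens filled sequentially by litter order within the batch
        fill = np.repeat(np.arange(pen_id, pen_id + pens_per_batch[b]),
                         sizes[pen_id: pen_id + pens_per_batch[b]])
        rec_pen += fill.tolist()
        pen_id += pens_per_batch[b]
    n_litters = len(litters)
    n_dams = n_litters
    n_sires = max(1, int(np.ceil(n_dams / design.dams_per_sire)))
    sire_of_litter = 1 + rng.integers(0, n_sires, n_litters)
    dam_of_litter = n_sires + 1 + np.arange(n_dams)
    n_founders = n_sires + n_dams
    sire = np.zeros(n_founders + design.n_animals, dtype=np.int64)
    dam = np.zeros_like(sire)
    lit = np.asarray(rec_litter)
    sire[n_founders:] = sire_of_litter[lit]
    dam[n_founders:] = dam_of_litter[lit]
    ped = Pedigree(sire, dam)
    frame = pd.DataFrame(
        {
            "animal": np.arange(n_founders + 1, n_founders + design.n_animals + 1),
            "batch": np.asarray(rec_batch),
            "pen": np.asarray(rec_pen),
            "litter": lit,
            "age_end": np.round(rng.normal(design.age_end_mean, design.age_end_sd,
                                           design.n_animals)),
        }
    )
    frame["n_pen"] = frame.groupby("pen")["pen"].transform("size")
    return ped, frame


@dataclass
class FixedEffects:
    """True systematic effects; all zero by default (estimation is invariant)."""

    trait_means: np.ndarray = field(default_factory=lambda: np.zeros(3))
    batch_effects: np.ndarray | None = None   # (n_batches, 3)
    age_slope: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_pen_slope: np.ndarray = field(default_factory=lambda: np.zeros(3))


def simulate_phenotypes(frame: pd.DataFrame, bv: np.ndarray, vc, rng,
                        fixed: FixedEffects | None = None,
                        covariate_cols: dict | None = None) -> pd.DataFrame:
    """Generate trait records for the animals in ``frame`` under the SAM.

    ``bv`` is the full-pedigree genetic sample ordered (d-traits, s-traits);
    returns a truth frame with every simulated component (reconstruction
    identity: y equals the sum of its columns exactly).
    """
    k = vc.P0.shape[0]
    fixed = fixed or FixedEffects(trait_means=np.zeros(k))
    pens, pen_codes = np.unique(frame["pen"], return_inverse=True)
    lits, lit_codes = np.unique(frame["litter"], return_inverse=True)
    pen_eff = rng.multivariate_normal(np.zeros(k), vc.P0, size=len(pens))
    lit_eff = rng.multivariate_normal(np.zeros(k), vc.L0, size=len(lits))
    res = rng.multivariate_normal(np.zeros(k), vc.R0, size=len(frame))
    anim = frame["animal"].to_numpy() - 1
    d = bv[anim, :k]
    s_all = bv[:, k:2 * k]
    # received social effects: pen totals minus own contribution
    s_own = s_all[anim]
    pen_tot = np.zeros((len(pens), k))
    np.add.at(pen_tot, pen_codes, s_own)
    s_recv = pen_tot[pen_codes] - s_own
    sys_part = np.tile(np.asarray(fixed.trait_means, float)[:k], (len(frame), 1))
    if fixed.batch_effects is not None:
        sys_part = sys_part + np.asarray(fixed.batch_effects)[frame["batch"].to_numpy(), :k]
    if covariate_cols:
        for col, slopes in covariate_cols.items():
            sys_part = sys_part + np.outer(frame[col].to_numpy(), np.asarray(slopes)[:k])
    y = sys_part + pen_eff[pen_codes] + lit_eff[lit_codes] + d + s_recv + res
    truth = {}
    names = TRAIT_COLS[:k] if k <= 3 else [f"t{i}" for i in range(k)]
    for t, name in enumerate(names):
        truth[f"sys_{name}"] = sys_part[:, t]
        truth[f"pen_{name}"] = pen_eff[pen_codes, t]
        truth[f"litter_{name}"] = lit_eff[lit_codes, t]
        truth[f"d_{name}"] = d[:, t]
        truth[f"s_recv_{name}"] = s_recv[:, t]
        truth[f"e_{name}"] = res[:, t]
        truth[name] = y[:, t]
    truth = pd.DataFrame(truth)
    truth.insert(0, "animal", frame["animal"].to_numpy())
    return truth


def simulate_dataset(design: StudyDesign | None = None,
                     vc: VarianceComponentsSAM | None = None,
                     fixed: FixedEffects | None = None,
                     seed: int = 0):
    """Full synthetic study: structure, genetic effects, records.

    Returns (pedigree, PhenotypeDataset).  Deterministic given ``seed``.
    """
    from .params import duroc_reference_components

    design = design or StudyDesign()
    vc = vc or duroc_reference_components()
    ped, frame = make_study_structure(design, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    bv = sample_genetic_effects(ped, vc.G0, rng)
    truth = simulate_phenotypes(frame, bv, vc, rng, fixed=fixed)
    k = vc.P0.shape[0]
    data = frame.copy()
    for name in TRAIT_COLS[:k]:
        data[name] = truth[name].to_numpy()
    return ped, PhenotypeDataset(data=data, bv=bv, truth=truth)
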