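"""Pedigree storage and relationship-matrix algebra.

Animals are identified by consecutive positive integers 1..n, sorted so that
parents always precede offspring.  Unknown parents are coded 0; there are no
genetic groups (a single line with a flat base population is assumed).

The numerator relationship matrix ``A`` is built with the tabular method; its
sparse inverse with Henderson's rules, using Meuwissen-Luo inbreeding so the
inverse is exact for inbred pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse


class PedigreeError(ValueError):
    """Raised for unknown identifiers or ordering violations."""


@njit(cache=True)
def _inbreeding_ml(sire, dam, f_out, start):
    """Meuwissen & Luo tracing, filling f_out[start:] (0-based arrays)."""
    n = sire.shape[0]
    # Mendelian (within-family) variance coefficient d_i needs parent F only.
    anc = np.empty(n, dtype=np.float64)   # path coefficients, indexed by animal
    mark = np.full(n, -1, dtype=np.int64)  # which animal the slot belongs to
    stack = np.empty(n, dtype=np.int64)
    for i in range(start, n):
        s = sire[i] - 1
        d = dam[i] - 1
        if s < 0 or d < 0:
            f_out[i] = 0.0
            continue
        # a_ii = sum_k c_k^2 d_k over ancestors k, seeding the animal itself
        # with path coefficient 1; then F_i = a_ii - 1
        aii = 0.0
        mark[i] = i
        anc[i] = 1.0
        work = stack
        work[0] = i
        nw = 1
        while nw > 0:
            # pop largest
            k = work[nw - 1]
            nw -= 1
            ck = anc[k]
            ks = sire[k] - 1
            kd = dam[k] - 1
            # d_k = 1 - 0.25(1+F_s) - 0.25(1+F_d); missing parent contributes 0
            dk = 1.0
            if ks >= 0:
                dk -= 0.25 * (1.0 + f_out[ks])
            if kd >= 0:
                dk -= 0.25 * (1.0 + f_out[kd])
            aii += ck * ck * dk
            for p in (ks, kd):
                if p >= 0:
                    if mark[p] == i:
                        anc[p] += 0.5 * ck
                    else:
                        mark[p] = i
                        anc[p] = 0.5 * ck
                        # insert keeping 'work' sorted ascending
                        lo = 0
                        hi = nw
                        while lo < hi:
                            mid = (lo + hi) // 2
                            if work[mid] < p:
                                lo = mid + 1
                            else:
                                hi = mid
                        for m in range(nw, lo, -1):
                            work[m] = work[m - 1]
                        work[lo] = p
                        nw += 1
        f_out[i] = aii - 1.0


@njit(cache=True)
def _tabular_A(sire, dam):
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s = sire[i] - 1
        d = dam[i] - 1
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[j, s]
            if d >= 0:
                v += 0.5 * A[j, d]
            A[i, j] = v
            A[j, i] = v
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return A


@dataclass
class Pedigree:
    """Sorted pedigree: arrays of sire and dam codes (0 = unknown parent).

    Parameters
    ----------
    sire, dam
        Integer arrays, ``sire[i]``/``dam[i]`` give the parents of animal
        ``i + 1``; both must be smaller than ``i + 1`` (parents precede
        offspring) and 0 marks an unknown parent.
    sex
        Optional per-animal sex codes ('M'/'F'); checked against parent roles.
    generation
        Optional per-animal generation labels.
    """

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray | None = None
    generation: np.ndarray | None = None
    _F: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.sire = np.ascontiguousarray(self.sire, dtype=np.int64)
        self.dam = np.ascontiguousarray(self.dam, dtype=np.int64)
        if self.sire.shape != self.dam.shape or self.sire.ndim != 1:
            raise PedigreeError("sire and dam must be 1-d arrays of equal length")
        n = self.n
        ids = np.arange(1, n + 1)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if np.any(par < 0) or np.any(par > n):
                raise PedigreeError(f"{name} contains an unknown animal id")
            if np.any(par >= ids):
                bad = int(ids[par >= ids][0])
                raise PedigreeError(
                    f"pedigree not sorted: animal {bad} has {name} {int(par[bad-1])} >= its own id"
                )
        if self.sex is not None:
            self.sex = np.asarray(self.sex)
            males = set(self.sire[self.sire > 0].tolist())
            females = set(self.dam[self.dam > 0].tolist())
            for a in males & females:
                raise PedigreeError(f"animal {a} appears as both sire and dam")
            for a in males:
                if self.sex[a - 1] == "F":
                    raise PedigreeError(f"sire {a} is recorded as female")
            for a in females:
                if self.sex[a - 1] == "M":
                    raise PedigreeError(f"dam {a} is recorded as male")

    @property
    def n(self) -> int:
        return self.sire.shape[0]

    # ------------------------------------------------------------------ io
    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "Pedigree":
        df = df.sort_values(df.columns[0])
        ids = df.iloc[:, 0].to_numpy(dtype=np.int64)
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise PedigreeError("animal ids must be consecutive integers 1..n")
        return cls(df.iloc[:, 1].to_numpy(np.int64), df.iloc[:, 2].to_numpy(np.int64), **kw)

    @classmethod
    def read(cls, path) -> "Pedigree":
        """Read a 3-column delimited text file (animal, sire, dam); optional header."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        if not str(df.columns[0]).lstrip("-").isdigit():
            pass  # header row consumed
        else:  # headerless: first row was data
            df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
        return cls.from_frame(df.iloc[:, :3])

    def write(self, path) -> None:
        pd.DataFrame(
            {"animal": np.arange(1, self.n + 1), "sire": self.sire, "dam": self.dam}
        ).to_csv(path, sep="\t", index=False)

    # -------------------------------------------------------- relationships
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficients F (Meuwissen-Luo tracing)."""
        if self._F is None or self._F.shape[0] != self.n:
            F = np.zeros(self.n)
            if self._F is not None and self._F.shape[0] < self.n:
                # pedigree only ever grows; F of existing animals is unchanged
                F[: self._F.shape[0]] = self._F
                start = self._F.shape[0]
            else:
                start = 0
            _inbreeding_ml(self.sire, self.dam, F, start)
            self._F = F
        return self._F

    def mendelian_variance_coeff(self) -> np.ndarray:
        """d_i = 1 - 0.25(1+F_s) - 0.25(1+F_d): within-family variance scale."""
        F = self.inbreeding()
        d = np.ones(self.n)
        has_s = self.sire > 0
        has_d = self.dam > 0
        d[has_s] -= 0.25 * (1.0 + F[self.sire[has_s] - 1])
        d[has_d] -= 0.25 * (1.0 + F[self.dam[has_d] - 1])
        return d

    def A(self, subset=None) -> np.ndarray:
        """Dense numerator relationship matrix (tabular method).

        ``subset`` restricts the returned rows/columns to those ids (the full
        recursion still runs over all ancestors).
        """
        Afull = _tabular_A(self.sire, self.dam)
        if subset is None:
            return Afull
        idx = np.asarray(subset, dtype=np.int64)
        if np.any(idx < 1) or np.any(idx > self.n):
            raise PedigreeError("subset contains an unknown animal id")
        return Afull[np.ix_(idx - 1, idx - 1)]

    def A_inverse(self) -> sparse.csr_matrix:
        """Sparse A^-1 by Henderson's rules with inbreeding accounted for."""
        n = self.n
        alpha = 1.0 / self.mendelian_variance_coeff()
        rows, cols, vals = [], [], []
        i = np.arange(n)
        s = self.sire - 1
        d = self.dam - 1
        # diagonal of animal itself
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in (s, d):
            m = p >= 0
            rows.append(i[m]); cols.append(p[m]); vals.append(-0.5 * alpha[m])
            rows.append(p[m]); cols.append(i[m]); vals.append(-0.5 * alpha[m])
            rows.append(p[m]); cols.append(p[m]); vals.append(0.25 * alpha[m])
        m = (s >= 0) & (d >= 0)
        rows.append(s[m]); cols.append(d[m]); vals.append(0.25 * alpha[m])
        rows.append(d[m]); cols.append(s[m]); vals.append(0.25 * alpha[m])
        Ainv = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        return Ainv.tocsr()

    # ---------------------------------------------------------- relatedness
    def _check_id(self, a: int) -> None:
        if not 1 <= a <= self.n:
            raise PedigreeError(f"unknown animal id {a}")

    def ancestors_depth2(self, a: int) -> frozenset:
        """Parents and grandparents of ``a`` (known ones only)."""
        self._check_id(a)
        out = set()
        for p in (self.sire[a - 1], self.dam[a - 1]):
            if p > 0:
                out.add(int(p))
                for g in (self.sire[p - 1], self.dam[p - 1]):
                    if g > 0:
                        out.add(int(g))
        return frozenset(out)

    def share_grandparent(self, a: int, b: int) -> bool:
        """True if a and b have any common ancestor at depth <= 2.

        A shared parent also counts ("close relatives" includes sib and
        parent-offspring matings under this reading).
        """
        return bool(self.ancestors_depth2(a) & self.ancestors_depth2(b))


def concat_generation(ped: Pedigree, sire_new, dam_new, sex_new=None, gen_label=None) -> Pedigree:
    """Extend a pedigree with a new cohort, carrying the inbreeding cache over."""
    sire = np.concatenate([ped.sire, np.asarray(sire_new, dtype=np.int64)])
    dam = np.concatenate([ped.dam, np.asarray(dam_new, dtype=np.int64)])
    sex = None
    if ped.sex is not None and sex_new is not None:
        sex = np.concatenate([ped.sex, np.asarray(sex_new)])
    gen = None
    if ped.generation is not None and gen_label is not None:
        gen = np.concatenate([ped.generation, np.full(len(sire_new), gen_label)])
    out = Pedigree(sire, dam, sex=sex, generation=gen)
    out._F = ped._F  # prefix is unchanged; inbreeding() extends it lazily
    return out
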