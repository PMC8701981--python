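"""Pedigree relationship matrices.

Implements the numerator relationship matrix A by the recursive tabular
method, Henderson's direct construction of the sparse inverse A^-1 with
inbreeding, extraction of the genotyped-animal block A22, and the average
inbreeding / coancestry summaries that enter the LR-method accuracy
denominator.

Animal codes are 1-based throughout, with 0 standing for an unknown parent,
which mirrors the pedigree file convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve_triangular

from ._kernels import inbreeding_tabular, tabular_a

RELATIONSHIP_KINDS = frozenset(
    {"A", "A_inv", "A22", "A22_inv", "G", "G_blend", "H_inv"}
)


@dataclass
class Pedigree:
    """A topologically ordered pedigree.

    ids holds the external (string) identifier of each animal in renumbered
    order; sire/dam hold 1-based parent codes with 0 for unknown, and every
    parent code is strictly smaller than its offspring's code.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray | None = None
    _code_of: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not self._code_of:
            self._code_of = {a: i + 1 for i, a in enumerate(self.ids)}
        self._check_ordered()

    def _check_ordered(self):
        n = len(self.ids)
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise ValueError("sire/dam arrays must match the number of animals")
        for i in range(n):
            if self.sire[i] > i or self.dam[i] > i:
                raise ValueError(
                    f"pedigree not topologically ordered: animal {i + 1} "
                    f"({self.ids[i]}) has a parent with a larger code"
                )
            if self.sire[i] == i + 1 or self.dam[i] == i + 1:
                raise ValueError(f"animal {self.ids[i]} is its own parent")

    def __len__(self):
        return len(self.ids)

    def code(self, animal_id) -> int:
        """1-based code of an external identifier."""
        return self._code_of[animal_id]

    def codes(self, animal_ids) -> np.ndarray:
        try:
            return np.array([self._code_of[a] for a in animal_ids], dtype=np.int64)
        except KeyError as err:
            raise KeyError(f"animal {err.args[0]!r} not in pedigree") from None

    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficients F_i (exact, tabular method)."""
        return inbreeding_tabular(self.sire, self.dam)

    def mendelian_variances(self) -> np.ndarray:
        """Within-family (Mendelian sampling) variances d_i.

        d_i = 0.5 - 0.25 (F_s + F_d) with both parents known,
        0.75 - 0.25 F_p with one parent known, and 1 for founders.
        """
        F = self.inbreeding()
        n = len(self)
        d = np.ones(n)
        for i in range(n):
            s, m = self.sire[i], self.dam[i]
            if s > 0 and m > 0:
                d[i] = 0.5 - 0.25 * (F[s - 1] + F[m - 1])
            elif s > 0:
                d[i] = 0.75 - 0.25 * F[s - 1]
            elif m > 0:
                d[i] = 0.75 - 0.25 * F[m - 1]
        return d

    def _lower_factor(self) -> sp.csr_matrix:
        # L = I - P with P carrying 0.5 at each known parent; A = L^-1 D L^-T
        n = len(self)
        rows, cols, vals = [], [], []
        for i in range(n):
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
            for p in (self.sire[i], self.dam[i]):
                if p > 0:
                    rows.append(i)
                    cols.append(p - 1)
                    vals.append(-0.5)
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix with its animal ordering and role tag."""

    values: object  # dense ndarray or scipy sparse
    ids: list
    kind: str

    def __post_init__(self):
        if self.kind not in RELATIONSHIP_KINDS:
            raise ValueError(f"unknown relationship-matrix kind {self.kind!r}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")

    @property
    def n(self) -> int:
        return len(self.ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)


@dataclass
class InbreedingSummary:
    """Average inbreeding and pairwise coancestry of a stated animal group."""

    F: np.ndarray
    F_bar: float
    f_bar: float


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Full numerator relationship matrix by the tabular method.

    A_ii = 1 + F_i with F_i = 0.5 A(s,d); off-diagonals follow the parent
    recursion A_ij = 0.5 (A_j,s + A_j,d).
    """
    A = tabular_a(pedigree.sire, pedigree.dam)
    return RelationshipMatrix(A, list(pedigree.ids), "A")


def build_A_inverse(pedigree: Pedigree) -> RelationshipMatrix:
    """Sparse A^-1 from per-animal contributions (Henderson, with inbreeding).

    Each animal adds 1/d_i times the outer product of (1, -0.5, -0.5) over
    (itself, sire, dam) restricted to known parents, where d_i is the
    Mendelian sampling variance accounting for parental inbreeding.
    """
    n = len(pedigree)
    d = pedigree.mendelian_variances()
    rows, cols, vals = [], [], []
    for i in range(n):
        b = 1.0 / d[i]
        parents = [p - 1 for p in (pedigree.sire[i], pedigree.dam[i]) if p > 0]
        rows.append(i)
        cols.append(i)
        vals.append(b)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * b, -0.5 * b]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * b)
    Ainv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    Ainv.sum_duplicates()
    return RelationshipMatrix(Ainv, list(pedigree.ids), "A_inv")


def _a_submatrix(pedigree: Pedigree, idx0: np.ndarray) -> np.ndarray:
    """Principal submatrix of A over 0-based animal indices idx0.

    Uses the factorisation A = L^-1 D L^-T (L sparse triangular), so only the
    requested columns of A are ever formed — the full dense A never is.
    """
    n = len(pedigree)
    L = pedigree._lower_factor()
    d = pedigree.mendelian_variances()
    E = np.zeros((n, len(idx0)))
    E[idx0, np.arange(len(idx0))] = 1.0
    W = spsolve_triangular(sp.csr_matrix(L.T), E, lower=False)
    V = spsolve_triangular(L, d[:, None] * W, lower=True)
    sub = V[idx0, :]
    return 0.5 * (sub + sub.T)


def extract_A22(pedigree: Pedigree, genotyped_ids) -> RelationshipMatrix:
    """Pedigree relationship block A22 over the genotyped animals.

    Returned in genotype-file order; computed column-by-column through the
    triangular factorisation of A rather than via the full dense matrix.
    """
    codes = pedigree.codes(genotyped_ids)
    A22 = _a_submatrix(pedigree, codes - 1)
    return RelationshipMatrix(A22, list(genotyped_ids), "A22")


def inbreeding_summary(pedigree: Pedigree, group) -> InbreedingSummary:
    """Mean inbreeding F-bar and mean pairwise coancestry f-bar of a group.

    F-bar averages A_ii - 1 over the group; f-bar averages A_ij / 2 over
    distinct unordered pairs (self-pairs excluded — they belong to F-bar).
    A singleton group has no pairs; f-bar is reported as 0 with a warning.
    """
    group = list(group)
    if not group:
        raise ValueError("group must be non-empty")
    codes = pedigree.codes(group)
    sub = _a_submatrix(pedigree, codes - 1)
    F = np.diag(sub) - 1.0
    F_bar = float(F.mean())
    k = len(group)
    if k == 1:
        warnings.warn("singleton group: mean coancestry undefined, reporting 0")
        f_bar = 0.0
    else:
        off_sum = sub.sum() - np.trace(sub)
        f_bar = float(off_sum / (k * (k - 1)) / 2.0)
    return InbreedingSummary(F=F, F_bar=F_bar, f_bar=f_bar)


def export_A_inverse_triplets(ainv: RelationshipMatrix, path) -> None:
    """Write A^-1 as 1-based (row, col, value) triplets, lower triangle."""
    if ainv.kind != "A_inv":
        raise ValueError("expected a matrix of kind A_inv")
    coo = sp.coo_matrix(sp.tril(ainv.values))
    with open(path, "w") as fh:
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r + 1}\t{c + 1}\t{v:.10g}\n")
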