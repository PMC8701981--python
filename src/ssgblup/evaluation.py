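"""Henderson's mixed model equations under PBLUP and single-step GBLUP.

The animal model is y = Xb + Zu + e with a slaughter-date factor (cell-means
coding, no explicit intercept) and a centred slaughter-age covariate as the
fixed part, and breeding values u with prior N(0, K sigma_a2).  PBLUP uses
K^-1 = A^-1; single-step GBLUP replaces it with H^-1, which adds
(w_G G + w_A A22)^-1 - A22^-1 in the genotyped block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .pedigree import RelationshipMatrix


@dataclass
class ModelSpec:
    """Trait name and the variance ratio lambda = sigma_e2 / sigma_a2."""

    trait: str
    variance_ratio: float

    def __post_init__(self):
        if self.variance_ratio <= 0:
            raise ValueError("variance ratio must be positive")


@dataclass
class EvaluationResult:
    """Solutions of one model fit: fixed effects and per-animal (G)EBV."""

    ebv: np.ndarray
    animal_ids: list
    fixed_solutions: pd.Series
    method: str
    dataset: str
    trait: str

    def ebv_series(self) -> pd.Series:
        return pd.Series(self.ebv, index=self.animal_ids, name="ebv")

    def ebv_of(self, animal_ids) -> np.ndarray:
        s = self.ebv_series()
        return s.loc[list(animal_ids)].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal_ids,
                "method": self.method,
                "dataset": self.dataset,
                "trait": self.trait,
                "ebv": self.ebv,
            }
        )


def _invert_pd(dense: np.ndarray, name: str) -> np.ndarray:
    try:
        c = np.linalg.cholesky(dense)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"{name} is singular or not positive definite"
        ) from None
    inv = np.linalg.inv(c)
    return inv.T @ inv


def build_H_inverse(
    A_inv: RelationshipMatrix,
    A22: RelationshipMatrix,
    G_blend: RelationshipMatrix,
    genotyped_ids,
) -> RelationshipMatrix:
    """Single-step combined relationship inverse.

    H^-1 = A^-1 everywhere, plus G_blend^-1 - A22^-1 in the genotyped block.
    G_blend and A22 must be indexed identically by genotyped_ids, which map
    into the full pedigree ordering of A^-1.
    """
    genotyped_ids = list(genotyped_ids)
    if list(A22.ids) != genotyped_ids or list(G_blend.ids) != genotyped_ids:
        raise ValueError("A22 and G_blend must be ordered by genotyped_ids")
    pos = {a: i for i, a in enumerate(A_inv.ids)}
    try:
        gi = np.array([pos[a] for a in genotyped_ids], dtype=np.int64)
    except KeyError as err:
        raise KeyError(f"genotyped animal {err.args[0]!r} not in pedigree") from None
    H = sp.lil_matrix(sp.csr_matrix(A_inv.values), copy=True)
    if genotyped_ids:
        delta = _invert_pd(G_blend.dense(), "blended G") - _invert_pd(
            A22.dense(), "A22"
        )
        H[np.ix_(gi, gi)] = H[np.ix_(gi, gi)].toarray() + delta
    return RelationshipMatrix(H.tocsr(), list(A_inv.ids), "H_inv")


def _design_matrices(phenotypes: pd.DataFrame, trait: str, animal_ids):
    records = phenotypes[phenotypes["trait"] == trait]
    if records.empty:
        raise ValueError(f"no phenotype records for trait {trait!r}")
    pos = {a: i for i, a in enumerate(animal_ids)}
    try:
        anim = np.array([pos[a] for a in records["animal"]], dtype=np.int64)
    except KeyError as err:
        raise KeyError(
            f"phenotyped animal {err.args[0]!r} absent from pedigree"
        ) from None
    levels = pd.Categorical(records["slaughter_date"])
    level_names = list(levels.categories)
    lev = np.asarray(levels.codes, dtype=np.int64)
    age = records["slaughter_age"].to_numpy(dtype=np.float64)
    age_c = age - age.mean()
    y = records["value"].to_numpy(dtype=np.float64)
    n = len(records)
    X = sp.csr_matrix(
        (np.ones(n), (np.arange(n), lev)), shape=(n, len(level_names))
    )
    if np.ptp(age_c) > 0:
        X = sp.hstack([X, sp.csr_matrix(age_c[:, None])], format="csr")
        level_names = level_names + ["slaughter_age"]
    else:
        warnings.warn("slaughter age constant across records: covariate dropped")
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), anim)), shape=(n, len(animal_ids))
    )
    return X, Z, y, level_names


def solve_mme(
    model: ModelSpec,
    phenotypes: pd.DataFrame,
    K_inv: RelationshipMatrix,
    dataset: str = "whole",
    method: str | None = None,
) -> EvaluationResult:
    """Solve the mixed model equations for one trait.

    [X'X  X'Z; Z'X  Z'Z + lambda K^-1] [b; u] = [X'y; Z'y], solved by sparse
    LU.  K^-1 spans the full pedigree, so unphenotyped animals receive
    breeding values through their relatives.
    """
    X, Z, y, level_names = _design_matrices(phenotypes, model.trait, K_inv.ids)
    lam = model.variance_ratio
    K = sp.csr_matrix(K_inv.values)
    lhs = sp.bmat(
        [
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + lam * K],
        ],
        format="csc",
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        lu = splu(lhs)
    except RuntimeError as err:
        raise RuntimeError(f"mixed model equations singular: {err}") from None
    sol = lu.solve(rhs)
    resid = lhs @ sol - rhs
    rel = np.linalg.norm(resid) / max(np.linalg.norm(rhs), 1e-300)
    if rel > 1e-10:
        # one refinement step; direct LU occasionally needs it on stiff systems
        sol -= lu.solve(resid)
        rel = np.linalg.norm(lhs @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
        if rel > 1e-10:
            raise RuntimeError(
                f"mixed model solver did not converge (relative residual {rel:.2e})"
            )
    nb = X.shape[1]
    if method is None:
        method = {"A_inv": "PBLUP", "H_inv": "ssGBLUP"}.get(K_inv.kind, K_inv.kind)
    return EvaluationResult(
        ebv=sol[nb:],
        animal_ids=list(K_inv.ids),
        fixed_solutions=pd.Series(sol[:nb], index=level_names),
        method=method,
        dataset=dataset,
        trait=model.trait,
    )
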