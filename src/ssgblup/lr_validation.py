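"""LR-method validation of genetic evaluations.

The LR method compares breeding values predicted from a partial dataset
(the focal cohort's phenotypes removed) with those from the whole dataset.
Its estimators are:

  accuracy^2 of the partial evaluation:
      cov(u_w, u_p) / ((1 + F_bar - 2 f_bar) * sigma2_u_inf)
  bias:        mean(u_p) - mean(u_w)          (expected 0)
  dispersion:  slope of u_w on u_p            (expected 1)
  ratios:      Pearson correlation between two EBV vectors, with
               1/rho - 1 as the relative accuracy gain.

F_bar and f_bar are the focal cohort's average inbreeding and coancestry;
sigma2_u_inf its equilibrium genetic variance under selection.  The
denominator sign (some sources print 1 + F_bar + 2 f_bar) and whether the
reported accuracy is the ratio or its square root are both configurable;
defaults are the minus sign and the square root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gibbs_vc import EquilibriumVariance
from .pedigree import InbreedingSummary


@dataclass
class FocalCohort:
    """Validation animals, typically the youngest birth cohorts."""

    ids: list
    rule: str = ""

    def __post_init__(self):
        self.ids = list(self.ids)

    @classmethod
    def from_birth_years(cls, pedigree, years) -> "FocalCohort":
        years = set(years)
        if pedigree.birth_year is None:
            raise ValueError("pedigree carries no birth years")
        ids = [
            a
            for i, a in enumerate(pedigree.ids)
            if pedigree.birth_year[i] in years
        ]
        return cls(ids=ids, rule=f"birth years {sorted(years)}")


@dataclass
class LRReport:
    """One row per (trait, method) of all LR estimators, as a DataFrame."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def add_row(self, **kwargs) -> None:
        self.table = pd.concat(
            [self.table, pd.DataFrame([kwargs])], ignore_index=True
        )


def split_partial(
    phenotypes: pd.DataFrame, cohort: FocalCohort
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Whole and partial phenotype sets; partial drops focal records only.

    Pedigree and genotypes are untouched: in the partial evaluation the
    focal animals keep their relationships and markers but lose phenotypes.
    """
    if not cohort.ids:
        return phenotypes, phenotypes.copy()
    focal = set(cohort.ids)
    if not focal & set(phenotypes["animal"]):
        raise ValueError("focal cohort has no phenotyped animals to remove")
    partial = phenotypes[~phenotypes["animal"].isin(focal)].reset_index(drop=True)
    return phenotypes, partial


def _check_pair(u_p: np.ndarray, u_w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u_p = np.asarray(u_p, dtype=float)
    u_w = np.asarray(u_w, dtype=float)
    if u_p.shape != u_w.shape or u_p.ndim != 1:
        raise ValueError("EBV vectors must be 1-D and of equal length")
    return u_p, u_w


def lr_accuracy(
    u_p: np.ndarray,
    u_w: np.ndarray,
    inb: InbreedingSummary,
    eq: EquilibriumVariance,
    sign: str = "minus",
    sqrt_convention: bool = True,
) -> float:
    """LR estimate of the partial evaluation's population accuracy.

    ratio = cov(u_w, u_p) / ((1 + F_bar +/- 2 f_bar) sigma2_u_inf); the
    returned value is sqrt(ratio) under the default convention (the ratio
    estimates a squared accuracy).  A negative covariance yields 0 with a
    warning rather than an error.
    """
    u_p, u_w = _check_pair(u_p, u_w)
    if u_p.std() == 0 or u_w.std() == 0:
        raise ValueError("EBV vector with zero variance")
    if sign == "minus":
        denom_rel = 1.0 + inb.F_bar - 2.0 * inb.f_bar
    elif sign == "plus":
        denom_rel = 1.0 + inb.F_bar + 2.0 * inb.f_bar
    else:
        raise ValueError("sign must be 'minus' or 'plus'")
    denom = denom_rel * eq.sigma2_u_inf
    if denom <= 0:
        raise ValueError("non-positive accuracy denominator")
    ratio = float(np.cov(u_w, u_p, ddof=1)[0, 1] / denom)
    if ratio < 0:
        warnings.warn("negative LR accuracy ratio clamped to 0")
        return 0.0
    return float(np.sqrt(ratio)) if sqrt_convention else ratio


def lr_bias(u_p: np.ndarray, u_w: np.ndarray) -> float:
    """mean(u_p) - mean(u_w), in trait units; expected 0 when unbiased."""
    u_p, u_w = _check_pair(u_p, u_w)
    return float(u_p.mean() - u_w.mean())


def lr_dispersion(u_p: np.ndarray, u_w: np.ndarray) -> float:
    """Regression slope of u_w on u_p; expected 1 without over/under-dispersion."""
    u_p, u_w = _check_pair(u_p, u_w)
    v = np.var(u_p, ddof=1)
    if v == 0:
        raise ValueError("partial EBV vector has zero variance")
    return float(np.cov(u_w, u_p, ddof=1)[0, 1] / v)


def lr_ratio(u_a: np.ndarray, u_b: np.ndarray) -> tuple[float, float]:
    """Correlation between two EBV vectors and the relative accuracy gain.

    The correlation estimates the ratio of the two accuracies; 1/rho - 1 is
    the relative gain moving from the less- to the more-informed evaluation.
    """
    u_a, u_b = _check_pair(u_a, u_b)
    if u_a.std() == 0 or u_b.std() == 0:
        raise ValueError("EBV vector with zero variance")
    rho = float(np.corrcoef(u_a, u_b)[0, 1])
    return rho, 1.0 / rho - 1.0


def compile_report(
    trait: str,
    focal_ids,
    results: dict,
    inb: InbreedingSummary,
    eq: EquilibriumVariance,
    sign: str = "minus",
    sqrt_convention: bool = True,
) -> LRReport:
    """Assemble the full LR report for one trait.

    results maps (method, dataset) -> EvaluationResult for methods PBLUP and
    ssGBLUP, datasets whole and partial.
    """
    report = LRReport()
    focal_ids = list(focal_ids)
    u = {
        key: res.ebv_of(focal_ids) for key, res in results.items()
    }
    rho_mp, gain_mp = lr_ratio(u[("PBLUP", "partial")], u[("ssGBLUP", "partial")])
    rho_mw, gain_mw = lr_ratio(u[("PBLUP", "whole")], u[("ssGBLUP", "whole")])
    for method in ("PBLUP", "ssGBLUP"):
        u_p, u_w = u[(method, "partial")], u[(method, "whole")]
        acc_p = lr_accuracy(u_p, u_w, inb, eq, sign, sqrt_convention)
        # whole-data accuracy: same estimator with the whole EBV in both slots
        acc_w = lr_accuracy(u_w, u_w, inb, eq, sign, sqrt_convention)
        rho_pw, gain_pw = lr_ratio(u_p, u_w)
        bias = lr_bias(u_p, u_w)
        disp = lr_dispersion(u_p, u_w)
        if acc_p > acc_w:
            warnings.warn(
                f"{method}: partial accuracy exceeds whole accuracy "
                "(sampling noise or model misfit)"
            )
        report.add_row(
            trait=trait,
            method=method,
            acc_partial=acc_p,
            acc_whole=acc_w,
            bias=bias,
            dispersion=disp,
            rho_methods_partial=rho_mp,
            gain_methods_partial=gain_mp,
            rho_methods_whole=rho_mw,
            gain_methods_whole=gain_mw,
            rho_partial_whole=rho_pw,
            gain_partial_whole=gain_pw,
            F_bar=inb.F_bar,
            f_bar=inb.f_bar,
            sigma2_u_inf=eq.sigma2_u_inf,
        )
    return report
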