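"""Bayesian variance components for the single-trait animal model.

A single-site Gibbs sampler draws fixed effects, breeding values and the two
variances from their full conditionals under flat priors (scaled inverse
chi-square with nu = -2, S = 0 on the variances), so posterior means are
directly comparable to REML.  Posterior summaries include heritability and
the coefficient of genetic variation; retained breeding-value draws for a
focal cohort yield the selection-adjusted equilibrium genetic variance used
by the LR-method accuracy denominator (the within-cohort genetic variance,
averaged over the posterior, after Sorensen's Gibbs approach).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._kernels import gibbs_chain
from .evaluation import ModelSpec, _design_matrices
from .pedigree import RelationshipMatrix


@dataclass
class GibbsConfig:
    """Chain settings; the default is a desk-scale profile.

    The production profile used for routine evaluations (550,000 cycles,
    50,000 burn-in, thinning 50) is available by passing those values.
    """

    chain_length: int = 50_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    def __post_init__(self):
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be below chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.chain_length - self.burn_in) // self.thin < 100:
            raise ValueError("retain at least 100 samples")


@dataclass
class VarianceComponents:
    """Posterior (or point) variance components and derived ratios.

    h2 = sigma2_a / (sigma2_a + sigma2_e); cv_g = 100 * sigma_a / trait mean.
    """

    sigma2_a: float
    sigma2_e: float
    sigma2_p: float
    h2: float
    cv_g: float | None = None
    posterior_sd: dict = field(default_factory=dict)

    @classmethod
    def from_estimates(
        cls, sigma2_a: float, sigma2_e: float, trait_mean: float | None = None
    ) -> "VarianceComponents":
        if sigma2_a <= 0 or sigma2_e <= 0:
            raise ValueError("variances must be positive")
        cv_g = None
        if trait_mean is not None:
            if trait_mean <= 0:
                raise ValueError("trait mean must be positive")
            cv_g = float(100.0 * np.sqrt(sigma2_a) / trait_mean)
        return cls(
            sigma2_a=sigma2_a,
            sigma2_e=sigma2_e,
            sigma2_p=sigma2_a + sigma2_e,
            h2=sigma2_a / (sigma2_a + sigma2_e),
            cv_g=cv_g,
        )

    @property
    def variance_ratio(self) -> float:
        """lambda = sigma_e2 / sigma_a2, the MME shrinkage ratio."""
        return self.sigma2_e / self.sigma2_a


@dataclass
class GibbsSamples:
    """Retained draws: the two variances and focal breeding values."""

    sigma2_a: np.ndarray
    sigma2_e: np.ndarray
    u_focal: np.ndarray
    focal_ids: list
    u_mean: np.ndarray
    animal_ids: list

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": np.arange(len(self.sigma2_a)),
                "sigma2_a": self.sigma2_a,
                "sigma2_e": self.sigma2_e,
            }
        )


@dataclass
class EquilibriumVariance:
    """Posterior mean within-cohort genetic variance and its Monte Carlo SE."""

    sigma2_u_inf: float
    mc_se: float


def split_psrf(x: np.ndarray) -> float:
    """Potential scale reduction factor from the two halves of one chain."""
    half = len(x) // 2
    chains = np.stack([x[:half], x[half : 2 * half]])
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W)) if W > 0 else np.inf


def run_gibbs(
    model: ModelSpec,
    phenotypes: pd.DataFrame,
    K_inv: RelationshipMatrix,
    config: GibbsConfig,
    focal_ids=None,
) -> tuple[VarianceComponents, GibbsSamples]:
    """Run the Gibbs chain and summarise the posterior.

    model.variance_ratio only seeds the initial variance split; the chain
    estimates both variances.  focal_ids selects the animals whose breeding
    value draws are retained (default: all pedigree animals would be too
    large, so none beyond the posterior mean are kept unless requested).
    """
    X, Z, y, level_names = _design_matrices(phenotypes, model.trait, K_inv.ids)
    # the sampler wants the factor as level indices and the covariate raw
    records = phenotypes[phenotypes["trait"] == model.trait]
    levels = pd.Categorical(records["slaughter_date"])
    lev = np.asarray(levels.codes, dtype=np.int64)
    age = records["slaughter_age"].to_numpy(dtype=np.float64)
    age_c = age - age.mean()
    pos = {a: i for i, a in enumerate(K_inv.ids)}
    anim = np.array([pos[a] for a in records["animal"]], dtype=np.int64)
    n_anim = len(K_inv.ids)

    rec_by_animal = sp.csr_matrix(
        (np.arange(len(anim)) + 1, (anim, np.arange(len(anim)))),
        shape=(n_anim, len(anim)),
    )
    rec_indptr = rec_by_animal.indptr.astype(np.int64)
    rec_indices = (rec_by_animal.data - 1).astype(np.int64)

    K = sp.csr_matrix(K_inv.values)
    if focal_ids is None:
        focal_ids = []
    focal_ids = list(focal_ids)
    focal_idx = np.array([pos[a] for a in focal_ids], dtype=np.int64)

    vy = float(np.var(y))
    lam0 = model.variance_ratio
    s_a0 = vy / (1.0 + lam0)
    s_e0 = vy * lam0 / (1.0 + lam0)

    sa, se, u_focal, u_mean = gibbs_chain(
        y.astype(np.float64),
        lev,
        int(lev.max()) + 1,
        age_c,
        anim,
        n_anim,
        K.indptr.astype(np.int64),
        K.indices.astype(np.int64),
        K.data.astype(np.float64),
        rec_indptr,
        rec_indices,
        focal_idx,
        config.chain_length,
        config.burn_in,
        config.thin,
        config.seed % (2**31),
        s_a0,
        s_e0,
    )
    if len(sa) == 0:
        raise RuntimeError("Gibbs chain diverged (non-finite variance draw)")
    for name, draws in (("sigma2_a", sa), ("sigma2_e", se)):
        r = split_psrf(draws)
        if r > 1.05:
            warnings.warn(
                f"split-chain PSRF for {name} is {r:.3f} (> 1.05): "
                "chain may not have converged"
            )
    trait_mean = float(records["value"].mean())
    components = summarize_components(sa, se, trait_mean)
    samples = GibbsSamples(
        sigma2_a=sa,
        sigma2_e=se,
        u_focal=u_focal,
        focal_ids=focal_ids,
        u_mean=u_mean,
        animal_ids=list(K_inv.ids),
    )
    return components, samples


def summarize_components(
    samples_a: np.ndarray, samples_e: np.ndarray, trait_mean: float
) -> VarianceComponents:
    """Posterior means, SDs and derived h2 / CV_g from retained draws."""
    samples_a = np.asarray(samples_a, dtype=float)
    samples_e = np.asarray(samples_e, dtype=float)
    if len(samples_a) < 100:
        raise ValueError("need at least 100 retained samples")
    if trait_mean <= 0:
        raise ValueError("trait mean must be positive")
    vc = VarianceComponents.from_estimates(
        float(samples_a.mean()), float(samples_e.mean()), trait_mean
    )
    h2_draws = samples_a / (samples_a + samples_e)
    vc.posterior_sd = {
        "sigma2_a": float(samples_a.std(ddof=1)),
        "sigma2_e": float(samples_e.std(ddof=1)),
        "sigma2_p": float((samples_a + samples_e).std(ddof=1)),
        "h2": float(h2_draws.std(ddof=1)),
    }
    # h2 posterior mean from the ratio draws, not the ratio of means
    vc.h2 = float(h2_draws.mean())
    return vc


def equilibrium_variance(u_samples: np.ndarray) -> EquilibriumVariance:
    """Equilibrium genetic variance of the focal cohort under selection.

    For each retained Gibbs draw, the empirical variance of the sampled
    breeding values across focal animals is computed; the posterior mean of
    that quantity is the cohort's genetic variance, automatically reduced by
    selection and drift relative to the base-population sigma_a2.
    """
    u_samples = np.asarray(u_samples, dtype=float)
    if u_samples.ndim != 2 or u_samples.shape[0] < 100:
        raise ValueError("need >= 100 retained focal breeding-value samples")
    if u_samples.shape[1] < 2:
        raise ValueError("focal group must contain at least two animals")
    per_draw = u_samples.var(axis=1, ddof=1)
    mean = float(per_draw.mean())
    if mean < 1e-12:
        warnings.warn("degenerate focal samples: equilibrium variance near zero")
    return EquilibriumVariance(
        sigma2_u_inf=mean,
        mc_se=float(per_draw.std(ddof=1) / np.sqrt(len(per_draw))),
    )
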