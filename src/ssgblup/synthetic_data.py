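"""Forward simulation of a livestock evaluation dataset.

Generates a discrete-generation pedigree, SNP genotypes by gene dropping
(unlinked loci, Mendelian transmission), strictly additive true breeding
values from QTL inside the SNP panel, and phenotypes with a slaughter-date
contemporary-group effect and a slaughter-age covariate — the data structure
a single-trait carcass evaluation assumes.  Optional truncation selection of
parents on phenotype lets the pedigree accumulate the selection and drift
that the LR accuracy denominator corrects for.

The default configuration is desk-scale: 500 founders plus four offspring
generations of 500 (2,000 phenotyped animals), 5,000 SNPs with 200 QTL, 40
slaughter-date levels, and the last generation as the focal cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix
from .pedigree import Pedigree


@dataclass
class SimulationConfig:
    n_founders: int = 500
    n_generations: int = 5  # founders + 4 offspring generations
    offspring_per_mating: int = 2
    n_snps: int = 5_000
    n_qtl: int = 200
    founder_maf_range: tuple = (0.1, 0.5)
    trait: str = "primal_cut"
    trait_mean: float = 30.0  # kg, a mid-range primal cut weight
    h2_true: float = 0.4
    sigma2_p_true: float = 10.0
    n_slaughter_dates: int = 40
    age_range: tuple = (690, 780)  # days from birth to slaughter
    age_slope: float = 0.05  # kg per day
    date_effect_sd: float = 1.5  # kg, contemporary-group spread
    selection: str = "none"  # or "truncation" on phenotype
    selection_fraction: float = 0.5
    genotyped_fraction: float = 0.85
    missing_rate: float = 0.01
    last_birth_year: int = 2017
    focal_birth_years: tuple = (2017,)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.h2_true < 1):
            raise ValueError("h2_true must be in (0, 1)")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie in (0, 0.5]")
        if self.selection not in ("none", "truncation"):
            raise ValueError("selection must be 'none' or 'truncation'")
        if self.n_generations < 1 or self.n_founders < 2:
            raise ValueError("need at least one generation of >= 2 founders")


@dataclass
class TruthSet:
    """Simulation ground truth kept alongside the observable data."""

    true_u: np.ndarray
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    sigma2_a: float
    sigma2_e: float
    date_effects: np.ndarray
    age_slope: float


@dataclass
class Dataset:
    """One simulated study: pedigree, genotyped subset, phenotypes, truth."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: TruthSet
    genotyped_ids: list
    focal_ids: list
    config: SimulationConfig


def _birth_years(config: SimulationConfig, generation: np.ndarray) -> np.ndarray:
    offset = config.n_generations - 1 - generation
    return config.last_birth_year - offset


def _mate_pairs(rng, parent_rows, scores, config):
    """Pair parents for the next generation, optionally after truncation."""
    parent_rows = np.asarray(parent_rows)
    if config.selection == "truncation" and scores is not None:
        k = max(2, int(np.ceil(len(parent_rows) * config.selection_fraction)))
        parent_rows = parent_rows[np.argsort(scores)[::-1][:k]]
    perm = rng.permutation(parent_rows)
    n_pairs = len(perm) // 2
    if n_pairs == 0:
        raise RuntimeError("no matings possible: parent pool too small")
    return perm[: 2 * n_pairs].reshape(n_pairs, 2)


def _transmit(rng, parent_geno: np.ndarray) -> np.ndarray:
    """One gamete per row: allele count transmitted by each parent genotype."""
    return (rng.random(parent_geno.shape) < parent_geno / 2.0).astype(np.int8)


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Run the full forward simulation.

    Generations are simulated jointly (pedigree, genotypes, breeding values,
    phenotypes) so that phenotypic truncation selection, when enabled, acts
    on the same trait the analysis later evaluates.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps

    founder_p = rng.uniform(*config.founder_maf_range, size=m)
    qtl = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    alpha = rng.standard_normal(config.n_qtl)

    # founders
    geno_gens = [rng.binomial(2, founder_p, size=(config.n_founders, m)).astype(np.int8)]
    u_founder_raw = geno_gens[0][:, qtl].astype(float) @ alpha
    v = np.var(u_founder_raw, ddof=1)
    if v <= 0:
        raise RuntimeError("all QTL monomorphic in founders: cannot scale effects")
    sigma2_a = config.h2_true * config.sigma2_p_true
    sigma2_e = (1.0 - config.h2_true) * config.sigma2_p_true
    scale = np.sqrt(sigma2_a / v)
    alpha *= scale

    sire_list = [np.zeros(config.n_founders, dtype=np.int64)]
    dam_list = [np.zeros(config.n_founders, dtype=np.int64)]
    gen_of = [np.zeros(config.n_founders, dtype=np.int64)]
    gen_start = [0]
    n_total = config.n_founders

    date_effects = rng.normal(0.0, config.date_effect_sd, config.n_slaughter_dates)

    def _u_of(geno):
        return geno[:, qtl].astype(float) @ alpha

    u_center = _u_of(geno_gens[0]).mean()

    def _phenotype(geno, rng):
        n = geno.shape[0]
        u = _u_of(geno) - u_center
        dates = rng.integers(0, config.n_slaughter_dates, n)
        ages = rng.uniform(*config.age_range, n)
        e = rng.normal(0.0, np.sqrt(sigma2_e), n)
        mid_age = 0.5 * (config.age_range[0] + config.age_range[1])
        y = (
            config.trait_mean
            + date_effects[dates]
            + config.age_slope * (ages - mid_age)
            + u
            + e
        )
        return u, y, dates, ages

    pheno_rows = []  # (row index, y, date, age)
    u_all = [(_u_of(geno_gens[0]) - u_center)]
    founder_scores = None
    if config.selection == "truncation":
        # founders are unphenotyped in the output but selection still needs a
        # phenotypic score; it is drawn from the same trait model
        _, y_f, _, _ = _phenotype(geno_gens[0], rng)
        founder_scores = y_f

    prev_rows = np.arange(config.n_founders)
    prev_scores = founder_scores
    for g in range(1, config.n_generations):
        pairs = _mate_pairs(rng, prev_rows, prev_scores, config)
        n_children = pairs.shape[0] * config.offspring_per_mating
        sire_rows = np.repeat(pairs[:, 0], config.offspring_per_mating)
        dam_rows = np.repeat(pairs[:, 1], config.offspring_per_mating)
        all_geno = np.vstack(geno_gens)
        child_geno = _transmit(rng, all_geno[sire_rows]) + _transmit(
            rng, all_geno[dam_rows]
        )
        geno_gens.append(child_geno)
        sire_list.append(sire_rows + 1)  # 1-based codes
        dam_list.append(dam_rows + 1)
        gen_of.append(np.full(n_children, g, dtype=np.int64))
        gen_start.append(n_total)
        u, y, dates, ages = _phenotype(child_geno, rng)
        u_all.append(u)
        rows = np.arange(n_total, n_total + n_children)
        for r, yy, dd, aa in zip(rows, y, dates, ages):
            pheno_rows.append((r, yy, dd, aa))
        n_total += n_children
        prev_rows = rows
        prev_scores = y if config.selection == "truncation" else None

    sire = np.concatenate(sire_list)
    dam = np.concatenate(dam_list)
    generation = np.concatenate(gen_of)
    ids = [f"A{i + 1}" for i in range(n_total)]
    pedigree = Pedigree(
        ids=ids, sire=sire, dam=dam, birth_year=_birth_years(config, generation)
    )
    geno_full = np.vstack(geno_gens)
    true_u = np.concatenate(u_all)

    phenotypes = pd.DataFrame(
        {
            "animal": [ids[r] for r, *_ in pheno_rows],
            "trait": config.trait,
            "value": [row[1] for row in pheno_rows],
            "slaughter_date": [f"D{row[2] + 1}" for row in pheno_rows],
            "slaughter_age": [row[3] for row in pheno_rows],
        }
    )

    # genotyped subset: every focal animal plus a fraction of the rest
    focal_years = set(config.focal_birth_years)
    focal_mask = np.isin(pedigree.birth_year, list(focal_years))
    focal_ids = [ids[i] for i in np.where(focal_mask)[0]]
    others = np.where(~focal_mask)[0]
    n_geno_others = int(round(config.genotyped_fraction * len(others)))
    geno_rows = np.sort(
        np.concatenate(
            [
                np.where(focal_mask)[0],
                rng.choice(others, size=n_geno_others, replace=False),
            ]
        )
    )
    codes = geno_full[geno_rows]
    mask = rng.random(codes.shape) < config.missing_rate
    genotypes = GenotypeMatrix(
        codes=codes,
        missing_mask=mask,
        animal_ids=[ids[i] for i in geno_rows],
        snp_ids=[f"S{j + 1}" for j in range(m)],
    )
    truth = TruthSet(
        true_u=true_u,
        qtl_indices=qtl,
        qtl_effects=alpha,
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        date_effects=date_effects,
        age_slope=config.age_slope,
    )
    return Dataset(
        pedigree=pedigree,
        genotypes=genotypes,
        phenotypes=phenotypes,
        truth=truth,
        genotyped_ids=list(genotypes.animal_ids),
        focal_ids=focal_ids,
        config=config,
    )


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Pedigree only (the full forward simulation is run, rest discarded)."""
    return simulate_dataset(config).pedigree


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig, rng=None
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Gene-drop genotypes down an existing ordered pedigree.

    Founder alleles are drawn at frequencies from founder_maf_range; each
    non-founder inherits one allele per parent per locus.  Returns the full
    (un-masked, all-animal) genotype matrix plus QTL indices and unscaled
    effects for downstream phenotype simulation.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = len(pedigree), config.n_snps
    founder_p = rng.uniform(*config.founder_maf_range, size=m)
    geno = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == 0 and d == 0:
            geno[i] = rng.binomial(2, founder_p)
            continue
        g_s = geno[s - 1] if s > 0 else rng.binomial(1, founder_p) * 2
        g_d = geno[d - 1] if d > 0 else rng.binomial(1, founder_p) * 2
        geno[i] = _transmit(rng, g_s[None, :])[0] + _transmit(rng, g_d[None, :])[0]
    qtl = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    alpha = rng.standard_normal(config.n_qtl)
    gm = GenotypeMatrix(
        codes=geno,
        missing_mask=np.zeros_like(geno, dtype=bool),
        animal_ids=list(pedigree.ids),
        snp_ids=[f"S{j + 1}" for j in range(m)],
    )
    return gm, qtl, alpha


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    qtl: np.ndarray,
    alpha: np.ndarray,
    rng=None,
) -> tuple[pd.DataFrame, TruthSet]:
    """Phenotypes for the non-founder animals from complete genotypes.

    QTL effects are rescaled so the founder breeding-value variance equals
    h2_true * sigma2_p_true; records follow y = mean + date effect +
    slope * (age - midpoint) + u + e.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if genotypes.missing_mask.any():
        raise ValueError("phenotype simulation needs complete genotypes")
    founders = np.where((pedigree.sire == 0) & (pedigree.dam == 0))[0]
    u_raw = genotypes.codes[:, qtl].astype(float) @ alpha
    v = np.var(u_raw[founders], ddof=1)
    if v <= 0:
        raise RuntimeError("all QTL monomorphic in founders: cannot scale effects")
    sigma2_a = config.h2_true * config.sigma2_p_true
    sigma2_e = (1.0 - config.h2_true) * config.sigma2_p_true
    alpha_s = alpha * np.sqrt(sigma2_a / v)
    u = genotypes.codes[:, qtl].astype(float) @ alpha_s
    u -= u[founders].mean()
    date_effects = rng.normal(0.0, config.date_effect_sd, config.n_slaughter_dates)
    recorded = np.where((pedigree.sire > 0) | (pedigree.dam > 0))[0]
    n_rec = len(recorded)
    dates = rng.integers(0, config.n_slaughter_dates, n_rec)
    ages = rng.uniform(*config.age_range, n_rec)
    mid_age = 0.5 * (config.age_range[0] + config.age_range[1])
    e = rng.normal(0.0, np.sqrt(sigma2_e), n_rec)
    y = (
        config.trait_mean
        + date_effects[dates]
        + config.age_slope * (ages - mid_age)
        + u[recorded]
        + e
    )
    phenotypes = pd.DataFrame(
        {
            "animal": [pedigree.ids[i] for i in recorded],
            "trait": config.trait,
            "value": y,
            "slaughter_date": [f"D{d + 1}" for d in dates],
            "slaughter_age": ages,
        }
    )
    truth = TruthSet(
        true_u=u,
        qtl_indices=qtl,
        qtl_effects=alpha_s,
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        date_effects=date_effects,
        age_slope=config.age_slope,
    )
    return phenotypes, truth
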