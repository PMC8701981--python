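"""End-to-end study orchestration.

run_lr_study executes the full comparison on in-memory data: genotype QC,
relationship matrices (A^-1, A22, G, blend, H^-1), Gibbs variance
components on the whole data, mixed-model solutions for PBLUP and ssGBLUP
on whole and partial datasets, and the LR report.  The CLI wraps this with
file I/O and per-stage caching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ModelSpec, build_H_inverse, solve_mme
from .genomic import blend_G, build_G, impute_missing, qc_filter, tune_G_to_A22
from .gibbs_vc import (
    EquilibriumVariance,
    GibbsConfig,
    VarianceComponents,
    equilibrium_variance,
    run_gibbs,
)
from .io_formats import RunConfig
from .lr_validation import FocalCohort, LRReport, compile_report, split_partial
from .pedigree import build_A_inverse, extract_A22, inbreeding_summary
from .synthetic_data import Dataset


@dataclass
class StudyResult:
    """Everything one trait's LR comparison produced."""

    report: LRReport
    components: VarianceComponents
    equilibrium: EquilibriumVariance
    evaluations: dict  # (method, dataset) -> EvaluationResult
    qc_report: object
    inbreeding: object
    focal_ids: list


def run_lr_study(
    data: Dataset,
    run_config: RunConfig | None = None,
    gibbs_config: GibbsConfig | None = None,
    focal_ids=None,
) -> StudyResult:
    """Run the whole-vs-partial LR comparison on a dataset.

    Variance components come from a Gibbs chain on the whole data under the
    pedigree relationship matrix; the resulting posterior-mean variance
    ratio is reused for all four mixed-model solves, and the retained focal
    breeding-value draws give the equilibrium genetic variance for the LR
    accuracy denominator.
    """
    cfg = run_config or RunConfig()
    gcfg = gibbs_config or GibbsConfig(seed=cfg.seed)
    pedigree = data.pedigree
    trait = data.config.trait

    if focal_ids is None:
        focal_ids = list(data.focal_ids)
    if len(focal_ids) < 2:
        raise ValueError("focal cohort must contain at least two animals")

    geno_qc, qc_report = qc_filter(
        data.genotypes, cfg.maf_min, cfg.het_dev_max, cfg.call_rate_min
    )
    geno_qc = impute_missing(geno_qc)

    A_inv = build_A_inverse(pedigree)
    A22 = extract_A22(pedigree, geno_qc.animal_ids)
    G = build_G(geno_qc)
    if cfg.tune_G:
        G = tune_G_to_A22(G, A22)
    Gb = blend_G(G, A22, cfg.w_G, cfg.w_A22)
    H_inv = build_H_inverse(A_inv, A22, Gb, geno_qc.animal_ids)

    probe = ModelSpec(trait, 1.0)  # ratio only seeds the chain
    components, samples = run_gibbs(
        probe, data.phenotypes, A_inv, gcfg, focal_ids=focal_ids
    )
    eq = equilibrium_variance(samples.u_focal)
    inb = inbreeding_summary(pedigree, focal_ids)

    whole, partial = split_partial(data.phenotypes, FocalCohort(focal_ids))
    model = ModelSpec(trait, components.variance_ratio)
    evaluations = {}
    for method, K in (("PBLUP", A_inv), ("ssGBLUP", H_inv)):
        for dataset_tag, pheno in (("whole", whole), ("partial", partial)):
            evaluations[(method, dataset_tag)] = solve_mme(
                model, pheno, K, dataset=dataset_tag, method=method
            )
    report = compile_report(
        trait,
        focal_ids,
        evaluations,
        inb,
        eq,
        sign=cfg.lr_denominator_sign,
        sqrt_convention=cfg.lr_sqrt_convention,
    )
    return StudyResult(
        report=report,
        components=components,
        equilibrium=eq,
        evaluations=evaluations,
        qc_report=qc_report,
        inbreeding=inb,
        focal_ids=focal_ids,
    )


def truth_accuracy(result: StudyResult, data: Dataset, method: str, dataset: str) -> float:
    """Correlation between EBV and simulated true breeding values (focal)."""
    pos = {a: i for i, a in enumerate(data.pedigree.ids)}
    idx = np.array([pos[a] for a in result.focal_ids])
    u_true = data.truth.true_u[idx]
    u_hat = result.evaluations[(method, dataset)].ebv_of(result.focal_ids)
    return float(np.corrcoef(u_hat, u_true)[0, 1])
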