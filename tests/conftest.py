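"""Shared fixtures.

The expensive simulation-based fixtures are session-scoped so that module
tests and the acceptance suite share one set of Gibbs chains and replicate
studies.
"""

import warnings

import numpy as np
import pytest

from ssgblup import (
    GibbsConfig,
    ModelSpec,
    Pedigree,
    RunConfig,
    SimulationConfig,
    run_gibbs,
    run_lr_study,
    simulate_dataset,
    truth_accuracy,
)
from ssgblup.pedigree import build_A_inverse

REPLICATE_GIBBS = dict(chain_length=6_000, burn_in=1_000, thin=5)


def random_pedigree(n, n_founders, seed):
    """Random ordered pedigree: each non-founder gets two earlier parents."""
    rng = np.random.default_rng(seed)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for i in range(n_founders, n):
        s, d = rng.integers(0, i, size=2)
        sire[i] = s + 1
        dam[i] = d + 1 if d != s else 0
    return Pedigree(ids=[f"P{i}" for i in range(n)], sire=sire, dam=dam)


@pytest.fixture(scope="session")
def trio_pedigree():
    return Pedigree(
        ids=["sire", "dam", "kid"],
        sire=np.array([0, 0, 1]),
        dam=np.array([0, 0, 2]),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated study reused by cheap structural tests."""
    cfg = SimulationConfig(
        n_founders=100,
        n_generations=4,
        offspring_per_mating=2,
        n_snps=400,
        n_qtl=60,
        h2_true=0.4,
        seed=42,
    )
    return simulate_dataset(cfg)


def _replicate_config(rep):
    return SimulationConfig(
        n_founders=200,
        n_generations=5,
        offspring_per_mating=2,
        n_snps=1_000,
        n_qtl=100,
        h2_true=0.4,
        seed=1_000 + rep,
    )


@pytest.fixture(scope="session")
def replicate_studies():
    """Ten replicate LR studies with simulation truth, for calibration checks."""
    out = []
    for rep in range(10):
        data = simulate_dataset(_replicate_config(rep))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_lr_study(
                data,
                RunConfig(seed=1_000 + rep),
                GibbsConfig(seed=2_000 + rep, **REPLICATE_GIBBS),
            )
        truth = {
            (m, d): truth_accuracy(res, data, m, d)
            for m in ("PBLUP", "ssGBLUP")
            for d in ("whole", "partial")
        }
        out.append((res, truth))
    return out


@pytest.fixture(scope="session")
def gibbs_recovery():
    """Desk-scale Gibbs chains at n=2,000 phenotyped for true h2 0.2 and 0.5."""
    results = {}
    for h2, seed in ((0.5, 7), (0.2, 8)):
        data = simulate_dataset(SimulationConfig(seed=seed, h2_true=h2))
        a_inv = build_A_inverse(data.pedigree)
        vc, samples = run_gibbs(
            ModelSpec(data.config.trait, 1.0),
            data.phenotypes,
            a_inv,
            GibbsConfig(chain_length=50_000, burn_in=5_000, thin=10, seed=10 + seed),
            focal_ids=data.focal_ids[:10],
        )
        results[h2] = (data, vc, samples)
    return results
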