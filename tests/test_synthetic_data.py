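"""Forward simulator: pedigree structure, gene dropping, phenotype model."""

import numpy as np
import pytest

from ssgblup import (
    SimulationConfig,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)
from ssgblup.pedigree import Pedigree, build_A


def _cfg(**kwargs):
    base = dict(
        n_founders=100,
        n_generations=3,
        offspring_per_mating=2,
        n_snps=300,
        n_qtl=50,
        h2_true=0.4,
        seed=0,
    )
    base.update(kwargs)
    return SimulationConfig(**base)


class TestPedigreeSimulation:
    def test_single_generation_gives_founders_only(self):
        ped = simulate_pedigree(_cfg(n_generations=1))
        assert len(ped) == 100
        assert (ped.sire == 0).all() and (ped.dam == 0).all()

    def test_animal_count_matches_closed_form(self):
        # 100 founders -> 50 matings x 2 offspring per generation
        ped = simulate_pedigree(_cfg())
        assert len(ped) == 100 + 2 * 50 * 2

    def test_mean_inbreeding_nondecreasing_across_generations(self):
        deltas = []
        for seed in range(10):
            ped = simulate_pedigree(
                _cfg(n_founders=40, n_generations=5, seed=seed, n_snps=50, n_qtl=10)
            )
            F = ped.inbreeding()
            years = ped.birth_year
            means = [F[years == y].mean() for y in np.unique(years)]
            deltas.append(np.diff(means))
        assert np.mean(np.concatenate(deltas)) >= 0

    def test_birth_years_end_at_last_focal_year(self):
        ped = simulate_pedigree(_cfg())
        assert ped.birth_year.max() == 2017
        assert len(np.unique(ped.birth_year)) == 3


class TestGenotypeSimulation:
    def test_mendelian_certainties_hold(self):
        data = simulate_dataset(_cfg(n_founders=60, missing_rate=0.0,
                                     genotyped_fraction=1.0))
        ped, g = data.pedigree, data.genotypes
        pos = {a: i for i, a in enumerate(g.animal_ids)}
        checked_homo = checked_cross = 0
        for i in range(len(ped)):
            s, d = ped.sire[i], ped.dam[i]
            if s == 0 or d == 0:
                continue
            row = g.codes[pos[ped.ids[i]]]
            rs = g.codes[pos[ped.ids[s - 1]]]
            rd = g.codes[pos[ped.ids[d - 1]]]
            both_zero = (rs == 0) & (rd == 0)
            assert (row[both_zero] == 0).all()
            cross = ((rs == 2) & (rd == 0)) | ((rs == 0) & (rd == 2))
            assert (row[cross] == 1).all()
            checked_homo += both_zero.sum()
            checked_cross += cross.sum()
        assert checked_homo > 0 and checked_cross > 0

    def test_founder_frequencies_recovered_within_binomial_error(self):
        cfg = _cfg(n_founders=500, n_generations=1, genotyped_fraction=1.0,
                   missing_rate=0.0, n_snps=400)
        rng = np.random.default_rng(cfg.seed)
        drawn_p = rng.uniform(*cfg.founder_maf_range, size=cfg.n_snps)
        data = simulate_dataset(cfg)
        realized = data.genotypes.codes.mean(axis=0) / 2.0
        se = np.sqrt(drawn_p * (1 - drawn_p) / (2 * 500))
        assert (np.abs(realized - drawn_p) < 5 * se).mean() > 0.99


class TestPhenotypeSimulation:
    def test_founder_breeding_value_variance_is_calibrated(self):
        cfg = _cfg(n_founders=500, n_generations=2)
        data = simulate_dataset(cfg)
        founders = np.where(
            (data.pedigree.sire == 0) & (data.pedigree.dam == 0)
        )[0]
        target = cfg.h2_true * cfg.sigma2_p_true
        assert np.var(data.truth.true_u[founders], ddof=1) == pytest.approx(
            target, rel=1e-9
        )

    def test_residual_variance_matches_configuration(self):
        cfg = _cfg(n_founders=400, n_generations=3)
        data = simulate_dataset(cfg)
        # reconstruct e = y - mean - date - age slope - u from the truth set
        ped = data.pedigree
        pos = {a: i for i, a in enumerate(ped.ids)}
        ph = data.phenotypes
        idx = np.array([pos[a] for a in ph["animal"]])
        date_idx = ph["slaughter_date"].str[1:].astype(int) - 1
        mid_age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
        e = (
            ph["value"].to_numpy()
            - cfg.trait_mean
            - data.truth.date_effects[date_idx]
            - cfg.age_slope * (ph["slaughter_age"].to_numpy() - mid_age)
            - data.truth.true_u[idx]
        )
        assert np.var(e, ddof=1) == pytest.approx(data.truth.sigma2_e, rel=0.15)

    def test_midparent_offspring_regression_near_heritability(self):
        cfg = SimulationConfig(
            n_founders=500, n_generations=5, offspring_per_mating=2,
            n_snps=1000, n_qtl=150, h2_true=0.5, seed=5,
        )
        data = simulate_dataset(cfg)
        ped, truth = data.pedigree, data.truth
        pos = {a: i for i, a in enumerate(ped.ids)}
        ph = data.phenotypes
        date_idx = ph["slaughter_date"].str[1:].astype(int) - 1
        mid_age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
        adj = (
            ph["value"].to_numpy()
            - truth.date_effects[date_idx]
            - cfg.age_slope * (ph["slaughter_age"].to_numpy() - mid_age)
        )
        adj_of = dict(zip(ph["animal"], adj))
        off, mid = [], []
        for i, a in enumerate(ped.ids):
            s, d = ped.sire[i], ped.dam[i]
            if s == 0 or d == 0 or a not in adj_of:
                continue
            ys, yd = adj_of.get(ped.ids[s - 1]), adj_of.get(ped.ids[d - 1])
            if ys is None or yd is None:
                continue
            off.append(adj_of[a])
            mid.append(0.5 * (ys + yd))
        slope = np.polyfit(mid, off, 1)[0]
        assert slope == pytest.approx(0.5, abs=0.1)


class TestDatasetStructure:
    def test_same_seed_is_byte_identical(self):
        d1, d2 = simulate_dataset(_cfg(seed=3)), simulate_dataset(_cfg(seed=3))
        assert np.array_equal(d1.genotypes.codes, d2.genotypes.codes)
        assert np.array_equal(d1.genotypes.missing_mask, d2.genotypes.missing_mask)
        assert d1.phenotypes.equals(d2.phenotypes)
        assert np.array_equal(d1.truth.true_u, d2.truth.true_u)

    def test_all_four_status_classes_present(self):
        data = simulate_dataset(_cfg(n_founders=200, n_generations=4,
                                     genotyped_fraction=0.5))
        genotyped = set(data.genotypes.animal_ids)
        phenotyped = set(data.phenotypes["animal"])
        everyone = set(data.pedigree.ids)
        assert genotyped - phenotyped
        assert phenotyped - genotyped
        assert genotyped & phenotyped
        assert everyone - genotyped - phenotyped

    def test_focal_animals_all_genotyped_and_phenotyped(self):
        data = simulate_dataset(_cfg())
        focal = set(data.focal_ids)
        assert focal <= set(data.genotypes.animal_ids)
        assert focal <= set(data.phenotypes["animal"])

    def test_sequential_ops_compose(self):
        cfg = _cfg(n_founders=80)
        ped = simulate_pedigree(cfg)
        gm, qtl, alpha = simulate_genotypes(ped, cfg)
        pheno, truth = simulate_phenotypes(ped, gm, cfg, qtl, alpha)
        founders = np.where((ped.sire == 0) & (ped.dam == 0))[0]
        assert np.var(truth.true_u[founders], ddof=1) == pytest.approx(
            cfg.h2_true * cfg.sigma2_p_true, rel=1e-9
        )
        assert set(pheno["animal"]).isdisjoint(
            {ped.ids[i] for i in founders}
        )
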