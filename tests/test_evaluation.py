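"""Mixed model equations and the single-step H inverse."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ssgblup.evaluation import ModelSpec, build_H_inverse, solve_mme
from ssgblup.genomic import blend_G, build_G, GenotypeMatrix
from ssgblup.pedigree import (
    RelationshipMatrix,
    build_A,
    build_A_inverse,
    extract_A22,
)

from conftest import random_pedigree


def _phenotypes(animals, values, dates=None, ages=None, trait="t"):
    n = len(animals)
    return pd.DataFrame(
        {
            "animal": animals,
            "trait": trait,
            "value": values,
            "slaughter_date": dates if dates is not None else ["d1"] * n,
            "slaughter_age": ages if ages is not None else np.linspace(700, 740, n),
        }
    )


class TestBuildHInverse:
    def _instance(self, seed=0, n=80, n_geno=30):
        ped = random_pedigree(n, 15, seed)
        rng = np.random.default_rng(seed)
        geno_ids = [ped.ids[i] for i in sorted(rng.choice(n, n_geno, replace=False))]
        codes = rng.binomial(2, rng.uniform(0.1, 0.5, 300), size=(n_geno, 300))
        gm = GenotypeMatrix(
            codes=codes.astype(np.int8),
            missing_mask=np.zeros_like(codes, dtype=bool),
            animal_ids=geno_ids,
            snp_ids=[f"s{j}" for j in range(300)],
        )
        A_inv = build_A_inverse(ped)
        A22 = extract_A22(ped, geno_ids)
        Gb = blend_G(build_G(gm), A22)
        return ped, geno_ids, A_inv, A22, Gb

    def test_equals_A_inverse_when_blend_is_A22(self):
        ped, geno_ids, A_inv, A22, _ = self._instance()
        fake_blend = RelationshipMatrix(A22.dense().copy(), list(A22.ids), "G_blend")
        H_inv = build_H_inverse(A_inv, A22, fake_blend, geno_ids)
        assert np.abs(H_inv.dense() - A_inv.dense()).max() < 1e-8

    def test_no_genotyped_animals_leaves_A_inverse(self):
        ped = random_pedigree(20, 5, 1)
        A_inv = build_A_inverse(ped)
        empty = RelationshipMatrix(np.zeros((0, 0)), [], "A22")
        blend = RelationshipMatrix(np.zeros((0, 0)), [], "G_blend")
        H_inv = build_H_inverse(A_inv, empty, blend, [])
        assert np.abs(H_inv.dense() - A_inv.dense()).max() == 0

    def test_matches_dense_joint_distribution_oracle(self):
        # H from the joint pedigree-genomic covariance, inverted numerically
        ped, geno_ids, A_inv, A22, Gb = self._instance(seed=2)
        n = len(ped)
        gi = np.array([ped.ids.index(a) for a in geno_ids])
        ui = np.array([i for i in range(n) if ped.ids[i] not in set(geno_ids)])
        A = build_A(ped).dense()
        A11, A12 = A[np.ix_(ui, ui)], A[np.ix_(ui, gi)]
        A22d = A[np.ix_(gi, gi)]
        Gd = Gb.dense()
        A22inv = np.linalg.inv(A22d)
        H = np.zeros((n, n))
        H[np.ix_(ui, ui)] = A11 + A12 @ A22inv @ (Gd - A22d) @ A22inv @ A12.T
        H[np.ix_(ui, gi)] = A12 @ A22inv @ Gd
        H[np.ix_(gi, ui)] = H[np.ix_(ui, gi)].T
        H[np.ix_(gi, gi)] = Gd
        H_inv = build_H_inverse(A_inv, A22, Gb, geno_ids)
        assert np.abs(H_inv.dense() - np.linalg.inv(H)).max() < 1e-6

    def test_singular_blend_named_in_error(self):
        ped, geno_ids, A_inv, A22, Gb = self._instance()
        bad = RelationshipMatrix(
            np.zeros_like(A22.dense()), list(A22.ids), "G_blend"
        )
        with pytest.raises(np.linalg.LinAlgError, match="blended G"):
            build_H_inverse(A_inv, A22, bad, geno_ids)


class TestSolveMME:
    def test_toy_system_matches_dense_solve(self):
        ped = random_pedigree(5, 3, 3)
        A_inv = build_A_inverse(ped)
        rng = np.random.default_rng(3)
        pheno = _phenotypes(list(ped.ids), 30 + rng.normal(0, 2, 5))
        lam = 1.5
        res = solve_mme(ModelSpec("t", lam), pheno, A_inv)
        # dense oracle: cell-means X (one level) + centred age covariate
        age = pheno["slaughter_age"].to_numpy()
        X = np.column_stack([np.ones(5), age - age.mean()])
        Z = np.eye(5)
        y = pheno["value"].to_numpy()
        K = A_inv.dense()
        lhs = np.block(
            [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * K]]
        )
        sol = np.linalg.solve(lhs, np.concatenate([X.T @ y, Z.T @ y]))
        assert np.allclose(res.fixed_solutions.to_numpy(), sol[:2], atol=1e-9)
        assert np.allclose(res.ebv, sol[2:], atol=1e-9)

    def test_infinite_shrinkage_zeroes_breeding_values(self):
        ped = random_pedigree(30, 10, 4)
        A_inv = build_A_inverse(ped)
        rng = np.random.default_rng(4)
        pheno = _phenotypes(list(ped.ids), 30 + rng.normal(0, 3, 30))
        res = solve_mme(ModelSpec("t", 1e9), pheno, A_inv)
        assert np.abs(res.ebv).max() < 1e-5 * pheno["value"].std()

    def test_constant_phenotypes_give_zero_ebv(self):
        ped = random_pedigree(10, 4, 5)
        A_inv = build_A_inverse(ped)
        pheno = _phenotypes(list(ped.ids), np.full(10, 25.0),
                            ages=np.full(10, 720.0))
        res = solve_mme(ModelSpec("t", 1.0), pheno, A_inv)
        assert np.abs(res.ebv).max() < 1e-10

    def test_record_order_invariance(self):
        ped = random_pedigree(40, 10, 6)
        A_inv = build_A_inverse(ped)
        rng = np.random.default_rng(6)
        pheno = _phenotypes(
            list(ped.ids),
            30 + rng.normal(0, 3, 40),
            dates=rng.choice(["d1", "d2", "d3"], 40),
        )
        res1 = solve_mme(ModelSpec("t", 2.0), pheno, A_inv)
        res2 = solve_mme(
            ModelSpec("t", 2.0), pheno.sample(frac=1, random_state=0), A_inv
        )
        assert np.allclose(res1.ebv, res2.ebv, atol=1e-8)

    def test_unphenotyped_terminal_progeny_gets_parent_average(self):
        # two phenotyped founders, one record-less child with no descendants
        ped = random_pedigree(3, 2, 0)
        ped.sire[2], ped.dam[2] = 1, 2
        A_inv = build_A_inverse(ped)
        pheno = _phenotypes(list(ped.ids[:2]), [28.0, 33.0])
        res = solve_mme(ModelSpec("t", 1.0), pheno, A_inv)
        assert res.ebv[2] == pytest.approx(0.5 * (res.ebv[0] + res.ebv[1]))

    def test_ssgblup_equals_pblup_when_blend_is_A22(self):
        ped = random_pedigree(50, 12, 7)
        A_inv = build_A_inverse(ped)
        geno_ids = list(ped.ids[20:40])
        A22 = extract_A22(ped, geno_ids)
        fake_blend = RelationshipMatrix(A22.dense().copy(), geno_ids, "G_blend")
        H_inv = build_H_inverse(A_inv, A22, fake_blend, geno_ids)
        rng = np.random.default_rng(7)
        pheno = _phenotypes(list(ped.ids), 30 + rng.normal(0, 3, 50))
        res_a = solve_mme(ModelSpec("t", 1.0), pheno, A_inv)
        res_h = solve_mme(ModelSpec("t", 1.0), pheno, H_inv)
        assert np.allclose(res_a.ebv, res_h.ebv, atol=1e-6)
        assert (res_a.method, res_h.method) == ("PBLUP", "ssGBLUP")
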