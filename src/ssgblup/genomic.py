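"""SNP quality control and the genomic relationship matrix.

QC removes, in order: animals by call rate, SNPs by call rate, SNPs by minor
allele frequency, and SNPs by heterozygosity deviation from Hardy-Weinberg
expectation (|Hobs - 2p(1-p)| above a threshold), each stage acting on the
matrix surviving the previous one.  G follows VanRaden's first method,
centring by observed allele frequencies of the post-QC genotyped set, and is
blended with the pedigree block A22 (default 0.95 G + 0.05 A22) to keep the
combined matrix invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import RelationshipMatrix


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of 0/1/2 allele counts with missingness."""

    codes: np.ndarray
    missing_mask: np.ndarray
    animal_ids: list
    snp_ids: list

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.codes.shape
        if self.missing_mask.shape != (n, m):
            raise ValueError("mask shape must match codes")
        if len(self.animal_ids) != n or len(self.snp_ids) != m:
            raise ValueError("id lists must match matrix shape")
        observed = self.codes[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("genotype codes must be 0, 1 or 2")

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed reference-allele frequency per SNP, ignoring missing."""
        called = ~self.missing_mask
        n_called = called.sum(axis=0)
        if (n_called == 0).any():
            raise ValueError("SNP with no called genotypes")
        return (self.codes * called).sum(axis=0) / (2.0 * n_called)

    def subset(self, animal_rows=None, snp_cols=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_animals) if animal_rows is None else animal_rows
        cols = np.arange(self.n_snps) if snp_cols is None else snp_cols
        return GenotypeMatrix(
            codes=self.codes[np.ix_(rows, cols)],
            missing_mask=self.missing_mask[np.ix_(rows, cols)],
            animal_ids=[self.animal_ids[i] for i in rows],
            snp_ids=[self.snp_ids[j] for j in cols],
        )


@dataclass
class QCReport:
    """Per-stage removal counts; retained = input - SNP removals."""

    n_input_snps: int
    n_removed_callrate_animal: int
    n_removed_callrate_snp: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained_snps: int

    def __post_init__(self):
        expected = (
            self.n_input_snps
            - self.n_removed_callrate_snp
            - self.n_removed_maf
            - self.n_removed_hwe
        )
        if self.n_retained_snps != expected:
            raise ValueError("QC counts do not reconcile")
        if min(vars(self).values()) < 0:
            raise ValueError("QC counts must be non-negative")

    def summary(self) -> str:
        return (
            f"{self.n_input_snps} SNPs input; removed "
            f"{self.n_removed_callrate_snp} by SNP call rate, "
            f"{self.n_removed_maf} by minor allele frequency, "
            f"{self.n_removed_hwe} by heterozygosity deviation; "
            f"{self.n_removed_callrate_animal} animals removed by call rate; "
            f"{self.n_retained_snps} SNPs retained."
        )


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    het_dev_max: float = 0.15,
    call_rate_min: float = 0.90,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard SNP-chip quality-control cascade.

    Stages run in the order animal call rate, SNP call rate, MAF,
    heterozygosity deviation; each stage recomputes its statistics on the
    matrix left by the previous stage.
    """
    if g.n_animals == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    called = ~g.missing_mask

    animal_cr = called.mean(axis=1)
    keep_animals = np.where(animal_cr >= call_rate_min)[0]
    n_rm_animal = g.n_animals - keep_animals.size
    g1 = g.subset(animal_rows=keep_animals) if n_rm_animal else g

    called = ~g1.missing_mask
    snp_cr = called.mean(axis=0)
    keep_cr = snp_cr >= call_rate_min
    n_rm_cr = int((~keep_cr).sum())
    g2 = g1.subset(snp_cols=np.where(keep_cr)[0]) if n_rm_cr else g1

    p = g2.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    keep_maf = maf >= maf_min
    n_rm_maf = int((~keep_maf).sum())
    g3 = g2.subset(snp_cols=np.where(keep_maf)[0]) if n_rm_maf else g2

    p = g3.allele_frequencies()
    called = ~g3.missing_mask
    het_obs = ((g3.codes == 1) & called).sum(axis=0) / called.sum(axis=0)
    het_exp = 2.0 * p * (1.0 - p)
    keep_hwe = np.abs(het_obs - het_exp) <= het_dev_max
    n_rm_hwe = int((~keep_hwe).sum())
    g4 = g3.subset(snp_cols=np.where(keep_hwe)[0]) if n_rm_hwe else g3

    if g4.n_snps == 0:
        raise ValueError("quality control removed every SNP")
    report = QCReport(
        n_input_snps=g.n_snps,
        n_removed_callrate_animal=n_rm_animal,
        n_removed_callrate_snp=n_rm_cr,
        n_removed_maf=n_rm_maf,
        n_removed_hwe=n_rm_hwe,
        n_retained_snps=g4.n_snps,
    )
    return g4, report


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing cells with the rounded per-SNP mean genotype (2p)."""
    if not g.missing_mask.any():
        return GenotypeMatrix(
            g.codes.copy(),
            np.zeros_like(g.missing_mask),
            list(g.animal_ids),
            list(g.snp_ids),
        )
    p = g.allele_frequencies()  # raises if a column is fully missing
    fill = np.clip(np.rint(2.0 * p), 0, 2).astype(np.int8)
    codes = g.codes.copy()
    rows, cols = np.where(g.missing_mask)
    codes[rows, cols] = fill[cols]
    return GenotypeMatrix(
        codes, np.zeros_like(g.missing_mask), list(g.animal_ids), list(g.snp_ids)
    )


def build_G(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    Z = M - 2p per SNP; G = Z Z' / (2 sum_j p_j (1 - p_j)), with p the
    observed allele frequencies of the genotyped set.
    """
    if g.missing_mask.any():
        raise ValueError("impute missing genotypes before building G")
    if g.n_animals < 2:
        raise ValueError("G requires at least two animals")
    p = g.allele_frequencies()
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: zero VanRaden denominator")
    Z = g.codes.astype(np.float64) - 2.0 * p
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(G, list(g.animal_ids), "G")


def tune_G_to_A22(G: RelationshipMatrix, A22: RelationshipMatrix) -> RelationshipMatrix:
    """Rescale G so its mean diagonal and mean off-diagonal match A22.

    Solves a + b*G = G* with the two moment conditions; the additive constant
    shifts the genomic base population onto the pedigree base.
    """
    if list(G.ids) != list(A22.ids):
        raise ValueError("G and A22 must share the same animal ordering")
    n = G.n
    Gd, Ad = G.dense(), A22.dense()
    g_diag, a_diag = np.trace(Gd) / n, np.trace(Ad) / n
    g_off = (Gd.sum() - np.trace(Gd)) / (n * (n - 1))
    a_off = (Ad.sum() - np.trace(Ad)) / (n * (n - 1))
    if np.isclose(g_diag, g_off):
        raise ValueError("degenerate G: cannot tune")
    b = (a_diag - a_off) / (g_diag - g_off)
    a = a_diag - b * g_diag
    return RelationshipMatrix(a + b * Gd, list(G.ids), "G")


def blend_G(
    G: RelationshipMatrix,
    A22: RelationshipMatrix,
    w_G: float = 0.95,
    w_A: float = 0.05,
) -> RelationshipMatrix:
    """Weighted blend w_G*G + w_A*A22 guaranteeing invertibility for w_A > 0."""
    if list(G.ids) != list(A22.ids):
        raise ValueError("G and A22 must share the same animal ordering")
    if not np.isclose(w_G + w_A, 1.0):
        raise ValueError("blend weights must sum to 1")
    blended = w_G * G.dense() + w_A * A22.dense()
    return RelationshipMatrix(blended, list(G.ids), "G_blend")
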