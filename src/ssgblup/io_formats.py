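"""Readers and writers for the on-disk artifacts.

Pedigree CSV (animal,sire,dam[,birth_year], unknown parent "0"), genotype
tables as PLINK-RAW-style text (header of SNP ids, rows of 0/1/2/NA),
phenotype CSV, LR-report TSV, and a flat YAML run configuration.

External identifiers are opaque strings; internally animals are renumbered
1..n in topological order (parents before offspring) with 0 reserved for an
unknown parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genomic import GenotypeMatrix
from .pedigree import Pedigree

LR_REPORT_COLUMNS = [
    "trait",
    "method",
    "acc_partial",
    "acc_whole",
    "bias",
    "dispersion",
    "rho_methods_partial",
    "gain_methods_partial",
    "rho_methods_whole",
    "gain_methods_whole",
    "rho_partial_whole",
    "gain_partial_whole",
    "F_bar",
    "f_bar",
    "sigma2_u_inf",
]


@dataclass
class RunConfig:
    """Flat configuration of a full study run.

    QC thresholds, the G/A22 blend, and the production MCMC settings default
    to the values used in routine Hanwoo carcass evaluation; the pipeline
    ships a lighter desk-scale MCMC profile separately.
    """

    traits: list = field(default_factory=lambda: ["trait"])
    maf_min: float = 0.01
    het_dev_max: float = 0.15
    call_rate_min: float = 0.90
    w_G: float = 0.95
    w_A22: float = 0.05
    tune_G: bool = False
    chain: int = 550_000
    burn_in: int = 50_000
    thin: int = 50
    seed: int = 1
    focal_birth_years: list = field(default_factory=lambda: [2016, 2017])
    lr_denominator_sign: str = "minus"  # "minus": 1 + F_bar - 2 f_bar
    lr_sqrt_convention: bool = True

    def __post_init__(self):
        if not np.isclose(self.w_G + self.w_A22, 1.0):
            raise ValueError("blend weights must sum to 1")
        if not (0 < self.w_G <= 1 and 0 <= self.w_A22 <= 1):
            raise ValueError("blend weights must lie in (0, 1]")
        if self.burn_in >= self.chain:
            raise ValueError("burn_in must be smaller than chain length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.lr_denominator_sign not in ("minus", "plus"):
            raise ValueError("lr_denominator_sign must be 'minus' or 'plus'")


def read_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def write_run_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def _toposort(records: dict) -> list:
    """Order animals so that parents precede offspring; detect cycles.

    records maps animal -> (sire, dam, birth_year) with None for unknown.
    Returns the ordered animal list; raises on a parent-offspring cycle,
    naming one animal involved.
    """
    order = []
    state = {}  # 0 = visiting, 1 = done
    for start in records:
        if state.get(start) == 1:
            continue
        stack = [(start, iter(_parents(records, start)))]
        state[start] = 0
        while stack:
            node, parents = stack[-1]
            advanced = False
            for p in parents:
                st = state.get(p)
                if st == 0:
                    raise ValueError(
                        f"pedigree cycle detected involving animal {p!r}"
                    )
                if st is None:
                    state[p] = 0
                    stack.append((p, iter(_parents(records, p))))
                    advanced = True
                    break
            if not advanced:
                state[node] = 1
                order.append(node)
                stack.pop()
    return order


def _parents(records, animal):
    if animal not in records:
        return ()
    s, d, _ = records[animal]
    return tuple(p for p in (s, d) if p is not None)


def read_pedigree(path, unknown_token: str = "0") -> Pedigree:
    """Read a pedigree CSV and return it renumbered in topological order.

    Rows are animal,sire,dam with an optional fourth birth-year column.
    Unknown parents carry unknown_token. Animals appearing only as parents
    are added as founders. Duplicate animals, self-ancestry and cycles are
    hard errors.
    """
    records = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.replace("\t", ",").split(",")]
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}:{lineno}: expected 3-4 columns")
            animal, sire, dam = parts[:3]
            if lineno == 1 and animal.lower() in ("animal", "id"):
                continue  # header
            year = None
            if len(parts) == 4 and parts[3] not in ("", unknown_token):
                year = int(parts[3])
            sire = None if sire == unknown_token else sire
            dam = None if dam == unknown_token else dam
            if animal in (sire, dam):
                raise ValueError(f"animal {animal!r} listed as its own parent")
            if animal in records:
                raise ValueError(f"duplicate animal id {animal!r}")
            records[animal] = (sire, dam, year)
    # implicit founders: ids seen only as parents
    for animal in list(records):
        for p in _parents(records, animal):
            if p not in records:
                records[p] = (None, None, None)
    order = _toposort(records)
    code = {a: i + 1 for i, a in enumerate(order)}
    n = len(order)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    year = np.full(n, -1, dtype=np.int64)
    for a in order:
        s, d, y = records[a]
        i = code[a] - 1
        sire[i] = code[s] if s is not None else 0
        dam[i] = code[d] if d is not None else 0
        if y is not None:
            year[i] = y
    return Pedigree(ids=order, sire=sire, dam=dam, birth_year=year)


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal,sire,dam,birth_year\n")
        for i, a in enumerate(pedigree.ids):
            s = pedigree.ids[pedigree.sire[i] - 1] if pedigree.sire[i] > 0 else "0"
            d = pedigree.ids[pedigree.dam[i] - 1] if pedigree.dam[i] > 0 else "0"
            y = pedigree.birth_year[i] if pedigree.birth_year is not None else -1
            fh.write(f"{a},{s},{d},{y if y >= 0 else 0}\n")


def read_genotypes(path) -> GenotypeMatrix:
    """Read a PLINK-RAW-style genotype table.

    First row: SNP ids (first field an id column label). Following rows:
    animal id then 0/1/2/NA codes, whitespace- or comma-separated. Any other
    cell value is a hard error naming the row and column.
    """
    with open(path) as fh:
        header = fh.readline().replace(",", " ").split()
        snp_ids = header[1:]
        animal_ids, rows, masks = [], [], []
        for lineno, line in enumerate(fh, 2):
            parts = line.replace(",", " ").split()
            if not parts:
                continue
            if len(parts) != len(snp_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(snp_ids) + 1} fields"
                )
            animal_ids.append(parts[0])
            row = np.zeros(len(snp_ids), dtype=np.int8)
            mask = np.zeros(len(snp_ids), dtype=bool)
            for j, cell in enumerate(parts[1:]):
                if cell == "NA":
                    mask[j] = True
                elif cell in ("0", "1", "2"):
                    row[j] = int(cell)
                else:
                    raise ValueError(
                        f"{path}:{lineno}: invalid genotype {cell!r} in "
                        f"column {snp_ids[j]}"
                    )
            rows.append(row)
            masks.append(mask)
    return GenotypeMatrix(
        codes=np.array(rows, dtype=np.int8),
        missing_mask=np.array(masks, dtype=bool),
        animal_ids=animal_ids,
        snp_ids=snp_ids,
    )


def write_genotypes(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal " + " ".join(g.snp_ids) + "\n")
        for i, a in enumerate(g.animal_ids):
            cells = [
                "NA" if g.missing_mask[i, j] else str(int(g.codes[i, j]))
                for j in range(len(g.snp_ids))
            ]
            fh.write(a + " " + " ".join(cells) + "\n")


PHENOTYPE_COLUMNS = ["animal", "trait", "value", "slaughter_date", "slaughter_age"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype CSV into a validated DataFrame.

    Columns: animal, trait, value (kg), slaughter_date (categorical level),
    slaughter_age (days). Values must be finite and positive.
    """
    df = pd.read_csv(path, dtype={"animal": str, "slaughter_date": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(df["value"])) or (df["value"] <= 0).any():
        raise ValueError("phenotype values must be finite and positive")
    if (df["slaughter_age"] <= 0).any():
        raise ValueError("slaughter ages must be positive")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_lr_report(report, path) -> None:
    """Write an LR validation report as TSV, one row per (trait, method)."""
    table = getattr(report, "table", report)
    table = table.reindex(columns=LR_REPORT_COLUMNS)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_lr_report(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"trait": str, "method": str}
    ).reindex(columns=LR_REPORT_COLUMNS)


def write_ebv_table(path, frames) -> None:
    """Write EBV tables (animal, method, dataset, trait, ebv) as one TSV."""
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_ebv_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"animal": str})
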