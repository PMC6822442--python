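"""Text-format I/O: PLINK PED/MAP, pedigree CSV, phenotype CSV.

PED rows are `FID IID PAT MAT SEX PHENO` followed by two allele calls per
SNP (A = reference, B = counted allele, 0 0 = missing); MAP rows are
`chrom snp cM bp`.  Dosage is the count of the B allele.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import GenotypeMatrix, Pedigree

__all__ = [
    "write_ped_map",
    "read_ped_map",
    "write_pedigree_csv",
    "read_pedigree_csv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
]

_ALLELES = ("A", "B")


def write_ped_map(genotypes: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write `<prefix>.ped` and `<prefix>.map`.

    Fractional (imputed) dosages are rounded to the nearest genotype
    class for the allele representation.
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    pd.DataFrame({
        "chrom": genotypes.chrom,
        "snp": genotypes.snp_ids,
        "cm": 0,
        "bp": genotypes.pos,
    }).to_csv(map_path, sep="\t", header=False, index=False)

    code = {0: "A A", 1: "A B", 2: "B B"}
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(genotypes.ids):
            calls = []
            for dose in genotypes.dosages[i]:
                if np.isnan(dose):
                    calls.append("0 0")
                else:
                    calls.append(code[int(round(dose))])
            fh.write(f"FAM1 {ind} 0 0 0 -9 " + " ".join(calls) + "\n")
    return ped_path, map_path


def read_ped_map(prefix) -> GenotypeMatrix:
    """Read a PED/MAP pair into a GenotypeMatrix (dosage = B-allele count).

    For each SNP the counted allele is the lexicographically later of the
    observed alleles (so A/B files count B); missing calls become nan.
    """
    prefix = Path(prefix)
    mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                     names=["chrom", "snp", "cm", "bp"], dtype=str)
    m = len(mp)
    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}")
            ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.asarray(rows, dtype="U8").reshape(len(ids), m, 2)
    dosages = np.full((len(ids), m), np.nan)
    for j in range(m):
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if not observed:
            continue
        counted = observed[-1]
        valid = (col != "0").all(axis=1)
        dosages[valid, j] = (col[valid] == counted).sum(axis=1)
    return GenotypeMatrix(
        dosages=dosages, ids=np.asarray(ids),
        chrom=mp["chrom"].to_numpy(),
        pos=mp["bp"].to_numpy(dtype=np.int64),
        snp_ids=mp["snp"].to_numpy())


def write_pedigree_csv(pedigree: Pedigree, path) -> Path:
    """id,sire,dam CSV with 0 for unknown parents."""
    path = Path(path)
    pedigree.to_dataframe().to_csv(path, index=False)
    return path


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path)
    return Pedigree.from_dataframe(df)


def write_phenotypes_csv(records: pd.DataFrame, path) -> Path:
    path = Path(path)
    records.to_csv(path, index=False)
    return path


def read_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
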