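"""PLINK bed/bim/fam reading and writing (bed v1.00, SNP-major).

Genotypes are stored as counts of the bim A1 allele (``allele_a``); the
2-bit bed codes are 00 = hom A1 (count 2), 10 = het, 11 = hom A2 (count 0),
01 = missing. Phenotype/covariate tables use the whitespace-delimited
FID IID VALUE... convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panels import MISSING, Cohort, SnpPanel

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# bed 2-bit code -> allele-count of A1; 1 is the missing code
_CODE_TO_COUNT = np.array([2, -1, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0, -1: 1, 1: 2, 0: 3}


def write_plink(cohort: Cohort, panel: SnpPanel, prefix: str | Path) -> None:
    """Write cohort + panel as PLINK bed/bim/fam files at ``prefix``."""
    if cohort.n_snps != panel.n_snps:
        raise ValueError("cohort and panel disagree on the number of SNPs")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    bim = pd.DataFrame({
        "chrom": panel.chromosome, "snp": panel.snp_id, "cm": 0,
        "pos": panel.position, "a1": panel.allele_a, "a2": panel.allele_b,
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    pheno = np.where(cohort.phenotype == 1, 2, np.where(cohort.phenotype == 0, 1, -9))
    fam = pd.DataFrame({
        "fid": cohort.family_id, "iid": cohort.individual_id,
        "pat": 0, "mat": 0, "sex": cohort.sex, "pheno": pheno,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n_ind = cohort.n_individuals
    codes = np.empty_like(cohort.genotypes, dtype=np.uint8)
    for count, code in _COUNT_TO_CODE.items():
        codes[cohort.genotypes == count] = code
    # SNP-major: one row of ceil(n_ind / 4) bytes per SNP, individuals packed
    # 4 to a byte, lowest-order bits first.
    n_pad = (-n_ind) % 4
    padded = np.zeros((cohort.n_snps, n_ind + n_pad), dtype=np.uint8)
    padded[:, :n_ind] = codes.T
    quads = padded.reshape(cohort.n_snps, -1, 4)
    payload = (quads[:, :, 0] | (quads[:, :, 1] << 2)
               | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(payload.tobytes())


def read_plink(prefix: str | Path) -> tuple[Cohort, SnpPanel]:
    """Read PLINK bed/bim/fam files back into (Cohort, SnpPanel).

    Panel frequencies are re-estimated from the genotypes (clipped away
    from 0 and 1 so monomorphic SNPs keep a valid panel entry).
    """
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype=str)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    n_snp, n_ind = len(bim), len(fam)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _MAGIC:
        raise ValueError("not a SNP-major PLINK bed v1.00 file (bad magic bytes)")
    bytes_per_snp = (n_ind + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(payload) != n_snp * bytes_per_snp:
        raise ValueError(
            f"bed payload has {len(payload)} bytes but bim/fam imply "
            f"{n_snp} x {bytes_per_snp}"
        )
    quads = payload.reshape(n_snp, bytes_per_snp)
    codes = np.empty((n_snp, 4 * bytes_per_snp), dtype=np.uint8)
    for j in range(4):
        codes[:, j::4] = (quads >> (2 * j)) & 0b11
    genotypes = _CODE_TO_COUNT[codes[:, :n_ind]].T.copy()

    g = np.ma.masked_equal(genotypes, MISSING)
    counts = g.count(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.asarray(g.sum(axis=0)) / np.maximum(2 * counts, 1)
    eps = 1.0 / (2 * n_ind + 2)
    p = np.clip(p, eps, 1 - eps)

    panel = SnpPanel(bim["snp"].to_numpy(dtype=object),
                     bim["chrom"].to_numpy(dtype=object),
                     bim["pos"].astype(np.int64).to_numpy(),
                     bim["a1"].to_numpy(dtype=object),
                     bim["a2"].to_numpy(dtype=object), p)
    pheno_raw = fam["pheno"].astype(float).astype(int)
    phenotype = np.where(pheno_raw == 2, 1, np.where(pheno_raw == 1, 0, -9)).astype(np.int8)
    cohort = Cohort(genotypes, phenotype, fam["sex"].astype(float).astype(np.int8).to_numpy(),
                    fam["fid"].to_numpy(dtype=object), fam["iid"].to_numpy(dtype=object))
    return cohort, panel


def write_pheno(cohort: Cohort, path: str | Path, values=None) -> None:
    """Write a FID IID VALUE phenotype file (defaults to case/control 1/0)."""
    vals = cohort.phenotype if values is None else np.asarray(values)
    pd.DataFrame({"fid": cohort.family_id, "iid": cohort.individual_id,
                  "value": vals}).to_csv(path, sep="\t", header=False, index=False)


def read_pheno(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None,
                       names=["fid", "iid", "value"], dtype={0: str, 1: str})


def write_covar(ids: tuple[np.ndarray, np.ndarray], matrix: np.ndarray,
                path: str | Path) -> None:
    """Write FID IID C1..Ck covariate columns (e.g. principal components)."""
    fid, iid = ids
    df = pd.DataFrame(matrix, columns=[f"C{i + 1}" for i in range(matrix.shape[1])])
    df.insert(0, "iid", iid)
    df.insert(0, "fid", fid)
    df.to_csv(path, sep="\t", header=False, index=False)
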