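"""Readers and writers for the standard formats around the pipeline.

PLINK bed/bim/fam (SNP-major 2-bit .bed; the effect allele is stored as
allele 1, so a hom-allele-1 code decodes to dosage 2), VCF via cyvcf2
(effect allele = ALT; multi-allelic records are skipped with a count),
phenotype TSV (missing values written as '.'), and YAML pipeline
configuration with strict key checking.  All tabular positions are
1-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import GenotypeMatrix

__all__ = [
    "PipelineConfig",
    "read_genotypes",
    "read_plink",
    "write_plink",
    "read_vcf",
    "read_phenotypes",
    "write_phenotypes",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes with effect allele as allele 1:
# 00 -> hom allele 1 (dosage 2), 01 -> missing, 10 -> het, 11 -> hom allele 2
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

PHENO_COLUMNS = [
    "iid", "sex", "age", "cohort", "fpg_mmol_l", "glu2h_mmol_l",
    "fins_pmol_l", "ins2h_pmol_l", "weight_kg", "selfreport_dm", "status",
]


def _byte_lut() -> np.ndarray:
    lut = np.empty((256, 4))
    for byte in range(256):
        for s in range(4):
            lut[byte, s] = _CODE_TO_DOSAGE[(byte >> (2 * s)) & 0b11]
    return lut


_LUT = _byte_lut()


def write_plink(prefix, G: GenotypeMatrix, fam: pd.DataFrame | None = None) -> None:
    """Write bed/bim/fam files for a genotype matrix.

    The effect allele is written as allele 1 of the .bim record.
    """
    prefix = Path(prefix)
    n, m = G.dosages.shape
    dos = G.dosages
    codes = np.full((m, n), 1, dtype=np.uint8)  # default missing (01)
    codes[(dos == 2.0).T] = 0
    codes[(dos == 1.0).T] = 2
    codes[(dos == 0.0).T] = 3
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    quads = codes.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame({
        "chrom": G.chrom, "snp_id": G.snp_ids, "cm": 0, "pos": G.pos,
        "a1": G.effect_alleles, "a2": G.other_alleles,
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    if fam is None:
        fam = pd.DataFrame({
            "fid": G.iids, "iid": G.iids, "pat": 0, "mat": 0,
            "sex": 0, "pheno": -9,
        })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix) -> GenotypeMatrix:
    """Read bed/bim/fam into a GenotypeMatrix (effect allele = allele 1)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes at offset 0 "
            f"(got {raw[:3].tobytes()!r}, expected SNP-major PLINK bed)"
        )
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != m * bytes_per_snp:
        raise ValueError(
            f"{prefix.with_suffix('.bed')}: expected {m * bytes_per_snp} data "
            f"bytes for {n} individuals x {m} SNPs, found {body.size}"
        )
    dosages = _LUT[body.reshape(m, bytes_per_snp)].reshape(m, -1)[:, :n].T
    return GenotypeMatrix(
        dosages=dosages, snp_ids=bim["snp_id"].to_numpy(),
        effect_alleles=bim["a1"].to_numpy(), other_alleles=bim["a2"].to_numpy(),
        chrom=bim["chrom"].to_numpy(), pos=bim["pos"].to_numpy(),
        iids=fam["iid"].to_numpy(),
    )


def read_vcf(path):
    """Read a VCF of biallelic SNPs; effect allele is ALT.

    Multi-allelic records are skipped; returns (GenotypeMatrix, n_skipped).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    iids = np.array(vcf.samples)
    cols, ids, ea, oa, chrom, pos = [], [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types)
        dos = np.where(gt == 0, 0.0,
                       np.where(gt == 1, 1.0,
                                np.where(gt == 3, 2.0, np.nan)))
        cols.append(dos)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        ea.append(var.ALT[0])
        oa.append(var.REF)
        chrom.append(var.CHROM)
        pos.append(var.POS)
    vcf.close()
    if not cols:
        raise ValueError(f"{path}: no biallelic SNP records found")
    G = GenotypeMatrix(
        dosages=np.column_stack(cols), snp_ids=np.array(ids),
        effect_alleles=np.array(ea), other_alleles=np.array(oa),
        chrom=np.array(chrom), pos=np.array(pos, dtype=int), iids=iids,
    )
    return G, n_skipped


def read_genotypes(path, format: str = "plink"):
    """Dispatch to the PLINK or VCF reader."""
    if format == "plink":
        return read_plink(path)
    if format == "vcf":
        return read_vcf(path)[0]
    raise ValueError(f"unknown genotype format {format!r}")


def write_phenotypes(path, pheno: pd.DataFrame) -> None:
    """Write the phenotype TSV with '.' for missing values."""
    out = pheno.copy()
    if "selfreport_dm" in out:
        out["selfreport_dm"] = out["selfreport_dm"].astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g")


def read_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", na_values=["."], dtype={"iid": str})
    if "selfreport_dm" in pheno:
        pheno["selfreport_dm"] = pheno["selfreport_dm"].astype("boolean").astype(bool)
    return pheno


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    Defaults follow the discovery study where it states a value: baseline
    risk 0.1, 20,000 power replicates, significance threshold 4.3e-7,
    1000 bootstrap replicates, K = 2 ancestral components, 10 principal
    components.
    """

    out_prefix: str = "recessmap_run"
    genotypes: str | None = None     # PLINK prefix; simulated when None
    phenotypes: str | None = None
    n: int = 1000
    m: int = 2000
    K: int = 2
    eaf_inuit: float = 0.31
    eaf_eu: float = 0.03
    or_effect: float = 3.0
    baseline_risk: float = 0.1
    divergence: float = 0.15
    missing_rate: float = 0.0
    reps: int = 20000
    alpha: float = 4.3e-7
    B: int = 1000
    n_pcs: int = 10
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
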