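"""Genotype matrices: loading, allele frequencies, MAF filtering, centering,
and the marker-variance scale used by the SNP-effect prior."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Animals x SNPs 0/1/2 codes (counts of allele A) with frequencies p."""

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    codes: np.ndarray
    p: np.ndarray = None

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.codes = np.asarray(self.codes)
        if self.codes.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise GenotypeError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.snp_ids)} SNPs")
        if self.p is None:
            self.p = allele_frequencies(self.codes)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p, 1.0 - self.p)


@dataclass(frozen=True)
class MarkerScale:
    """Prior scale of SNP effects: sigma_g2 = (1-k) sigma_a2 / sum 2 p_i q_i."""

    sum2pq: float
    sigma_g2: float
    k: float
    sigma_a2: float


def allele_frequencies(codes: np.ndarray) -> np.ndarray:
    """p_i = (column sum) / (2 n); rejects codes outside {0, 1, 2}."""
    codes = np.asarray(codes)
    if codes.shape[0] == 0:
        return np.zeros(codes.shape[1] if codes.ndim == 2 else 0)
    bad = (codes != 0) & (codes != 1) & (codes != 2)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeError(
            f"genotype code {codes[i, j]!r} at animal row {i}, SNP column {j} "
            "not in {0, 1, 2}")
    return codes.sum(axis=0) / (2.0 * codes.shape[0])


def maf_filter(gm: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Retain SNPs with MAF >= threshold (inclusive), preserving SNP order."""
    if not 0.0 <= threshold <= 0.5:
        raise GenotypeError(f"MAF threshold {threshold} outside [0, 0.5]")
    keep = gm.maf >= threshold
    n_kept = int(keep.sum())
    log.info("MAF filter >= %g: retained %d of %d SNPs", threshold, n_kept, gm.n_snps)
    if n_kept == 0:
        log.warning("MAF filter >= %g removed every SNP", threshold)
    return GenotypeMatrix(
        animal_ids=gm.animal_ids, snp_ids=gm.snp_ids[keep],
        codes=gm.codes[:, keep], p=gm.p[keep],
    )


def center_genotypes(gm: GenotypeMatrix) -> np.ndarray:
    """Z with Z_ij = codes_ij - 2 p_j (column means of Z are 0)."""
    return gm.codes.astype(float) - 2.0 * gm.p


def marker_scale(p: np.ndarray, k: float, sigma_a2: float) -> MarkerScale:
    """sum2pq and the per-SNP prior variance (1-k) sigma_a2 / sum2pq."""
    p = np.asarray(p, dtype=float)
    sum2pq = float(np.sum(2.0 * p * (1.0 - p)))
    if sum2pq <= 0.0:
        raise GenotypeError("all SNPs monomorphic: sum 2pq = 0")
    return MarkerScale(sum2pq=sum2pq, sigma_g2=(1.0 - k) * sigma_a2 / sum2pq,
                       k=k, sigma_a2=sigma_a2)


def load_genotypes_tsv(path, plink_raw: bool = False,
                       animal_subset: Optional[Sequence[str]] = None) -> GenotypeMatrix:
    """Read a genotype table.

    Default dialect: tab-separated, first column ``animal_id``, remaining
    columns are SNP codes with SNP ids in the header.  With
    ``plink_raw=True`` a PLINK ``.raw``-like dialect is accepted instead:
    whitespace-separated with FID/IID/PAT/MAT/SEX/PHENOTYPE prefix columns,
    IID used as the animal id.
    """
    if plink_raw:
        df = pd.read_csv(path, sep=r"\s+")
        meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
                if c in df.columns]
        if "IID" not in meta:
            raise GenotypeError("PLINK-RAW dialect requires an IID column")
        ids = df["IID"].astype(str).to_numpy()
        df = df.drop(columns=meta)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
        if df.columns[0] != "animal_id":
            raise GenotypeError(
                f"first genotype column must be 'animal_id', got {df.columns[0]!r}")
        ids = df["animal_id"].to_numpy()
        df = df.drop(columns=["animal_id"])
    codes = df.to_numpy()
    if np.isnan(codes.astype(float)).any():
        raise GenotypeError("missing genotype codes are not supported")
    codes = codes.astype(np.int8)
    gm = GenotypeMatrix(animal_ids=ids, snp_ids=df.columns.to_numpy(), codes=codes)
    if animal_subset is not None:
        keep = np.isin(gm.animal_ids.astype(str), list(animal_subset))
        gm = GenotypeMatrix(animal_ids=gm.animal_ids[keep], snp_ids=gm.snp_ids,
                            codes=gm.codes[keep])
    return gm


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.codes, columns=gm.snp_ids)
    df.insert(0, "animal_id", gm.animal_ids)
    df.to_csv(path, sep="\t", index=False)
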