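"""Core genotype container for accession-by-SNP panels.

A :class:`GenotypePanel` holds diploid calls for one named population
(e.g. a wild *Glycine soja* panel or a cultivated *G. max* evaluation
panel) over a set of biallelic SNPs.  Calls are stored as a compact
``int8`` matrix with the coding

====  =========================================
code  meaning
====  =========================================
0     homozygous for allele A (``allele_a``)
1     heterozygous
2     homozygous for allele B (``allele_b``)
-1    missing
====  =========================================

SNP metadata (id, chromosome, position, alleles) lives in a pandas
DataFrame sorted by (chromosome, position), so genomic-window
operations can rely on positional order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_A = 0
HET = 1
HOM_B = 2
MISSING = -1

#: required columns of the SNP metadata frame
SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]


@dataclass
class SnpRecord:
    """One biallelic SNP: identifier, map location and its two alleles."""

    snp_id: str
    chrom: int
    pos: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"SNP {self.snp_id}: position must be positive")
        if self.allele_a == self.allele_b:
            raise ValueError(f"SNP {self.snp_id}: alleles must differ")


@dataclass
class GenotypePanel:
    """Accessions x SNPs diploid call matrix for one named panel."""

    panel_id: str
    accession_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"snps frame lacks columns {missing_cols}")
        if self.calls.shape != (len(self.accession_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.snps)} SNPs"
            )
        order = self.snps[["chrom", "pos"]].to_numpy()
        if len(order) > 1 and not (
            (np.diff(order[:, 0]) > 0)
            | ((np.diff(order[:, 0]) == 0) & (np.diff(order[:, 1]) >= 0))
        ).all():
            raise ValueError("SNPs must be sorted by (chromosome, position)")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps["snp_id"][self.snps["snp_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")
        self.snps = self.snps.reset_index(drop=True)

    # -- basic geometry ------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.snps["snp_id"])

    def missing_fraction(self) -> float:
        """Overall fraction of missing calls."""
        if self.calls.size == 0:
            return 0.0
        return float((self.calls == MISSING).mean())

    # -- derived matrices ----------------------------------------------
    def dose_b(self) -> np.ndarray:
        """Count of allele B per call (0/1/2), NaN where missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def dose_major(self) -> np.ndarray:
        """Numeric coding with homozygous major allele = 2, minor = 0.

        Heterozygotes map to 1; missing to NaN.  "Major" is decided per
        SNP from this panel's own non-missing calls (ties go to allele A).
        """
        d = self.dose_b()
        with np.errstate(invalid="ignore"):
            freq_b = np.nanmean(d, axis=0) / 2.0
        major_is_b = freq_b > 0.5  # ties -> allele A is major
        out = 2.0 - d  # dose of allele A
        out[:, major_is_b] = d[:, major_is_b]
        return out

    # -- subsetting ----------------------------------------------------
    def take_snps(self, mask_or_index) -> "GenotypePanel":
        """Panel restricted to a boolean mask or integer index over SNPs."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            panel_id=self.panel_id,
            accession_ids=list(self.accession_ids),
            snps=self.snps.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx].copy(),
        )

    def restrict_to(self, snp_ids) -> "GenotypePanel":
        """Panel restricted to the given snp_ids, in panel order."""
        wanted = set(snp_ids)
        mask = self.snps["snp_id"].isin(wanted).to_numpy()
        return self.take_snps(mask)

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            panel_id=self.panel_id,
            accession_ids=list(self.accession_ids),
            snps=self.snps.copy(),
            calls=self.calls.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.panel_id == other.panel_id
            and self.accession_ids == other.accession_ids
            and self.snps.reset_index(drop=True).equals(
                other.snps.reset_index(drop=True)
            )
            and np.array_equal(self.calls, other.calls)
        )
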