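"""HapMap genotype I/O, QC filters and kNN imputation.

Implements the genotype-processing chain applied to each panel before
any population-genetic or association analysis:

1. heterozygous calls converted to missing (inbred-line panels),
2. SNPs with missing fraction strictly above 10% dropped,
3. SNPs monomorphic for the same allele in every panel dropped,
4. panels intersected to their common SNP set,
5. remaining missing genotypes imputed with an LD-kNN scheme: for each
   missing call, rank nearby SNPs by LD r^2 with the target SNP, find
   the k accessions most similar to the focal accession over the
   top-LD SNPs, and impute the neighbours' majority genotype.

Missing trait values are imputed separately with a plain kNN on
Euclidean genotype distance.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .panel import GenotypePanel, HET, HOM_A, HOM_B, MISSING
from .traits import TraitRecord

__all__ = [
    "read_hapmap", "write_hapmap", "hets_to_missing", "filter_missingness",
    "filter_monomorphic", "intersect_snps", "impute_ld_knn", "impute_trait_knn",
    "HapmapParseError",
]

log = logging.getLogger(__name__)

HAPMAP_HEADER = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
    "protLSID", "assayLSID", "panelLSID", "QCcode",
]

_IUPAC_HET = {
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"),
    "W": ("A", "T"), "K": ("G", "T"), "M": ("A", "C"),
}


class HapmapParseError(ValueError):
    """Malformed HapMap input; message names the offending line."""


def _decode_call(token: str, a: str, b: str, path, lineno: int) -> int:
    t = token.strip().upper()
    if t in ("NN", "N", "", "--", "-"):
        return MISSING
    if len(t) == 1:
        if t in _IUPAC_HET:
            if {a, b} != set(_IUPAC_HET[t]):
                raise HapmapParseError(
                    f"{path}:{lineno}: het code {t} inconsistent with alleles {a}/{b}")
            return HET
        t = t + t  # single-letter homozygote
    if len(t) != 2:
        raise HapmapParseError(f"{path}:{lineno}: unparsable call {token!r}")
    alleles = set(t)
    if not alleles <= {a, b}:
        raise HapmapParseError(
            f"{path}:{lineno}: call {token!r} not biallelic for {a}/{b}")
    if t[0] != t[1]:
        return HET
    return HOM_A if t[0] == a else HOM_B


def read_hapmap(path, panel_id: str | None = None) -> GenotypePanel:
    """Read a tab-separated HapMap genotype file into a GenotypePanel.

    Expects the 11 standard metadata columns followed by one column per
    accession.  Diploid calls may be two-letter ("AA", "AG"), single
    IUPAC codes (het), or "NN"/"N" for missing.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 12:
            raise HapmapParseError(f"{path}:1: fewer than 12 columns in header")
        accession_ids = header[11:]
        n_acc = len(accession_ids)
        rows, calls, seen = [], [], set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 11 + n_acc:
                raise HapmapParseError(
                    f"{path}:{lineno}: expected {11 + n_acc} columns, got {len(fields)}")
            snp_id, alleles = fields[0], fields[1]
            if snp_id in seen:
                raise HapmapParseError(f"{path}:{lineno}: duplicate snp_id {snp_id!r}")
            seen.add(snp_id)
            try:
                a, b = alleles.split("/")
            except ValueError:
                raise HapmapParseError(
                    f"{path}:{lineno}: alleles field {alleles!r} not 'A/B'") from None
            if a == b or len(a) != 1 or len(b) != 1:
                raise HapmapParseError(
                    f"{path}:{lineno}: site not biallelic ({alleles!r})")
            rows.append((snp_id, int(fields[2]), int(fields[3]), a, b))
            calls.append([_decode_call(t, a, b, path, lineno) for t in fields[11:]])
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "allele_a", "allele_b"])
    order = np.lexsort((snps["pos"], snps["chrom"]))
    snps = snps.iloc[order].reset_index(drop=True)
    mat = np.asarray(calls, dtype=np.int8).T[:, order] if calls else \
        np.zeros((len(accession_ids), 0), dtype=np.int8)
    return GenotypePanel(panel_id or str(path), list(accession_ids), snps, mat)


def write_hapmap(panel: GenotypePanel, path) -> None:
    """Write a panel as tab-separated HapMap text (two-letter calls, NN missing)."""
    with open(path, "w") as fh:
        fh.write("\t".join(HAPMAP_HEADER + list(panel.accession_ids)) + "\n")
        for j, snp in panel.snps.iterrows():
            a, b = snp["allele_a"], snp["allele_b"]
            codes = {HOM_A: a + a, HET: a + b, HOM_B: b + b, MISSING: "NN"}
            meta = [str(snp["snp_id"]), f"{a}/{b}", str(int(snp["chrom"])),
                    str(int(snp["pos"])), "+", "NA", "NA", "NA", "NA", "NA", "NA"]
            fh.write("\t".join(meta + [codes[int(c)] for c in panel.calls[:, j]]) + "\n")


# -- QC filters --------------------------------------------------------

def hets_to_missing(panel: GenotypePanel) -> GenotypePanel:
    """Replace every heterozygous call with missing; homozygotes untouched."""
    out = panel.copy()
    out.calls[out.calls == HET] = MISSING
    return out


def filter_missingness(panel: GenotypePanel, max_missing: float = 0.10) -> GenotypePanel:
    """Drop SNPs whose missing fraction strictly exceeds ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must lie in [0, 1]")
    frac = (panel.calls == MISSING).mean(axis=0)
    keep = frac <= max_missing
    removed = int((~keep).sum())
    if removed:
        log.info("%s: removed %d SNPs with missingness > %.2f",
                 panel.panel_id, removed, max_missing)
    return panel.take_snps(keep)


def _fixed_allele(calls: np.ndarray) -> int | None:
    """Code of the single allele a SNP is fixed for, or None if polymorphic."""
    obs = calls[calls != MISSING]
    if obs.size == 0:
        return None
    if (obs == HOM_A).all():
        return HOM_A
    if (obs == HOM_B).all():
        return HOM_B
    return None  # het present or both homozygotes observed


def filter_monomorphic(panels: list[GenotypePanel],
                       scope: str = "across-all") -> list[GenotypePanel]:
    """Remove monomorphic SNPs.

    ``across-all``: drop SNPs fixed for the *same* allele in every panel
    (a SNP fixed A in one panel and B in another is jointly polymorphic
    and kept).  Requires all panels to share one SNP ordering.
    ``per-panel``: drop, within each panel independently, SNPs with only
    one observed allele.
    """
    if scope == "per-panel":
        out = []
        for p in panels:
            keep = np.array([_fixed_allele(p.calls[:, j]) is None
                             for j in range(p.n_snps)])
            q = p.take_snps(keep)
            if q.n_snps == 0:
                warnings.warn(f"{p.panel_id}: no polymorphic SNPs remain")
            out.append(q)
        return out
    if scope != "across-all":
        raise ValueError(f"unknown scope {scope!r}")
    ids0 = list(panels[0].snps["snp_id"])
    for p in panels[1:]:
        if list(p.snps["snp_id"]) != ids0:
            raise ValueError("across-all scope requires identical SNP ordering")
    m = panels[0].n_snps
    drop = np.zeros(m, dtype=bool)
    for j in range(m):
        fixed = {_fixed_allele(p.calls[:, j]) for p in panels}
        drop[j] = len(fixed) == 1 and None not in fixed
    out = [p.take_snps(~drop) for p in panels]
    if out and out[0].n_snps == 0:
        warnings.warn("no SNPs remain after monomorphic filter")
    return out


def intersect_snps(panels: list[GenotypePanel]) -> list[GenotypePanel]:
    """Restrict all panels to their common SNP ids (identical ordering)."""
    if len(panels) < 2:
        raise ValueError("need at least two panels to intersect")
    common = set(panels[0].snps["snp_id"])
    for p in panels[1:]:
        common &= set(p.snps["snp_id"])
    if not common:
        raise ValueError("empty SNP intersection across panels")
    return [p.restrict_to(common) for p in panels]


# -- imputation --------------------------------------------------------

def _r2_with_target(dose: np.ndarray, j: int, cand: np.ndarray) -> np.ndarray:
    """r^2 of each candidate SNP with SNP j over complete pairs (NaN-aware)."""
    x = dose[:, j]
    out = np.full(cand.size, np.nan)
    for idx, c in enumerate(cand):
        y = dose[:, c]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 2:
            continue
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            continue
        out[idx] = np.corrcoef(xs, ys)[0, 1] ** 2
    return out


def impute_ld_knn(panel: GenotypePanel, n_ld_snps: int = 30, k: int = 10,
                  max_dist_bp: float = 1e7) -> GenotypePanel:
    """LD-kNN genotype imputation.

    For each missing call at SNP j: rank other SNPs within
    ``max_dist_bp`` on the same chromosome by LD r^2 with j, keep the
    top ``n_ld_snps``, find the ``k`` accessions (with an observed call
    at j) having the fewest genotype mismatches to the focal accession
    over those SNPs, and impute the majority genotype among them.
    Majority ties fall back to the panel-wide major genotype at j;
    neighbour ties break by accession input order.  Observed calls are
    never altered.
    """
    if panel.n_accessions < k + 1:
        raise ValueError(f"need at least {k + 1} accessions for k={k}")
    out = panel.copy()
    dose = panel.dose_b()
    chrom = panel.snps["chrom"].to_numpy()
    pos = panel.snps["pos"].to_numpy()
    for j in np.flatnonzero((panel.calls == MISSING).any(axis=0)):
        observed = panel.calls[:, j] != MISSING
        if not observed.any():
            warnings.warn(
                f"{panel.snps['snp_id'].iloc[j]}: no observed calls, left missing")
            continue
        cand = np.flatnonzero(
            (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= max_dist_bp))
        cand = cand[cand != j]
        r2 = _r2_with_target(dose, j, cand)
        keep = ~np.isnan(r2)
        cand, r2 = cand[keep], r2[keep]
        ld_set = cand[np.argsort(-r2, kind="stable")[:n_ld_snps]]
        # majority fallback: most common observed genotype at j
        vals, counts = np.unique(panel.calls[observed, j], return_counts=True)
        panel_major = int(vals[np.argmax(counts)])
        donors = np.flatnonzero(observed)
        for a in np.flatnonzero(panel.calls[:, j] == MISSING):
            if ld_set.size == 0:
                out.calls[a, j] = panel_major
                continue
            fa = panel.calls[a][ld_set]
            fd = panel.calls[donors][:, ld_set]
            comparable = (fa != MISSING) & (fd != MISSING)
            mism = ((fd != fa) & comparable).sum(axis=1)
            nn = donors[np.argsort(mism, kind="stable")[:k]]
            g, c = np.unique(panel.calls[nn, j], return_counts=True)
            best = c == c.max()
            out.calls[a, j] = int(g[best][0]) if best.sum() == 1 else panel_major
    return out


def impute_trait_knn(traits: list[TraitRecord], panel: GenotypePanel,
                     k: int = 5) -> list[TraitRecord]:
    """Fill missing ratings with the mean of the k nearest accessions.

    Distance is Euclidean on the numeric genotype coding (allele-B dose);
    genotype NaNs are mean-filled per SNP for the distance computation.
    Observed ratings are never altered.
    """
    if len(traits) != panel.n_accessions:
        raise ValueError("traits must align with panel accessions")
    ratings = np.array([t.rating for t in traits], dtype=float)
    complete = ~np.isnan(ratings)
    if complete.sum() < k:
        raise ValueError(f"fewer than k={k} accessions with observed traits")
    if complete.all():
        return [TraitRecord(t.accession_id, t.rating, t.open_pod_fraction,
                            t.transformed) for t in traits]
    dose = panel.dose_b()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(dose, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    dose = np.where(np.isnan(dose), col_mean, dose)
    donors = np.flatnonzero(complete)
    out = []
    for i, t in enumerate(traits):
        if complete[i]:
            out.append(TraitRecord(t.accession_id, t.rating,
                                   t.open_pod_fraction, t.transformed))
            continue
        d = np.linalg.norm(dose[donors] - dose[i], axis=1)
        nn = donors[np.argsort(d, kind="stable")[:k]]
        out.append(TraitRecord(t.accession_id, float(ratings[nn].mean())))
    return out
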