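"""Marker-assisted selection and gBLUP genomic selection.

MAS side: at each QTL SNP the *favorable* allele is the one carried by
the homozygote group with the lower mean dehiscence rating.  Per rating
group j (1..5) the percentage of accessions carrying the favorable
allele is tabulated; the two printed selection-efficiency statistics
average favorable-allele enrichment in the most-resistant group (rating
1) and unfavorable-allele enrichment in the most-susceptible group (the
largest observed rating).  Accessions are ranked by how many favorable
alleles they stack.

GS side: gBLUP fits y = 1 mu + u + e with u ~ (0, K sigma_u^2) for a
genomic kinship K, by REML through the eigendecomposition of K.  It
returns genomic breeding values (BLUPs of u), their prediction error
variances, and K-fold cross-validated prediction accuracy, where fold
membership is redrawn per repetition (bootstrap assignment by default,
classical partitioning behind ``mode="partition"``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .panel import GenotypePanel, HET, HOM_A, HOM_B, MISSING
from .gwas import KinshipMatrix

__all__ = [
    "FavorableAlleleTable", "GsFit",
    "favorable_alleles", "group_percentages", "panel_selection_efficiency",
    "snp_selection_efficiency", "rank_haplotypes",
    "gblup_fit", "kfold_cv", "prediction_r",
]

log = logging.getLogger(__name__)


# -- marker-assisted selection ----------------------------------------------

@dataclass
class FavorableAlleleTable:
    """Favorable/unfavorable allele per QTL SNP plus carrier matrix."""

    panel_id: str
    snp_ids: list[str]
    favorable_allele: list[str]
    unfavorable_allele: list[str]
    #: accession x QTL boolean matrix: carries >= 1 favorable allele
    carriers: np.ndarray = field(repr=False)
    accession_ids: list[str] = field(default_factory=list)


def _rating_groups(trait) -> np.ndarray:
    """Bin (possibly averaged) ratings to integer groups 1..5."""
    r = np.asarray(trait, dtype=float)
    return np.clip(np.rint(r), 1, 5).astype(int)


def favorable_alleles(trait, panel: GenotypePanel,
                      qtl_snp_ids: list[str]) -> FavorableAlleleTable:
    """Determine the favorable allele at each QTL SNP.

    Accessions are split by homozygous genotype; the allele of the
    lower-mean-rating group is favorable.  Equal group means break
    toward the major allele.  A SNP with only one homozygote class is
    an error.
    """
    ratings = np.asarray(trait, dtype=float)
    if ratings.size != panel.n_accessions:
        raise ValueError("trait length does not match panel")
    sub = panel.restrict_to(qtl_snp_ids)
    present = set(sub.snps["snp_id"])
    absent = [s for s in qtl_snp_ids if s not in present]
    if absent:
        raise ValueError(f"QTL SNPs not in panel: {absent}")
    fav, unfav, carrier_cols, kept_ids = [], [], [], []
    for j, snp in sub.snps.iterrows():
        col = sub.calls[:, j]
        is_a, is_b = col == HOM_A, col == HOM_B
        if not is_a.any() or not is_b.any():
            raise ValueError(f"SNP {snp['snp_id']} is monomorphic in {panel.panel_id}")
        mean_a = ratings[is_a].mean()
        mean_b = ratings[is_b].mean()
        if math.isclose(mean_a, mean_b):
            fav_is_a = is_a.sum() >= is_b.sum()  # tie -> major allele
        else:
            fav_is_a = mean_a < mean_b
        a, b = snp["allele_a"], snp["allele_b"]
        fav.append(a if fav_is_a else b)
        unfav.append(b if fav_is_a else a)
        fav_hom = HOM_A if fav_is_a else HOM_B
        carrier_cols.append((col == fav_hom) | (col == HET))
        kept_ids.append(snp["snp_id"])
    return FavorableAlleleTable(
        panel_id=panel.panel_id, snp_ids=kept_ids,
        favorable_allele=fav, unfavorable_allele=unfav,
        carriers=np.column_stack(carrier_cols),
        accession_ids=list(panel.accession_ids))


def group_percentages(table: FavorableAlleleTable, trait) -> pd.DataFrame:
    """Percentage of favorable-allele carriers per SNP x rating group.

    Rows are QTL SNPs, columns the integer rating groups 1..5; empty
    groups are NaN (undefined).
    """
    groups = _rating_groups(trait)
    out = pd.DataFrame(index=pd.Index(table.snp_ids, name="snp_id"),
                       columns=range(1, 6), dtype=float)
    for j in range(1, 6):
        in_group = groups == j
        if not in_group.any():
            continue
        out[j] = table.carriers[in_group].mean(axis=0) * 100.0
    return out


def _extreme_groups(pct: pd.DataFrame, low: int, high: int | None) -> tuple[int, int]:
    observed = [j for j in pct.columns if pct[j].notna().any()]
    if high is None:
        high = max(observed)
    if pct[low].isna().all():
        raise ValueError(f"extreme group {low} is empty")
    if pct[high].isna().all():
        raise ValueError(f"extreme group {high} is empty")
    return low, high


def panel_selection_efficiency(pct: pd.DataFrame, low: int = 1,
                               high: int | None = None) -> float:
    """Panel-level selection efficiency over all QTL SNPs.

    (average % favorable alleles in the rating-``low`` group + average %
    unfavorable alleles in the rating-``high`` group) / 2 / 100.  ``high``
    defaults to the largest observed rating group.
    """
    low, high = _extreme_groups(pct, low, high)
    return float((pct[low].mean() + (100.0 - pct[high]).mean()) / 2.0 / 100.0)


def snp_selection_efficiency(snp_id: str, pct: pd.DataFrame, low: int = 1,
                             high: int | None = None) -> float:
    """Single-SNP selection efficiency (same statistic restricted to one SNP)."""
    low, high = _extreme_groups(pct, low, high)
    row = pct.loc[snp_id]
    return float((row[low] + (100.0 - row[high])) / 2.0 / 100.0)


def rank_haplotypes(table: FavorableAlleleTable, trait) -> pd.DataFrame:
    """Accessions ranked by the number of favorable alleles carried.

    Returns accession_id, n_favorable, percent (of the QTL set) and the
    accession's rating, sorted by descending count with ties broken by
    accession id.
    """
    counts = table.carriers.sum(axis=1)
    n_qtl = len(table.snp_ids)
    df = pd.DataFrame({
        "accession_id": table.accession_ids,
        "n_favorable": counts,
        "percent": counts / n_qtl * 100.0,
        "rating": np.asarray(trait, dtype=float),
    })
    return df.sort_values(["n_favorable", "accession_id"],
                          ascending=[False, True]).reset_index(drop=True)


# -- gBLUP -------------------------------------------------------------------

@dataclass
class GsFit:
    """gBLUP fit: variance components, breeding values, error variances."""

    accession_ids: list[str]
    sigma_u2: float
    sigma_e2: float
    gbv: np.ndarray = field(repr=False)
    pev: np.ndarray = field(repr=False)
    heritability: float = 0.0


def _reml_kinship(y: np.ndarray, k: np.ndarray) -> tuple[float, float]:
    """REML variance components for y = 1 mu + u + e, u ~ (0, K sigma_u2)."""
    n = y.size
    eigvals, u = np.linalg.eigh(k)
    eigvals = np.maximum(eigvals, 0.0)
    ys = u.T @ y
    xs = u.T @ np.ones((n, 1))

    def neg_reml(log_lam: float) -> float:
        lam = 10.0 ** log_lam
        w = lam * eigvals + 1.0
        xtwx = float((xs[:, 0] ** 2 / w).sum())
        beta = float((xs[:, 0] * ys / w).sum()) / xtwx
        r = ys - xs[:, 0] * beta
        sig2 = max(float((r * r / w).sum()) / (n - 1), 1e-300)
        return 0.5 * ((n - 1) * math.log(sig2) + np.log(w).sum() + math.log(xtwx))

    res = optimize.minimize_scalar(neg_reml, bounds=(-6.0, 6.0), method="bounded")
    lam = 10.0 ** res.x
    w = lam * eigvals + 1.0
    xtwx = float((xs[:, 0] ** 2 / w).sum())
    beta = float((xs[:, 0] * ys / w).sum()) / xtwx
    r = ys - xs[:, 0] * beta
    sigma_e2 = float((r * r / w).sum()) / (n - 1)
    return lam * sigma_e2, sigma_e2


def _projection(k: np.ndarray, sigma_u2: float, sigma_e2: float) -> np.ndarray:
    """P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1 with X the intercept."""
    n = k.shape[0]
    v = sigma_u2 * k + sigma_e2 * np.eye(n)
    vinv = np.linalg.inv(v)
    x = np.ones((n, 1))
    vx = vinv @ x
    return vinv - vx @ vx.T / (x.T @ vx).item()


def gblup_fit(trait, kinship_matrix: KinshipMatrix) -> GsFit:
    """Fit the gBLUP mixed model and return GBV and PEV per accession.

    GBV = sigma_u^2 K P y (the BLUP of u); PEV is the diagonal of
    sigma_u^2 K - sigma_u^2 K P K sigma_u^2, the conditional variance of
    u given the data at the REML optimum.
    """
    y = np.asarray(trait, dtype=float)
    k = kinship_matrix.values
    if y.size != k.shape[0]:
        raise ValueError("trait length does not match kinship")
    eig_min = np.linalg.eigvalsh(k).min()
    if eig_min < -1e-8 * max(1.0, float(np.abs(k).max())):
        raise ValueError(f"kinship not PSD (smallest eigenvalue {eig_min:.3e})")
    if y.var() == 0:
        return GsFit(list(kinship_matrix.accession_ids), 0.0, 0.0,
                     np.zeros(y.size), np.zeros(y.size), 0.0)
    sigma_u2, sigma_e2 = _reml_kinship(y, k)
    p = _projection(k, sigma_u2, sigma_e2)
    gbv = sigma_u2 * (k @ (p @ y))
    ku = sigma_u2 * k
    pev = np.maximum(np.diag(ku) - np.einsum("ij,jk,ki->i", ku, p, ku), 0.0)
    h2 = sigma_u2 / (sigma_u2 + sigma_e2) if sigma_u2 + sigma_e2 > 0 else 0.0
    return GsFit(list(kinship_matrix.accession_ids), sigma_u2, sigma_e2,
                 gbv, pev, h2)


def prediction_r(trait, gbv) -> float:
    """Pearson correlation between observed trait and predicted values."""
    y = np.asarray(trait, dtype=float)
    g = np.asarray(gbv, dtype=float)
    if y.size != g.size:
        raise ValueError("length mismatch")
    if y.std() == 0 or g.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(y, g)[0, 1])


def kfold_cv(trait, kinship_matrix: KinshipMatrix,
             folds: tuple[int, ...] = (2, 5, 10, 20), reps: int = 100,
             mode: str = "bootstrap", seed: int | None = 0,
             min_holdout: int = 3) -> dict[int, float]:
    """K-fold cross-validated genomic prediction accuracy.

    Per repetition, accessions are (re)assigned to folds — by default
    each accession's fold label is drawn independently at random
    (assignment with replacement), ``mode="partition"`` gives a classical
    random equal split.  Each fold is held out in turn: its trait values
    are masked and its GBVs predicted from the training accessions via
    the kinship-partitioned mixed model; accuracy r is the Pearson
    correlation of observed vs predicted in the held-out set.  Variance
    components are estimated once on the full data and reused across
    folds.  Repetitions producing a fold with fewer than ``min_holdout``
    held-out accessions (or a constant held-out trait) are redrawn.

    Returns the mean r per fold count.
    """
    y = np.asarray(trait, dtype=float)
    k = kinship_matrix.values
    n = y.size
    rng = np.random.default_rng(seed)
    sigma_u2, sigma_e2 = _reml_kinship(y, k)
    if sigma_e2 <= 0:
        sigma_e2 = max(sigma_e2, 1e-8 * max(y.var(), 1.0))
    out: dict[int, float] = {}
    for n_folds in folds:
        if n_folds < 2 or n_folds > n // min_holdout:
            raise ValueError(f"fold count {n_folds} infeasible for n={n}")
        rs: list[float] = []
        done = 0
        attempts = 0
        while done < reps:
            attempts += 1
            if attempts > 50 * reps:
                raise RuntimeError("could not draw valid fold assignments")
            if mode == "bootstrap":
                labels = rng.integers(0, n_folds, size=n)
            elif mode == "partition":
                labels = np.repeat(np.arange(n_folds), -(-n // n_folds))[:n]
                rng.shuffle(labels)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            sizes = np.bincount(labels, minlength=n_folds)
            if sizes.min() < min_holdout:
                log.debug("fold with <%d accessions; repetition redrawn", min_holdout)
                continue
            rep_rs = []
            ok = True
            for f in range(n_folds):
                test = labels == f
                train = ~test
                y_tr = y[train]
                if y_tr.std() == 0 or y[test].std() == 0:
                    ok = False
                    break
                v_tr = sigma_u2 * k[np.ix_(train, train)] \
                    + sigma_e2 * np.eye(int(train.sum()))
                vinv_r = np.linalg.solve(v_tr, y_tr - y_tr.mean())
                pred = sigma_u2 * k[np.ix_(test, train)] @ vinv_r
                if pred.std() == 0:
                    ok = False
                    break
                rep_rs.append(float(np.corrcoef(y[test], pred)[0, 1]))
            if not ok:
                log.debug("degenerate fold; repetition redrawn")
                continue
            rs.extend(rep_rs)
            done += 1
        out[n_folds] = float(np.mean(rs))
    return out
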