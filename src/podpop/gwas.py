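"""Single-marker association scans, support intervals and colocalization.

Two scan models are provided over the 0/2 major-allele dose coding:

* ``glm_scan`` — ordinary least squares of the (transformed) trait on
  each SNP dose plus optional covariates (e.g. principal components),
  with a two-sided t-test on the dose coefficient;
* ``mlm_scan`` — a kinship mixed model.  Variance components are
  estimated once by REML on the null (no-SNP) model through an
  eigendecomposition of the kinship matrix, then every SNP is tested by
  generalized least squares in the rotated space (the
  population-parameters-previously-determined shortcut).

Significance is declared on Benjamini-Hochberg q-values; p-values
convert to LOD scores as log10(1/p).  QTL support intervals come either
from the 1.5-LOD drop around a peak or, for literature RIL populations,
from the 163/(N R^2) centimorgan rule, with a linear 5 cM = 2.2 Mb
conversion between genetic and physical coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import GenotypePanel, MISSING
from .popgen import bh_adjust

__all__ = [
    "KinshipMatrix", "ScanResult", "SupportInterval", "QtlCall",
    "maf_filter", "kinship", "select_pcs_bic", "glm_scan", "mlm_scan",
    "pvalue_to_lod", "support_interval_1p5lod", "ril_ci",
    "cm_to_mb", "mb_to_cm", "colocalize", "link_prior_qtls", "confirmed_qtls",
    "genomic_inflation",
]

#: linear genetic/physical ratio: 5 cM on the consensus map = 2.2 Mb
MB_PER_CM = 0.44


# -- types ----------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Accession x accession relatedness matrix with a method tag."""

    accession_ids: list[str]
    values: np.ndarray = field(repr=False)
    method: str = "marker-vanraden"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if v.shape != (n, n):
            raise ValueError("kinship shape does not match accession count")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        self.values = (v + v.T) / 2.0


@dataclass
class ScanResult:
    """Per-SNP association results for one panel and model."""

    panel_id: str
    model: str                      # "glm" | "mlm"
    n_pcs: int
    table: pd.DataFrame = field(repr=False)  # snp_id chrom pos effect p q lod
    sigma_g2: float | None = None
    sigma_e2: float | None = None

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q_value"] < q_threshold]


@dataclass
class SupportInterval:
    """QTL confidence interval in physical and genetic coordinates."""

    peak_snp_id: str
    chrom: int
    bp_lower: int
    bp_upper: int
    cm_lower: float
    cm_upper: float
    method: str  # "lod-1.5" | "ril-formula"

    def __post_init__(self) -> None:
        if self.bp_lower > self.bp_upper:
            raise ValueError("interval bounds out of order")


@dataclass
class QtlCall:
    """A candidate QTL SNP with its cross-panel and literature evidence."""

    snp_id: str
    chrom: int
    pos: int
    panels_significant: list[str]
    colocalized: bool
    prior_links: list[tuple[str, int]] = field(default_factory=list)
    domestication_overlap: bool = False


# -- marker QC -------------------------------------------------------------

def maf_filter(panel: GenotypePanel, min_maf: float = 0.05) -> GenotypePanel:
    """Keep polymorphic SNPs with minor-allele frequency >= ``min_maf``."""
    from .popgen import allele_frequencies
    p = allele_frequencies(panel)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    keep = ~np.isnan(maf) & (maf >= min_maf) & (maf > 0)
    return panel.take_snps(keep)


# -- kinship ----------------------------------------------------------------

def kinship(panel: GenotypePanel, method: str = "marker-vanraden") -> KinshipMatrix:
    """Relatedness matrix from an imputed panel.

    ``ibs-proportion``: fraction of shared genotype states per accession
    pair, rescaled as max(0, 2 (IBS - 0.5)).
    ``marker-vanraden``: centered-dose cross-product Z Z' / (2 sum p(1-p))
    on the 0/2 major-allele dose coding, p the major-allele frequency.
    """
    if (panel.calls == MISSING).any():
        raise ValueError("kinship requires a fully imputed panel")
    if method == "ibs-proportion":
        c = panel.calls
        n = panel.n_accessions
        ibs = np.empty((n, n))
        for i in range(n):
            ibs[i] = (c == c[i]).mean(axis=1)
        k = np.maximum(0.0, 2.0 * (ibs - 0.5))
    elif method == "marker-vanraden":
        dose = panel.dose_major()
        p = dose.mean(axis=0) / 2.0
        var = 2.0 * (p * (1.0 - p)).sum()
        if var <= 0:
            raise ValueError("no polymorphic SNPs for VanRaden kinship")
        z = dose - 2.0 * p
        k = z @ z.T / var
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    return KinshipMatrix(list(panel.accession_ids), k, method)


# -- covariate selection -----------------------------------------------------

def select_pcs_bic(trait, pcs: np.ndarray, max_pcs: int) -> int:
    """Forward BIC selection of the number of PC covariates.

    Fits trait ~ intercept + PC1..j for j = 0, 1, ..., adding the next
    PC while the Bayesian information criterion improves; returns the
    BIC-minimizing j.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    max_pcs = min(max_pcs, pcs.shape[1] if pcs.ndim == 2 else 0)

    def bic(j: int) -> float:
        x = np.column_stack([np.ones(n), pcs[:, :j]]) if j else np.ones((n, 1))
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss = float(((y - x @ beta) ** 2).sum())
        kparams = x.shape[1] + 1  # + residual variance
        return n * math.log(max(rss, 1e-300) / n) + kparams * math.log(n)

    best_j, best = 0, bic(0)
    for j in range(1, max_pcs + 1):
        b = bic(j)
        if b < best:
            best_j, best = j, b
        else:
            break
    return best_j


# -- scans -------------------------------------------------------------------

def _design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != n:
        c = c.T
    return np.column_stack([np.ones(n), c])


def _scan_table(panel: GenotypePanel, effect, pval) -> pd.DataFrame:
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    return pd.DataFrame({
        "snp_id": panel.snps["snp_id"],
        "chrom": panel.snps["chrom"],
        "pos": panel.snps["pos"],
        "effect": effect,
        "p_value": pval,
        "q_value": bh_adjust(pval),
        "lod": -np.log10(pval),
    })


def glm_scan(trait, panel: GenotypePanel, covariates=None,
             n_pcs: int = 0) -> ScanResult:
    """Per-SNP least squares of the trait on 0/2 dose plus covariates.

    Two-sided t-test on the dose coefficient; collinear SNPs get p = 1
    with a warning.  ``n_pcs`` only labels how many of the covariate
    columns are principal components.
    """
    y = np.asarray(trait, dtype=float)
    if y.size != panel.n_accessions:
        raise ValueError("trait length does not match panel")
    if y.std() == 0:
        raise ValueError("constant trait: association scan undefined")
    g = panel.dose_major()
    if np.isnan(g).any():
        raise ValueError("missing genotypes present: impute before scanning")
    x0 = _design(y.size, covariates)
    q, _ = np.linalg.qr(x0)
    yr = y - q @ (q.T @ y)
    gr = g - q @ (q.T @ g)
    gg = (gr * gr).sum(axis=0)
    collinear = gg < 1e-12
    if collinear.any():
        warnings.warn(f"{int(collinear.sum())} SNPs collinear with covariates; p=1")
    gg_safe = np.where(collinear, 1.0, gg)
    beta = gr.T @ yr / gg_safe
    dfree = y.size - x0.shape[1] - 1
    rss = (yr * yr).sum() - beta**2 * gg_safe
    sigma2 = np.maximum(rss, 0.0) / dfree
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / np.sqrt(sigma2 / gg_safe)
    pval = 2.0 * stats.t.sf(np.abs(tstat), dfree)
    pval = np.where(collinear, 1.0, pval)
    beta = np.where(collinear, 0.0, beta)
    return ScanResult(panel.panel_id, "glm", n_pcs, _scan_table(panel, beta, pval))


def _reml_null(y: np.ndarray, x0: np.ndarray, eigvals: np.ndarray,
               u: np.ndarray) -> tuple[float, float]:
    """REML variance components (sigma_g2, sigma_e2) for y = X0 b + u + e."""
    n, p = x0.shape
    ys = u.T @ y
    xs = u.T @ x0

    def neg_reml(log_lam: float) -> float:
        lam = 10.0 ** log_lam
        w = lam * eigvals + 1.0
        xtwx = xs.T @ (xs / w[:, None])
        xtwy = xs.T @ (ys / w)
        beta = np.linalg.solve(xtwx, xtwy)
        r = ys - xs @ beta
        rss = float((r * r / w).sum())
        sig2 = rss / (n - p)
        _, logdet_xtwx = np.linalg.slogdet(xtwx)
        ll = -0.5 * ((n - p) * math.log(sig2) + np.log(w).sum() + logdet_xtwx)
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=(-6.0, 6.0), method="bounded")
    lam = 10.0 ** res.x
    w = lam * eigvals + 1.0
    xtwx = xs.T @ (xs / w[:, None])
    beta = np.linalg.solve(xtwx, xs.T @ (ys / w))
    r = ys - xs @ beta
    sigma_e2 = float((r * r / w).sum()) / (n - p)
    return lam * sigma_e2, sigma_e2


def mlm_scan(trait, panel: GenotypePanel, covariates=None,
             kinship_matrix: KinshipMatrix | None = None,
             n_pcs: int = 0) -> ScanResult:
    """Kinship mixed-model scan.

    Null-model REML fixes the variance components; each SNP is then
    tested by weighted least squares in the kinship eigenspace with a
    t reference distribution, so that kinship = identity reproduces the
    GLM scan exactly.
    """
    if kinship_matrix is None:
        raise ValueError("mlm_scan requires a kinship matrix")
    y = np.asarray(trait, dtype=float)
    if y.std() == 0:
        raise ValueError("constant trait: association scan undefined")
    k = kinship_matrix.values
    eigvals, u = np.linalg.eigh(k)
    if eigvals.min() < -1e-8 * max(1.0, abs(eigvals).max()):
        raise ValueError(
            f"kinship not positive semidefinite (smallest eigenvalue "
            f"{eigvals.min():.3e})")
    eigvals = np.maximum(eigvals, 0.0)
    x0 = _design(y.size, covariates)
    sigma_g2, sigma_e2 = _reml_null(y, x0, eigvals, u)
    lam = sigma_g2 / sigma_e2 if sigma_e2 > 0 else 1e6
    w = lam * eigvals + 1.0
    sw = 1.0 / np.sqrt(w)

    g = panel.dose_major()
    if np.isnan(g).any():
        raise ValueError("missing genotypes present: impute before scanning")
    # whiten: multiply rotated data by 1/sqrt(w), then run OLS machinery
    yt = (u.T @ y) * sw
    x0t = (u.T @ x0) * sw[:, None]
    gt = (u.T @ g) * sw[:, None]
    q, _ = np.linalg.qr(x0t)
    yr = yt - q @ (q.T @ yt)
    gr = gt - q @ (q.T @ gt)
    gg = (gr * gr).sum(axis=0)
    collinear = gg < 1e-12
    if collinear.any():
        warnings.warn(f"{int(collinear.sum())} SNPs collinear with covariates; p=1")
    gg_safe = np.where(collinear, 1.0, gg)
    beta = gr.T @ yr / gg_safe
    dfree = y.size - x0.shape[1] - 1
    rss = (yr * yr).sum() - beta**2 * gg_safe
    sigma2 = np.maximum(rss, 0.0) / dfree
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / np.sqrt(sigma2 / gg_safe)
    pval = 2.0 * stats.t.sf(np.abs(tstat), dfree)
    pval = np.where(collinear, 1.0, pval)
    beta = np.where(collinear, 0.0, beta)
    return ScanResult(panel.panel_id, "mlm", n_pcs, _scan_table(panel, beta, pval),
                      sigma_g2=sigma_g2, sigma_e2=sigma_e2)


def genomic_inflation(scan: ScanResult) -> float:
    """Genomic-inflation factor: median chi-square over its null median 0.456."""
    chi2 = stats.chi2.isf(scan.table["p_value"].to_numpy(), df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# -- LOD, intervals and conversions ------------------------------------------

def pvalue_to_lod(p):
    """LOD score = log10(1/p)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("p must lie in (0, 1]")
    out = -np.log10(p_arr)
    return float(out) if out.ndim == 0 else out


def cm_to_mb(cm, mb_per_cm: float = MB_PER_CM):
    """Genetic to physical distance at the consensus-map linear ratio."""
    c = np.asarray(cm, dtype=float)
    if np.any(c < 0):
        raise ValueError("distance must be nonnegative")
    out = c * mb_per_cm
    return float(out) if out.ndim == 0 else out


def mb_to_cm(mb, mb_per_cm: float = MB_PER_CM):
    """Physical to genetic distance at the consensus-map linear ratio."""
    m = np.asarray(mb, dtype=float)
    if np.any(m < 0):
        raise ValueError("distance must be nonnegative")
    out = m / mb_per_cm
    return float(out) if out.ndim == 0 else out


def ril_ci(n_pop: int, r2: float) -> float:
    """95% CI width (cM) for a RIL-population QTL: 163 / (N R^2)."""
    if n_pop < 1:
        raise ValueError("population size must be >= 1")
    if not 0.0 < r2 <= 1.0:
        raise ValueError("R^2 must lie in (0, 1]")
    return 163.0 / (n_pop * r2)


def support_interval_1p5lod(scan: ScanResult, peak_snp_id: str,
                            drop: float = 1.5,
                            mb_per_cm: float = MB_PER_CM) -> SupportInterval:
    """1.5-LOD support interval around a peak SNP.

    The interval spans the contiguous run of SNPs around the peak whose
    LOD stays within ``drop`` of the peak LOD; physical bounds are the
    positions of the SNPs flanking that run (or the run edge at a
    chromosome end).  Genetic bounds use the linear cM/Mb ratio.
    """
    t = scan.table
    hit = t.index[t["snp_id"] == peak_snp_id]
    if len(hit) != 1:
        raise ValueError(f"peak SNP {peak_snp_id!r} not in scan")
    i = int(hit[0])
    chrom = int(t["chrom"].iloc[i])
    on_chr = t[t["chrom"] == chrom].reset_index()
    j = int(on_chr.index[on_chr["snp_id"] == peak_snp_id][0])
    lod = on_chr["lod"].to_numpy()
    if (j > 0 and lod[j - 1] > lod[j]) or (j < len(lod) - 1 and lod[j + 1] > lod[j]):
        raise ValueError(f"{peak_snp_id} is not a local LOD maximum on chr {chrom}")
    thr = lod[j] - drop
    lo = j
    while lo > 0 and lod[lo - 1] >= thr:
        lo -= 1
    hi = j
    while hi < len(lod) - 1 and lod[hi + 1] >= thr:
        hi += 1
    pos = on_chr["pos"].to_numpy()
    bp_lower = int(pos[lo - 1]) if lo > 0 else int(pos[lo])
    bp_upper = int(pos[hi + 1]) if hi < len(pos) - 1 else int(pos[hi])
    return SupportInterval(
        peak_snp_id=peak_snp_id, chrom=chrom,
        bp_lower=bp_lower, bp_upper=bp_upper,
        cm_lower=mb_to_cm(bp_lower / 1e6, mb_per_cm),
        cm_upper=mb_to_cm(bp_upper / 1e6, mb_per_cm),
        method="lod-1.5",
    )


# -- cross-panel calls ---------------------------------------------------------

def colocalize(scans: list[ScanResult], q_threshold: float = 0.05) -> list[QtlCall]:
    """QTL calls from per-panel significance.

    A SNP significant (q below threshold) in >= 2 panels is a colocalized
    call; SNPs significant in exactly one panel are returned with
    ``colocalized=False`` and await confirmation by a prior-QTL link.
    """
    ids0 = list(scans[0].table["snp_id"])
    for s in scans[1:]:
        if list(s.table["snp_id"]) != ids0:
            raise ValueError("scans must share an identical SNP set")
    meta = scans[0].table[["snp_id", "chrom", "pos"]]
    sig_panels: dict[str, list[str]] = {}
    for s in scans:
        for snp in s.significant(q_threshold)["snp_id"]:
            sig_panels.setdefault(snp, []).append(s.panel_id)
    calls = []
    for _, row in meta.iterrows():
        panels = sig_panels.get(row["snp_id"])
        if not panels:
            continue
        calls.append(QtlCall(
            snp_id=row["snp_id"], chrom=int(row["chrom"]), pos=int(row["pos"]),
            panels_significant=panels, colocalized=len(panels) >= 2))
    return calls


def link_prior_qtls(calls: list[QtlCall], prior: pd.DataFrame,
                    window_bp: float = 2.2e6) -> list[QtlCall]:
    """Attach same-chromosome prior QTLs within the tight-linkage window.

    ``prior`` needs columns name, chrom, pos_bp (extra columns such as N
    and R2 are ignored here).  Each matching prior QTL is attached with
    its signed distance (prior minus call position).  Entries without a
    position are skipped with a warning.
    """
    for c in calls:
        c.prior_links = []
        for _, row in prior.iterrows():
            if pd.isna(row.get("pos_bp")):
                warnings.warn(f"prior QTL {row.get('name')!r} has no position; skipped")
                continue
            if int(row["chrom"]) != c.chrom:
                continue
            dist = int(row["pos_bp"]) - c.pos
            if abs(dist) <= window_bp:
                c.prior_links.append((str(row["name"]), dist))
    return calls


def confirmed_qtls(calls: list[QtlCall]) -> list[QtlCall]:
    """Calls retained by the two-criterion rule: colocalized in >= 2
    panels, or single-panel but tightly linked to a prior QTL."""
    return [c for c in calls if c.colocalized or c.prior_links]
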