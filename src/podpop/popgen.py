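"""Population-genetic statistics and the domestication-SNP scan.

A domestication-related SNP is called by three joint criteria against
the wild panel:

1. the cultivated panel shows a genome-wide Tajima's |D| > 2 (excess of
   intermediate-frequency alleles, the footprint of a selected,
   ascertained SNP panel),
2. the wild-vs-cultivated allele-frequency difference is significant by
   a chi-square goodness-of-fit test on relative frequencies, with
   Benjamini-Hochberg q-values computed separately within each
   wild-cultivated pair, and
3. the pairwise F_ST at the SNP exceeds 0.05 (at least moderate
   differentiation).

F_ST here is the two-population frequency form s^2 / (T (1 - T)) with
the divisor-2 (population) variance, so complete fixation difference
gives F_ST = 1.  Diversity statistics treat accessions as inbred lines,
i.e. one sequence each.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel, HET, HOM_A, HOM_B, MISSING

__all__ = [
    "DiversityResult", "PcaResult", "DeltaKSeries",
    "allele_frequencies", "tajima_constants", "diversity_stats",
    "chisq_gof_divergence", "bh_adjust", "fst_pairwise",
    "divergence_table", "call_domestication_snps",
    "genotype_pca", "delta_k", "ld_r2_window",
]


# -- allele frequencies ------------------------------------------------

def allele_frequencies(panel: GenotypePanel) -> np.ndarray:
    """Per-SNP frequency of the reference allele (allele A).

    Computed over non-missing calls; heterozygotes contribute 0.5.
    Fully missing SNPs yield NaN with a warning.
    """
    c = panel.calls
    obs = (c != MISSING).sum(axis=0)
    score = (c == HOM_A).sum(axis=0) + 0.5 * (c == HET).sum(axis=0)
    if (obs == 0).any():
        bad = panel.snps["snp_id"][obs == 0].tolist()
        warnings.warn(f"SNPs with no observed calls: {bad[:5]}"
                      + ("..." if len(bad) > 5 else ""))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(obs > 0, score / obs, np.nan)


# -- diversity / Tajima's D --------------------------------------------

@dataclass
class DiversityResult:
    """Genome-wide diversity summary for one panel."""

    panel_id: str
    n: int                 # sample size (sequences = accessions)
    m: int                 # SNPs ascertained
    S: int                 # segregating SNPs
    pi_per_snp: float      # mean pairwise diversity per SNP
    theta_per_snp: float   # Watterson estimator per SNP
    tajima_d: float


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima's (1989) normalizing constants for sample size n."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def diversity_stats(panel: GenotypePanel) -> DiversityResult:
    """Nucleotide diversity, Watterson's theta and Tajima's D per panel.

    Accessions are treated as single sequences (inbred lines).  Per-SNP
    pairwise diversity is 2p(1-p) * n/(n-1); Watterson's estimator uses
    the segregating-SNP count S; D normalizes their genome-wide totals
    with the standard constants.  Both pi and theta are also reported as
    per-SNP averages over the m ascertained SNPs.
    """
    n = panel.n_accessions
    if n < 4:
        raise ValueError("diversity_stats needs at least 4 accessions")
    p = allele_frequencies(panel)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    p = p[ok]
    seg = (p > 0) & (p < 1)
    S = int(seg.sum())
    if S == 0:
        raise ValueError(f"{panel.panel_id}: no segregating sites, D undefined")
    k = tajima_constants(n)
    pi_total = float((2.0 * p * (1.0 - p) * n / (n - 1)).sum())
    theta_total = S / k["a1"]
    denom = math.sqrt(k["e1"] * S + k["e2"] * S * (S - 1))
    d = (pi_total - theta_total) / denom
    return DiversityResult(panel.panel_id, n, m, S,
                           pi_total / m, theta_total / m, float(d))


# -- divergence tests ---------------------------------------------------

def chisq_gof_divergence(p_wild, p_max, n_wild=None, n_max=None,
                         use_counts: bool = False):
    """Goodness-of-fit chi-square for a wild-vs-cultivated frequency split.

    Default (``use_counts=False``): the relative-frequency form — cells
    are the two panels' reference-allele frequencies, the expected value
    their pooled mean (p_wild + p_max) / 2, chi2 = sum (obs - exp)^2/exp.
    This statistic is bounded (max 1 at complete fixation difference) and
    serves as a descriptive divergence index.

    ``use_counts=True``: the count-based contingency form actually
    computed by frequency-table software — observed allele counts per
    panel against expectations from the pooled frequency, which scales
    with sample size and yields calibrated p-values.  Requires the
    per-panel allele sample sizes ``n_wild``/``n_max``.

    p-values come from chi-square with df = 1; SNPs where the allele is
    absent (or fixed) in both panels get chi2 = 0, p = 1.  Returns
    (chi2, p_value) as scalars or arrays matching the input shape.
    """
    pw = np.asarray(p_wild, dtype=float)
    pm = np.asarray(p_max, dtype=float)
    e = (pw + pm) / 2.0
    if use_counts:
        if n_wild is None or n_max is None:
            raise ValueError("count-based test needs n_wild and n_max")
        nw = np.asarray(n_wild, dtype=float)
        nm = np.asarray(n_max, dtype=float)
        denom = e * (1.0 - e)
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = np.where(denom > 0,
                            (nw * (pw - e) ** 2 + nm * (pm - e) ** 2) / denom,
                            0.0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = np.where(e > 0, ((pw - e) ** 2 + (pm - e) ** 2) / e, 0.0)
    pval = stats.chi2.sf(chi2, df=1)
    pval = np.where(chi2 == 0, 1.0, pval)
    if np.isscalar(p_wild) and np.isscalar(p_max):
        return float(chi2), float(pval)
    return chi2, pval


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fst_pairwise(p_a, p_b):
    """Two-population F_ST: s^2 / (T (1 - T)).

    s^2 is the divisor-2 (population) variance of the two allele
    frequencies and T their mean, so F_ST(0, 1) = 1 and the statistic is
    symmetric and allele-label invariant.  Returns 0 where T is 0 or 1.
    """
    pa = np.asarray(p_a, dtype=float)
    pb = np.asarray(p_b, dtype=float)
    t = (pa + pb) / 2.0
    s2 = ((pa - t) ** 2 + (pb - t) ** 2) / 2.0
    denom = t * (1.0 - t)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom > 0, s2 / denom, 0.0)
    if np.isscalar(p_a) and np.isscalar(p_b):
        return float(fst)
    return fst


def divergence_table(wild: GenotypePanel, cultivated: list[GenotypePanel],
                     use_counts: bool = True) -> pd.DataFrame:
    """Per-SNP, per wild-cultivated pair divergence statistics.

    Returns a long DataFrame with columns snp_id, chrom, pos, pair
    (cultivated panel id), p_wild, p_max, expected, chi2, p_value,
    q_value, fst.  BH adjustment runs separately within each pair.

    By default the chi-square uses the count-based contingency form
    (sample sizes = non-missing accessions per SNP), which is the
    variant with calibrated p-values; set ``use_counts=False`` for the
    bounded relative-frequency index.
    """
    ids0 = list(wild.snps["snp_id"])
    for c in cultivated:
        if list(c.snps["snp_id"]) != ids0:
            raise ValueError("panels must share an identical SNP set (intersect first)")
    pw = allele_frequencies(wild)
    nw = (wild.calls != MISSING).sum(axis=0)
    frames = []
    for c in cultivated:
        pm = allele_frequencies(c)
        nm = (c.calls != MISSING).sum(axis=0)
        chi2, pval = chisq_gof_divergence(pw, pm, n_wild=nw, n_max=nm,
                                          use_counts=use_counts)
        frames.append(pd.DataFrame({
            "snp_id": wild.snps["snp_id"],
            "chrom": wild.snps["chrom"],
            "pos": wild.snps["pos"],
            "pair": c.panel_id,
            "p_wild": pw,
            "p_max": pm,
            "expected": (pw + pm) / 2.0,
            "chi2": chi2,
            "p_value": pval,
            "q_value": bh_adjust(pval),
            "fst": fst_pairwise(pw, pm),
        }))
    return pd.concat(frames, ignore_index=True)


def call_domestication_snps(diversity: dict[str, DiversityResult],
                            divergence: pd.DataFrame,
                            q_threshold: float = 0.05,
                            d_threshold: float = 2.0,
                            fst_threshold: float = 0.05) -> pd.Series:
    """Three-criterion domestication call per SNP.

    A SNP is flagged when, in at least one wild-cultivated pair, the
    q-value is below ``q_threshold`` AND that pair's F_ST is strictly
    above ``fst_threshold`` AND the cultivated panel of that pair has
    genome-wide |Tajima's D| strictly above ``d_threshold``.

    ``diversity`` maps cultivated panel_id -> DiversityResult and must
    cover every pair id in ``divergence``.
    """
    pairs = divergence["pair"].unique()
    missing = [p for p in pairs if p not in diversity]
    if missing:
        raise ValueError(f"diversity results missing for panels {missing}")
    div = divergence.copy()
    div["panel_d_ok"] = div["pair"].map(
        {p: abs(diversity[p].tajima_d) > d_threshold for p in pairs})
    hit = (div["q_value"] < q_threshold) & (div["fst"] > fst_threshold) \
        & div["panel_d_ok"]
    flags = div.assign(hit=hit).groupby("snp_id", sort=False)["hit"].any()
    order = divergence["snp_id"].drop_duplicates()
    return flags.reindex(order).rename("domestication_flag")


# -- PCA ----------------------------------------------------------------

@dataclass
class PcaResult:
    """Principal components of the 0/1-coded genotype matrix."""

    accession_ids: list[str]
    panel_of: list[str]
    coordinates: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)
    variance_explained: np.ndarray = field(repr=False)


def genotype_pca(panels: list[GenotypePanel] | GenotypePanel,
                 n_components: int = 2) -> PcaResult:
    """PCA on the 0/1 genotype coding (hom major = 1, hom minor = 0).

    Panels must share one SNP set and be fully imputed (no missing, no
    heterozygous calls).  The matrix is column-centered only; eigenvalues
    are those of the SNP covariance matrix (divisor n-1), non-increasing.
    """
    if isinstance(panels, GenotypePanel):
        panels = [panels]
    ids0 = list(panels[0].snps["snp_id"])
    for p in panels[1:]:
        if list(p.snps["snp_id"]) != ids0:
            raise ValueError("panels must share an identical SNP set")
    calls = np.vstack([p.calls for p in panels])
    if (calls == MISSING).any():
        raise ValueError("missing genotypes present: impute before PCA")
    if (calls == HET).any():
        raise ValueError("heterozygous calls present: run QC before PCA")
    accession_ids = [a for p in panels for a in p.accession_ids]
    panel_of = [p.panel_id for p in panels for _ in p.accession_ids]
    # hom major allele = 1, hom minor = 0, majority over the combined set
    hom_b = (calls == HOM_B).astype(float)
    major_is_b = hom_b.mean(axis=0) > 0.5
    x = np.where(major_is_b[None, :], hom_b, 1.0 - hom_b)
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    n = x.shape[0]
    eig = s**2 / (n - 1)
    total = xc.var(axis=0, ddof=1).sum()
    ncomp = min(n_components, s.size)
    return PcaResult(
        accession_ids=accession_ids,
        panel_of=panel_of,
        coordinates=(u * s)[:, :ncomp],
        eigenvalues=eig[:ncomp],
        variance_explained=eig[:ncomp] / total if total > 0 else eig[:ncomp] * 0,
    )


# -- Evanno delta-K -----------------------------------------------------

@dataclass
class DeltaKSeries:
    """Second-order rate of change of the admixture log-likelihood over K."""

    k_values: np.ndarray
    mean_loglik: np.ndarray
    replicate_sd: np.ndarray
    delta_k: np.ndarray    # NaN at the two endpoints
    best_k: int


def delta_k(k_values, logliks) -> DeltaKSeries:
    """Evanno-style delta-K from replicate log-likelihoods per K.

    ``logliks`` is a sequence (per K) of replicate log-likelihood values.
    delta K(K) = |L(K+1) - 2 L(K) + L(K-1)| / s(K) for interior K; the
    endpoints are undefined (NaN).  Zero replicate SD at an interior K is
    an error (division by zero).
    """
    k = np.asarray(k_values, dtype=int)
    if k.size < 3:
        raise ValueError("delta-K needs at least 3 consecutive K values")
    if np.any(np.diff(k) != 1):
        raise ValueError("K values must be consecutive")
    reps = [np.asarray(r, dtype=float) for r in logliks]
    if len(reps) != k.size or any(r.size < 2 for r in reps):
        raise ValueError("need >= 2 replicates for every K")
    mean_l = np.array([r.mean() for r in reps])
    sd = np.array([r.std(ddof=1) for r in reps])
    dk = np.full(k.size, np.nan)
    for i in range(1, k.size - 1):
        if sd[i] == 0:
            raise ValueError(f"zero replicate SD at K={k[i]}: delta-K undefined")
        dk[i] = abs(mean_l[i + 1] - 2 * mean_l[i] + mean_l[i - 1]) / sd[i]
    best = int(k[np.nanargmax(dk)])
    return DeltaKSeries(k, mean_l, sd, dk, best)


# -- windowed LD --------------------------------------------------------

def ld_r2_window(panel: GenotypePanel, window_bp: int = 30_000) -> pd.DataFrame:
    """Pairwise LD r^2 for same-chromosome SNP pairs within a window.

    r^2 is the squared Pearson correlation of the numeric genotype coding
    over accessions where both calls are observed.  Pairs where either
    SNP is constant over the complete observations are skipped with a
    warning.  Remove per-panel monomorphic SNPs first.
    """
    dose = panel.dose_b()
    chrom = panel.snps["chrom"].to_numpy()
    pos = panel.snps["pos"].to_numpy()
    rows = []
    skipped = 0
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        for ii, i in enumerate(idx):
            for j in idx[ii + 1:]:
                dist = abs(int(pos[j]) - int(pos[i]))
                if dist > window_bp:
                    if pos[j] > pos[i]:
                        break
                    continue
                x, y = dose[:, i], dose[:, j]
                ok = ~(np.isnan(x) | np.isnan(y))
                xs, ys = x[ok], y[ok]
                if ok.sum() < 2 or xs.std() == 0 or ys.std() == 0:
                    skipped += 1
                    continue
                r = np.corrcoef(xs, ys)[0, 1]
                rows.append((panel.snps["snp_id"].iloc[i],
                             panel.snps["snp_id"].iloc[j], dist, r * r))
    if skipped:
        warnings.warn(f"{skipped} constant-SNP pairs skipped in LD window scan")
    return pd.DataFrame(rows, columns=["snp_i", "snp_j", "distance_bp", "r2"])
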