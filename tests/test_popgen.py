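"""Diversity statistics, divergence tests, PCA, delta-K and windowed LD.

Tajima's D, the PCA eigenvalues and the VanRaden kinship are checked
against independently coded brute-force oracles.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import podpop as pp
from podpop.panel import GenotypePanel, HOM_A, HOM_B, HET, MISSING
from podpop.popgen import DiversityResult

from test_genio import mk_panel


# -- independent Tajima's D oracle ---------------------------------------

def tajima_d_brute_force(haplotypes: np.ndarray) -> float:
    """Textbook Tajima's D on an n x m 0/1 haplotype matrix.

    Mean pairwise difference by full enumeration of all n(n-1)/2 pairs;
    Watterson's theta from the segregating-site count; constants from
    first principles.
    """
    n, _ = haplotypes.shape
    seg = np.array([len(np.unique(col)) > 1 for col in haplotypes.T])
    s = int(seg.sum())
    if s == 0:
        raise ValueError("no segregating sites")
    pi = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            pi += (haplotypes[i] != haplotypes[j]).sum()
    pi /= n * (n - 1) / 2
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def haplo_to_panel(h: np.ndarray) -> GenotypePanel:
    return mk_panel(np.where(h == 0, HOM_A, HOM_B).astype(np.int8),
                    pos=list(range(100, 100 + 100 * h.shape[1], 100)))


def test_tajima_d_matches_brute_force_oracle():
    rng = np.random.default_rng(31)
    for _ in range(20):
        n = rng.integers(5, 15)
        m = rng.integers(5, 25)
        h = (rng.random((n, m)) < rng.uniform(0.1, 0.9, size=m)).astype(int)
        if not any(0 < h[:, j].sum() < n for j in range(m)):
            continue
        panel = haplo_to_panel(h)
        assert pp.diversity_stats(panel).tajima_d == pytest.approx(
            tajima_d_brute_force(h), abs=1e-9)


def test_tajima_d_fixture_n10():
    rng = np.random.default_rng(32)
    h = (rng.random((10, 5)) < 0.5).astype(int)
    panel = haplo_to_panel(h)
    res = pp.diversity_stats(panel)
    assert res.tajima_d == pytest.approx(tajima_d_brute_force(h), abs=1e-9)
    assert res.S <= 5 and res.pi_per_snp >= 0 and res.theta_per_snp >= 0


def test_tajima_d_errors():
    mono = mk_panel(np.full((6, 3), HOM_A, dtype=np.int8))
    with pytest.raises(ValueError):
        pp.diversity_stats(mono)
    tiny = mk_panel(np.array([[HOM_A, HOM_B], [HOM_B, HOM_A]], dtype=np.int8))
    with pytest.raises(ValueError):
        pp.diversity_stats(tiny)


def test_tajima_d_large_positive_under_sweep_ascertainment(qc_bundle):
    """Intermediate-frequency ascertained SNPs give strongly positive D,
    the regime observed in cultivated panels."""
    _, panels, _ = qc_bundle
    for panel in panels[1:]:
        assert pp.diversity_stats(panel).tajima_d > 2.0


def test_allele_frequencies_trivials():
    p = mk_panel([[HOM_A, HOM_A, HOM_A, HET],
                  [HOM_A, HOM_B, HOM_A, HET],
                  [HOM_A, HOM_A, HOM_A, MISSING],
                  [HOM_A, HOM_B, HOM_B, HOM_A]])
    f = pp.allele_frequencies(p)
    assert f[0] == 1.0
    assert f[1] == 0.5
    assert f[2] == 0.75
    assert f[3] == pytest.approx((0.5 + 0.5 + 1.0) / 3)  # hets count half


# -- chi-square divergence ------------------------------------------------

def test_chisq_divergence_worked_values():
    chi2, p = pp.chisq_gof_divergence(0.6, 0.6)
    assert chi2 == 0.0 and p == 1.0
    chi2, _ = pp.chisq_gof_divergence(1.0, 0.5)
    assert chi2 == pytest.approx((0.25**2 + 0.25**2) / 0.75)
    chi2, _ = pp.chisq_gof_divergence(1.0, 0.0)
    assert chi2 == pytest.approx(1.0)
    chi2, p = pp.chisq_gof_divergence(0.0, 0.0)  # allele absent in both
    assert chi2 == 0.0 and p == 1.0


def test_chisq_divergence_increasing_in_gap_at_fixed_mean():
    gaps = np.linspace(0, 0.6, 7)
    stats_ = [pp.chisq_gof_divergence(0.5 + g / 2, 0.5 - g / 2)[0] for g in gaps]
    assert all(b > a for a, b in zip(stats_, stats_[1:]))
    assert stats_[0] == 0.0


def test_chisq_count_variant_scales_with_sample_size():
    c_small, p_small = pp.chisq_gof_divergence(0.9, 0.5, 50, 50, use_counts=True)
    c_big, p_big = pp.chisq_gof_divergence(0.9, 0.5, 500, 500, use_counts=True)
    assert c_big == pytest.approx(10 * c_small)
    assert p_big < p_small


# -- BH ---------------------------------------------------------------------

def test_bh_adjust_hand_cases():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    assert pp.bh_adjust(p) == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert pp.bh_adjust([0.3]) == pytest.approx([0.3])
    same = pp.bh_adjust([0.2, 0.2, 0.2])
    assert same == pytest.approx([0.2, 0.2, 0.2])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_adjust_properties(pvals):
    p = np.array(pvals)
    q = pp.bh_adjust(p)
    assert np.all(q >= p - 1e-12)
    assert np.all(q <= 1.0)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in sorted-p order


# -- F_ST ---------------------------------------------------------------------

def test_fst_worked_values():
    assert pp.fst_pairwise(0.3, 0.3) == 0.0
    assert pp.fst_pairwise(0.0, 1.0) == 1.0
    assert pp.fst_pairwise(0.1, 0.9) == pytest.approx(0.64)
    assert pp.fst_pairwise(0.0, 0.0) == 0.0  # T = 0 convention


@settings(deadline=None, max_examples=100)
@given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
def test_fst_symmetry_and_allele_label_invariance(pa, pb):
    f = pp.fst_pairwise(pa, pb)
    assert 0.0 <= f <= 1.0 + 1e-12
    assert f == pytest.approx(pp.fst_pairwise(pb, pa))
    assert f == pytest.approx(pp.fst_pairwise(1 - pa, 1 - pb))


# -- domestication call --------------------------------------------------------

def _one_snp_divergence(q, fst):
    return pd.DataFrame({
        "snp_id": ["s0"], "chrom": [1], "pos": [100], "pair": ["CULT1"],
        "p_wild": [0.9], "p_max": [0.1], "expected": [0.5],
        "chi2": [10.0], "p_value": [q], "q_value": [q], "fst": [fst],
    })


def test_domestication_call_fst_boundary_is_strict():
    div = {"CULT1": DiversityResult("CULT1", 100, 10, 10, 0.3, 0.1, 3.0)}
    flagged = pp.call_domestication_snps(div, _one_snp_divergence(0.001, 0.051))
    assert bool(flagged.iloc[0])
    not_flagged = pp.call_domestication_snps(div, _one_snp_divergence(0.001, 0.05))
    assert not bool(not_flagged.iloc[0])
    low_d = {"CULT1": DiversityResult("CULT1", 100, 10, 10, 0.3, 0.1, 1.0)}
    assert not bool(pp.call_domestication_snps(low_d, _one_snp_divergence(0.001, 0.5)).iloc[0])
    with pytest.raises(ValueError):
        pp.call_domestication_snps({}, _one_snp_divergence(0.001, 0.5))


# -- PCA -----------------------------------------------------------------------

def test_pca_eigenvalues_match_covariance_oracle():
    rng = np.random.default_rng(33)
    calls = rng.choice([HOM_A, HOM_B], size=(10, 20)).astype(np.int8)
    panel = mk_panel(calls)
    res = pp.genotype_pca(panel, n_components=5)
    hom_b = (calls == HOM_B).astype(float)
    major_b = hom_b.mean(axis=0) > 0.5
    x = np.where(major_b[None, :], hom_b, 1 - hom_b)
    eig = np.linalg.eigvalsh(np.cov(x.T))[::-1]
    assert res.eigenvalues == pytest.approx(eig[:5], abs=1e-9)
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)
    assert res.variance_explained.sum() <= 1.0 + 1e-9


def test_pca_separates_diverged_panels(qc_bundle):
    _, panels, _ = qc_bundle
    clean = [pp.impute_ld_knn(pp.hets_to_missing(p)) for p in
             pp.intersect_snps([pp.filter_missingness(pp.hets_to_missing(p))
                                for p in panels])]
    res = pp.genotype_pca(clean, n_components=2)
    pc1 = res.coordinates[:, 0]
    wild = np.array(res.panel_of) == "WILD"
    side = pc1[wild].mean() > pc1[~wild].mean()
    correct = (pc1[wild] > 0).mean() if side else (pc1[wild] < 0).mean()
    correct_c = (pc1[~wild] < 0).mean() if side else (pc1[~wild] > 0).mean()
    assert correct > 0.9 and correct_c > 0.9


def test_pca_duplicate_accessions_identical_coordinates():
    rng = np.random.default_rng(34)
    calls = rng.choice([HOM_A, HOM_B], size=(6, 15)).astype(np.int8)
    calls[3] = calls[0]
    res = pp.genotype_pca(mk_panel(calls))
    assert res.coordinates[3] == pytest.approx(res.coordinates[0])
    with_missing = calls.copy()
    with_missing[0, 0] = MISSING
    with pytest.raises(ValueError):
        pp.genotype_pca(mk_panel(with_missing))


# -- delta-K --------------------------------------------------------------------

def test_delta_k_zero_for_linear_loglik():
    k = [1, 2, 3, 4, 5]
    logliks = [np.array([-100.0 * kk, -100.0 * kk + 1]) for kk in k]
    res = pp.delta_k(k, logliks)
    interior = res.delta_k[1:-1]
    assert interior == pytest.approx(np.zeros(3), abs=1e-9)
    assert np.isnan(res.delta_k[0]) and np.isnan(res.delta_k[-1])


def test_delta_k_detects_kink():
    k = [1, 2, 3, 4, 5]
    means = {1: -500, 2: -300, 3: -200, 4: -190, 5: -185}  # elbow at K=3
    rng = np.random.default_rng(35)
    logliks = [means[kk] + rng.normal(0, 2.0, size=20) for kk in k]
    assert pp.delta_k(k, logliks).best_k == 3


def test_delta_k_errors():
    with pytest.raises(ValueError):
        pp.delta_k([1, 2], [[1.0, 2.0], [1.0, 2.0]])
    with pytest.raises(ValueError):
        pp.delta_k([1, 2, 3], [[1.0, 2.0], [5.0, 5.0], [1.0, 2.0]])  # zero SD


# -- LD window -------------------------------------------------------------------

def test_ld_window_duplicate_and_bounds():
    rng = np.random.default_rng(36)
    col = rng.choice([HOM_A, HOM_B], size=12).astype(np.int8)
    other = rng.choice([HOM_A, HOM_B], size=12).astype(np.int8)
    calls = np.column_stack([col, col, other])
    p = mk_panel(calls, pos=[1000, 2000, 33001])  # third SNP 31 kb from first
    out = pp.ld_r2_window(p, window_bp=30_000)
    pair = out[(out.snp_i == "s0") & (out.snp_j == "s1")]
    assert pair["r2"].iloc[0] == pytest.approx(1.0)
    assert not ((out.snp_i == "s0") & (out.snp_j == "s2")).any()


def test_ld_window_null_mean_small():
    rng = np.random.default_rng(37)
    calls = rng.choice([HOM_A, HOM_B], size=(500, 40)).astype(np.int8)
    p = mk_panel(calls, pos=list(range(1000, 1000 + 1000 * 40, 1000)))
    out = pp.ld_r2_window(p, window_bp=30_000)
    assert len(out) > 100
    assert out["r2"].mean() < 0.05
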