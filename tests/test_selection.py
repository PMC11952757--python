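"""Marker-assisted selection statistics and gBLUP genomic selection."""

import numpy as np
import pandas as pd
import pytest

import podpop as pp
from podpop.panel import HOM_A, HOM_B

from test_genio import mk_panel


def _perfect_marker_panel():
    """40 accessions: allele A at s0 predicts rating 1, allele B rating 5."""
    ratings = np.array([1.0] * 20 + [5.0] * 20)
    calls = np.zeros((40, 2), dtype=np.int8)
    calls[20:, 0] = HOM_B
    rng = np.random.default_rng(51)
    calls[:, 1] = rng.choice([HOM_A, HOM_B], size=40)  # trait-independent SNP
    return ratings, mk_panel(calls)


# -- favorable alleles -----------------------------------------------------

def test_favorable_allele_perfect_predictor():
    ratings, panel = _perfect_marker_panel()
    tab = pp.favorable_alleles(ratings, panel, ["s0", "s1"])
    assert tab.favorable_allele[0] == "A"
    assert tab.unfavorable_allele[0] == "G"


def test_favorable_allele_tie_goes_to_major():
    ratings = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 2.0])
    calls = np.array([[HOM_A], [HOM_A], [HOM_A], [HOM_A], [HOM_B], [HOM_B]],
                     dtype=np.int8)
    tab = pp.favorable_alleles(ratings, mk_panel(calls), ["s0"])
    assert tab.favorable_allele[0] == "A"  # equal means -> major allele


def test_favorable_allele_monomorphic_rejected():
    calls = np.full((6, 1), HOM_A, dtype=np.int8)
    with pytest.raises(ValueError, match="s0"):
        pp.favorable_alleles(np.arange(6.0), mk_panel(calls), ["s0"])


def test_negative_effect_allele_recovered_in_simulation():
    """The allele reducing liability is recovered as favorable in >=95% of
    replicates of a single-QTL panel."""
    rng = np.random.default_rng(52)
    hits = 0
    n = 200
    for _ in range(100):
        p_freq = rng.uniform(0.3, 0.7)
        dose_is_b = rng.random(n) < p_freq
        calls = np.where(dose_is_b, HOM_B, HOM_A).astype(np.int8)[:, None]
        # allele B lowers the rating
        liability = -1.0 * dose_is_b + rng.normal(0, 0.7, n)
        ratings = np.clip(np.digitize(liability, [-1.2, -0.7, -0.3, 0.2]) + 1, 1, 5)
        tab = pp.favorable_alleles(ratings.astype(float), mk_panel(calls), ["s0"])
        hits += tab.favorable_allele[0] == "G"  # allele_b default is G
    assert hits >= 95


# -- group percentages and efficiencies ---------------------------------------

def test_group_percentages_worked_values():
    ratings, panel = _perfect_marker_panel()
    ratings = ratings.copy()
    ratings[:4] = [1, 1, 1, 2]  # group 2 gets one accession
    tab = pp.favorable_alleles(ratings, panel, ["s0"])
    pct = pp.group_percentages(tab, ratings)
    assert pct.loc["s0", 1] == 100.0
    assert pct.loc["s0", 5] == 0.0
    assert np.isnan(pct.loc["s0", 3])  # empty group undefined


def test_group_percentage_three_of_four():
    ratings = np.array([1.0, 1.0, 1.0, 1.0, 5.0, 5.0])
    calls = np.array([[HOM_A], [HOM_A], [HOM_A], [HOM_B], [HOM_B], [HOM_B]],
                     dtype=np.int8)
    tab = pp.favorable_alleles(ratings, mk_panel(calls), ["s0"])
    pct = pp.group_percentages(tab, ratings)
    assert pct.loc["s0", 1] == pytest.approx(75.0)  # 3 of 4 carriers


def test_selection_efficiency_formulas():
    pct = pd.DataFrame({1: [80.0, 80.0], 2: [50.0, 50.0], 3: [50.0, 50.0],
                        4: [50.0, 50.0], 5: [40.0, 40.0]},
                       index=pd.Index(["a", "b"], name="snp_id"))
    # favorable 80% in group 1, unfavorable 60% in group 5 -> 0.7
    assert pp.panel_selection_efficiency(pct) == pytest.approx(0.7)
    assert pp.snp_selection_efficiency("a", pct) == pytest.approx(0.7)


def test_perfect_and_null_markers(assoc_bundle):
    ratings, panel = _perfect_marker_panel()
    tab = pp.favorable_alleles(ratings, panel, ["s0"])
    pct = pp.group_percentages(tab, ratings)
    assert pp.panel_selection_efficiency(pct) == pytest.approx(1.0)
    # trait-independent markers across a large panel -> efficiency ~ 0.5
    _, raw_panel, _, records = assoc_bundle
    sim_panel = pp.maf_filter(raw_panel, min_maf=0.1)
    sim_ratings = np.array([t.rating for t in records])
    rng = np.random.default_rng(53)
    random_snps = list(sim_panel.snps["snp_id"].iloc[
        rng.choice(sim_panel.n_snps, 50, replace=False)])
    p = sim_panel.restrict_to(random_snps)
    tab = pp.favorable_alleles(sim_ratings, p, random_snps)
    pct = pp.group_percentages(tab, sim_ratings)
    assert pp.panel_selection_efficiency(pct) == pytest.approx(0.5, abs=0.05)


def test_panel_efficiency_equals_mean_of_snp_efficiencies(assoc_bundle):
    _, panel, truth, records = assoc_bundle
    ratings = np.array([t.rating for t in records])
    qtls = [s for s in truth.qtl_snp_ids]
    tab = pp.favorable_alleles(ratings, panel, qtls)
    pct = pp.group_percentages(tab, ratings)
    per_snp = [pp.snp_selection_efficiency(s, pct) for s in tab.snp_ids]
    assert pp.panel_selection_efficiency(pct) == pytest.approx(np.mean(per_snp))


def test_efficiency_invariant_to_allele_relabeling():
    ratings = np.array([1.0, 1.0, 1.0, 5.0, 5.0, 5.0])
    calls = np.array([[HOM_A], [HOM_A], [HOM_B], [HOM_B], [HOM_B], [HOM_A]],
                     dtype=np.int8)
    tab = pp.favorable_alleles(ratings, mk_panel(calls), ["s0"])
    eff = pp.panel_selection_efficiency(pp.group_percentages(tab, ratings))
    flipped = mk_panel((HOM_B - calls + HOM_A).astype(np.int8))
    tab2 = pp.favorable_alleles(ratings, flipped, ["s0"])
    eff2 = pp.panel_selection_efficiency(pp.group_percentages(tab2, ratings))
    assert eff == pytest.approx(eff2)


def test_high_group_defaults_to_max_observed():
    """A panel whose worst rating is 4 uses group 4 as the upper extreme."""
    ratings = np.array([1.0, 1.0, 1.0, 4.0, 4.0, 4.0])
    calls = np.array([[HOM_A], [HOM_A], [HOM_A], [HOM_B], [HOM_B], [HOM_B]],
                     dtype=np.int8)
    tab = pp.favorable_alleles(ratings, mk_panel(calls), ["s0"])
    pct = pp.group_percentages(tab, ratings)
    assert pp.panel_selection_efficiency(pct) == pytest.approx(1.0)


# -- haplotype ranking ----------------------------------------------------------

def test_rank_haplotypes_counts_and_percentages():
    rng = np.random.default_rng(54)
    n_qtl = 86
    carriers = rng.random((5, n_qtl)) < 0.5
    carriers[0] = True          # carries everything
    carriers[1] = False         # carries nothing
    carriers[2, :] = False
    carriers[2, :62] = True     # 62 of 86
    tab = pp.FavorableAlleleTable(
        "P", [f"s{i}" for i in range(n_qtl)], ["A"] * n_qtl, ["G"] * n_qtl,
        carriers, [f"acc{i}" for i in range(5)])
    ranked = pp.rank_haplotypes(tab, np.ones(5))
    assert ranked.iloc[0]["accession_id"] == "acc0"
    assert ranked.iloc[0]["percent"] == 100.0
    assert ranked.iloc[-1]["accession_id"] == "acc1"
    row62 = ranked[ranked["accession_id"] == "acc2"].iloc[0]
    assert row62["percent"] == pytest.approx(72.1, abs=0.05)  # 62/86


def test_rank_haplotypes_ties_break_by_id():
    carriers = np.ones((3, 4), dtype=bool)
    tab = pp.FavorableAlleleTable("P", list("abcd"), ["A"] * 4, ["G"] * 4,
                                  carriers, ["z", "m", "a"])
    ranked = pp.rank_haplotypes(tab, np.ones(3))
    assert list(ranked["accession_id"]) == ["a", "m", "z"]


# -- gBLUP ------------------------------------------------------------------------

def test_gblup_recovers_breeding_values(assoc_bundle, assoc_kinship):
    _, panel, truth, records = assoc_bundle
    y = np.array([t.transformed for t in records])
    fit = pp.gblup_fit(y, assoc_kinship)
    bv = truth.bv_vector(panel)
    assert pp.prediction_r(bv, fit.gbv) > 0.7
    assert fit.sigma_u2 > 0 and fit.sigma_e2 > 0
    assert (fit.pev > 0).all()
    assert abs(fit.gbv.mean()) < 1e-6  # centered kinship -> GBV sums to ~0


def test_gblup_constant_trait_and_duplicates():
    rng = np.random.default_rng(55)
    calls = rng.choice([HOM_A, HOM_B], size=(30, 60)).astype(np.int8)
    calls[7] = calls[3]
    panel = mk_panel(calls)
    k = pp.kinship(panel, "marker-vanraden")
    fit = pp.gblup_fit(np.full(30, 2.0), k)
    assert fit.sigma_u2 == pytest.approx(0.0, abs=1e-9)
    assert fit.gbv == pytest.approx(np.zeros(30), abs=1e-9)
    y = rng.standard_normal(30)
    y[7] = y[3]
    fit = pp.gblup_fit(y, k)
    assert fit.gbv[7] == pytest.approx(fit.gbv[3], abs=1e-8)


def test_prediction_r_trivials():
    y = np.arange(10.0)
    assert pp.prediction_r(y, y) == pytest.approx(1.0)
    assert pp.prediction_r(y, -y) == pytest.approx(-1.0)
    rng = np.random.default_rng(56)
    assert abs(pp.prediction_r(rng.standard_normal(1000),
                               rng.standard_normal(1000))) < 0.1
    with pytest.raises(ValueError):
        pp.prediction_r(np.ones(5), np.arange(5.0))


def test_kfold_modes_and_reproducibility(assoc_bundle, assoc_kinship):
    _, panel, _, records = assoc_bundle
    y = np.array([t.transformed for t in records])
    a = pp.kfold_cv(y, assoc_kinship, folds=(5,), reps=5, seed=3)
    b = pp.kfold_cv(y, assoc_kinship, folds=(5,), reps=5, seed=3)
    assert a == b
    c = pp.kfold_cv(y, assoc_kinship, folds=(5,), reps=5, seed=3, mode="partition")
    assert isinstance(c[5], float)
    with pytest.raises(ValueError):
        pp.kfold_cv(y, assoc_kinship, folds=(1,), reps=2)


def test_kfold_monte_carlo_error_shrinks_with_reps():
    """The SE of the mean CV accuracy shrinks roughly as 1/sqrt(reps)."""
    rng = np.random.default_rng(57)
    calls = rng.choice([HOM_A, HOM_B], size=(100, 200)).astype(np.int8)
    panel = mk_panel(calls, pos=list(range(100, 100 + 100 * 200, 100)))
    k = pp.kinship(panel, "marker-vanraden")
    dose = panel.dose_major()
    y = dose[:, :20].sum(axis=1) + rng.standard_normal(100) * 1.5
    means_small = [pp.kfold_cv(y, k, folds=(2,), reps=4, seed=s)[2]
                   for s in range(8)]
    means_big = [pp.kfold_cv(y, k, folds=(2,), reps=16, seed=s)[2]
                 for s in range(8)]
    ratio = np.std(means_small) / np.std(means_big)
    assert 1.2 < ratio < 3.5  # ~2 expected, wide band for 8-sample SDs
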