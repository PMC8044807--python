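"""Dual-LASSO selection, modal imputation, risk-allele orientation, PRS."""
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enrichprs import (
    GenotypeMatrix,
    PRSModel,
    PRSVariant,
    build_prs_model,
    compute_prs,
    impute_missing_mode,
    lasso_select,
    load_published_panel,
    orient_risk_allele,
)
from enrichprs.containers import MISSING

from conftest import make_annotation, make_genotypes

# Independent column sum of the published panel's 20 weights, added by
# hand before the loader was written.
PANEL_WEIGHT_SUM = 21.381


# --------------------------------------------------------------------------
# dual-LASSO selection
# --------------------------------------------------------------------------

def _selection_data(n, m, planted, seed, beta=0.8):
    rng = np.random.default_rng(seed)
    calls = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
    y = beta * calls[:, :planted].sum(axis=1) + rng.normal(0, 2, n)
    y = np.clip(y + (3 - np.quantile(y, 0.6)), 0, 10)
    gm = make_genotypes(calls)
    phen = pd.DataFrame(
        {
            "individual_id": gm.individual_ids,
            "nrs_6_12mo": y,
            "cpsp": (y > 3).astype(int),
        }
    )
    return gm, phen


def test_selection_is_intersection_of_both_supports():
    gm, phen = _selection_data(300, 40, planted=3, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = lasso_select(gm, phen, gm.variant_ids, seed=0)
    assert set(sel.selected) == set(sel.linear_selected) & set(sel.logistic_selected)
    # selection preserves candidate order
    assert list(sel.selected) == [v for v in gm.variant_ids if v in set(sel.selected)]


def test_planted_variants_survive_dual_selection_across_seeds():
    """3 planted variants (beta 0.8) among 100 nulls at n = 500: the
    intersection recovers all three in at least 90% of 50 seeds."""
    hits = 0
    for seed in range(50):
        gm, phen = _selection_data(500, 103, planted=3, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = lasso_select(gm, phen, gm.variant_ids, seed=seed)
        hits += {"v0", "v1", "v2"} <= set(sel.selected)
    assert hits >= 45


def test_pure_noise_candidates_select_nothing_typically():
    """With no signal the cross-validated penalty collapses the model:
    median intersection size over 50 seeds is 0."""
    sizes = []
    for seed in range(50):
        gm, phen = _selection_data(500, 100, planted=0, seed=1000 + seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = lasso_select(gm, phen, gm.variant_ids, seed=seed)
        sizes.append(len(sel.selected))
    assert np.median(sizes) == 0


def test_empty_candidate_set_is_an_error(small_cohort):
    with pytest.raises(ValueError, match="empty"):
        lasso_select(small_cohort.genotypes, small_cohort.phenotypes, [])


def test_missing_genotypes_must_be_imputed_first():
    gm, phen = _selection_data(100, 5, planted=0, seed=2)
    calls = gm.calls.copy()
    calls[0, 0] = MISSING
    gm2 = make_genotypes(calls)
    with pytest.raises(ValueError, match="impute"):
        lasso_select(gm2, phen, gm2.variant_ids)


# --------------------------------------------------------------------------
# modal imputation
# --------------------------------------------------------------------------

def test_impute_fills_with_group_mode():
    calls = np.array([[0], [0], [0], [1], [MISSING]])
    gm = make_genotypes(calls)
    imputed, report = impute_missing_mode(gm)
    assert imputed.calls[4, 0] == 0
    assert report["n_imputed"] == 1


def test_impute_is_identity_without_missing():
    calls = np.array([[0, 1], [2, 1], [1, 0]])
    gm = make_genotypes(calls)
    imputed, report = impute_missing_mode(gm)
    assert np.array_equal(imputed.calls, gm.calls)
    assert report["n_imputed"] == 0


def test_impute_respects_groups():
    # group A is mostly 0, group B mostly 2; one missing call per group
    calls = np.array([[0], [0], [MISSING], [2], [2], [MISSING]])
    gm = make_genotypes(calls)
    groups = {s: ("A" if i < 3 else "B") for i, s in enumerate(gm.individual_ids)}
    imputed, _ = impute_missing_mode(gm, groups)
    assert imputed.calls[2, 0] == 0
    assert imputed.calls[5, 0] == 2


def test_impute_accuracy_accounting_131_by_16():
    """131 individuals x 16 variants with 45 missing cells leaves 2,051
    observed genotypes for accuracy evaluation."""
    rng = np.random.default_rng(0)
    calls = rng.binomial(2, 0.3, size=(131, 16)).astype(np.int8)
    flat = rng.choice(calls.size, size=45, replace=False)
    calls[np.unravel_index(flat, calls.shape)] = MISSING
    gm = make_genotypes(calls)
    imputed, report = impute_missing_mode(gm)
    assert report["n_imputed"] == 45
    assert report["n_observed"] == 2051


def test_impute_errors_when_group_has_no_observations():
    calls = np.array([[MISSING], [MISSING], [0]])
    gm = make_genotypes(calls)
    groups = {gm.individual_ids[0]: "A", gm.individual_ids[1]: "A",
              gm.individual_ids[2]: "B"}
    with pytest.raises(ValueError, match="every member"):
        impute_missing_mode(gm, groups)


# --------------------------------------------------------------------------
# risk-allele orientation
# --------------------------------------------------------------------------

def test_orientation_examples_from_published_panel():
    # minor allele raises pain -> minor is the risk allele
    assert orient_risk_allele(1.657, major_allele="G", minor_allele="A") == ("A", 1.657)
    # minor allele lowers pain -> major carries the risk
    assert orient_risk_allele(-2.299, major_allele="G", minor_allele="A") == ("G", 2.299)


def test_orientation_invariant_under_allele_recoding():
    # recoding major<->minor flips beta; the (risk allele, weight) pair is stable
    a = orient_risk_allele(0.9, "G", "A")
    b = orient_risk_allele(-0.9, "A", "G")
    assert a == b


def test_orientation_rejects_zero_or_nonfinite_beta():
    with pytest.raises(ValueError):
        orient_risk_allele(0.0, "G", "A")
    with pytest.raises(ValueError):
        orient_risk_allele(float("nan"), "G", "A")


def test_build_prs_model_from_association_table():
    assoc = pd.DataFrame(
        {"variant_id": ["v0", "v1"], "beta": [0.5, -1.2], "se": [0.1, 0.2],
         "p_value": [0.01, 0.02], "n_used": [100, 100]}
    )
    annot = make_annotation(["v0", "v1"])
    model = build_prs_model(assoc, annot, ["v0", "v1"])
    assert model.m == 2
    assert model.variants[0].risk_allele == "G"  # minor (beta > 0)
    assert model.variants[1].risk_allele == "A"  # major (beta < 0)
    assert model.variants[1].weight == 1.2


# --------------------------------------------------------------------------
# PRS computation
# --------------------------------------------------------------------------

def test_published_panel_loads_with_expected_structure():
    panel = load_published_panel()
    assert panel.m == 20
    genes = {v.gene for v in panel.variants}
    assert genes == {"ATXN1", "PRKCA", "CACNG2", "DRD2", "KCNJ3", "KCNJ6", "KCNK3"}
    assert sum(v.weight for v in panel.variants) == pytest.approx(PANEL_WEIGHT_SUM)
    assert all(v.weight > 0 for v in panel.variants)


def _panel_genotypes(panel, fill):
    """Genotypes carrying `fill` copies of the risk allele everywhere."""
    calls = np.zeros((3, panel.m), dtype=np.int8)
    for j, v in enumerate(panel.variants):
        minor_count = fill if v.risk_allele == v.minor_allele else 2 - fill
        calls[:, j] = minor_count
    return GenotypeMatrix(["a", "b", "c"], [v.variant_id for v in panel.variants], calls)


def test_prs_zero_and_maximum_scores():
    panel = load_published_panel()
    zero = compute_prs(panel, _panel_genotypes(panel, 0))
    assert (zero["prs"] == 0).all()
    full = compute_prs(panel, _panel_genotypes(panel, 2))
    assert full["prs"].iloc[0] == pytest.approx(2 * PANEL_WEIGHT_SUM)
    assert panel.max_score == pytest.approx(2 * PANEL_WEIGHT_SUM)


def test_prs_single_heterozygote_scores_its_weight():
    panel = load_published_panel()
    gm = _panel_genotypes(panel, 0)
    calls = gm.calls.copy()
    j = [v.variant_id for v in panel.variants].index("rs62069959")
    v = panel.variants[j]
    calls[0, j] = 1 if v.risk_allele == v.minor_allele else 1  # heterozygote
    gm2 = GenotypeMatrix(gm.individual_ids, gm.variant_ids, calls)
    scores = compute_prs(panel, gm2).set_index("individual_id")
    assert scores.at["a", "prs"] == pytest.approx(2.299)
    assert scores.at["b", "prs"] == 0.0


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=25)
def test_prs_linearity_and_bounds(seed):
    """PRS is an exact weighted risk-allele sum: linear in genotype
    'addition' and bounded by [0, 2 * sum of weights]."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(1, 8))
    weights = np.round(rng.uniform(0.1, 2.5, m), 3)
    variants = tuple(
        PRSVariant(f"v{j}", "G1", "A", "G", "G" if rng.random() < 0.5 else "A",
                   float(weights[j]))
        for j in range(m)
    )
    model = PRSModel(variants=variants)
    g1 = rng.integers(0, 2, size=(5, m)).astype(np.int8)  # halves so g1+g2 stays valid
    g2 = rng.integers(0, 2, size=(5, m)).astype(np.int8)
    ids = [f"s{i}" for i in range(5)]
    vids = [v.variant_id for v in variants]
    s1 = compute_prs(model, GenotypeMatrix(ids, vids, g1))["prs"]
    s2 = compute_prs(model, GenotypeMatrix(ids, vids, g2))["prs"]
    s12 = compute_prs(model, GenotypeMatrix(ids, vids, g1 + g2))["prs"]
    riskflip = np.array([1 if v.risk_allele == v.minor_allele else -1 for v in variants])
    # linearity up to the constant offset of major-allele-risk variants
    offset = 2 * weights[riskflip < 0].sum()
    np.testing.assert_allclose(s12, s1 + s2 - offset, atol=1e-9)
    for s in (s1, s2, s12):
        assert ((s >= -1e-9) & (s <= model.max_score + 1e-9)).all()


def test_prs_errors_on_absent_variant_or_missing_call():
    panel = load_published_panel()
    gm = _panel_genotypes(panel, 1).subset_variants(
        [v.variant_id for v in panel.variants][:-1]
    )
    with pytest.raises(ValueError, match="absent"):
        compute_prs(panel, gm)
    gm2 = _panel_genotypes(panel, 1)
    calls = gm2.calls.copy()
    calls[0, 0] = MISSING
    gm3 = GenotypeMatrix(gm2.individual_ids, gm2.variant_ids, calls)
    with pytest.raises(ValueError, match="missing"):
        compute_prs(panel, gm3)


def test_prs_model_json_roundtrip(tmp_path):
    panel = load_published_panel()
    path = panel.to_json(tmp_path / "model.json")
    again = PRSModel.from_json(path)
    assert again.variants == panel.variants
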