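"""The six-step screening battery: each screen and the fixed-point loop."""

import warnings

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import kstest

from catdev.calibration import ResponseMatrix, eap_scores, fit_model
from catdev.errors import ScreeningError
from catdev.pool_screening import (dif_screen, discrimination_screen,
                                   q3_screen, s_x2_screen, screen_pool,
                                   unidimensionality_screen)
from catdev.irt_models import ItemBank, ItemParameters
from catdev.synthetic_data import (CohortSpec, generate_cohort,
                                   make_item_bank, planted_defect_design,
                                   simulate_responses)


# -- step 1: unidimensionality ----------------------------------------------

def test_unidimensional_pool_passes(clean_cohort):
    res = unidimensionality_screen(clean_cohort.responses)
    assert res.passed and res.eigen_ratio >= 4.0 and not res.removed


def test_off_dimension_item_removed():
    spec = CohortSpec(seed=5, n_persons=500, n_dichotomous=4, n_polytomous=10,
                      off_dimension_items=("i07",))
    cohort = generate_cohort(spec)
    res = unidimensionality_screen(cohort.responses)
    assert res.removed == ["i07"]
    assert res.loadings["i07"] < 0.3


def test_two_orthogonal_factors_fail_ratio():
    # half the items driven by an independent second trait
    spec = CohortSpec(seed=6, n_persons=500, n_dichotomous=0, n_polytomous=12,
                      off_dimension_items=tuple(f"i{j:02d}" for j in range(7, 13)))
    cohort = generate_cohort(spec)
    res = unidimensionality_screen(cohort.responses)
    assert res.eigen_ratio < 3.0 and not res.passed


def test_constant_item_raises():
    codes = np.ones((100, 3), dtype=int)
    codes[:, :2] = np.random.default_rng(0).integers(0, 2, size=(100, 2))
    resp = ResponseMatrix([f"p{i}" for i in range(100)], ["a", "b", "flat"], codes)
    with pytest.raises(ScreeningError, match="flat"):
        unidimensionality_screen(resp)


# -- step 3: Q3 --------------------------------------------------------------

def test_q3_symmetry_and_clean_null(clean_cohort, calibrated_clean):
    bank, _, thetas = calibrated_clean
    res = q3_screen(clean_cohort.responses, bank, thetas)
    M = res.matrix.values
    assert np.allclose(M, M.T, equal_nan=True)
    off = M[~np.isnan(M)]
    assert np.all(np.abs(off) <= 1.0)
    assert not res.flagged_pairs


def test_q3_detects_planted_dependence():
    detected = 0
    _, bank0 = planted_defect_design(seed=0)
    for s in range(8):
        spec = CohortSpec(seed=700 + s, n_persons=500, n_dichotomous=6,
                          n_polytomous=14,
                          dependent_pairs=((("i10", "i11"), 0.8),))
        cohort = generate_cohort(spec, bank=bank0)
        est, _ = fit_model(cohort.responses, "GRM")
        th = eap_scores(cohort.responses, est)
        res = q3_screen(cohort.responses, est, th)
        pairs = {frozenset((a, b)) for a, b, _ in res.flagged_pairs}
        if frozenset(("i10", "i11")) in pairs and res.removed[0] in ("i10", "i11"):
            detected += 1
    assert detected >= 7     # >= 80% detection of a 0.8-loading nuisance pair


# -- step 4: S-X^2 -----------------------------------------------------------

def test_s_x2_type_one_error_and_uniformity():
    """On model-true data (refit each replicate) S-X^2 p-values are
    approximately uniform and the 1% test rejects at about its level."""
    spec = CohortSpec(seed=1, n_persons=400, n_dichotomous=4, n_polytomous=8)
    pvals = []
    for s in range(60):
        rng = np.random.default_rng(3000 + s)
        bank = make_item_bank(spec, rng)
        th = rng.normal(size=400)
        resp = simulate_responses(bank, th, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est, _ = fit_model(resp, "GRM")
            res = s_x2_screen(resp, est)
        pvals.extend(res.table["p"].dropna().tolist())
    pvals = np.asarray(pvals)
    assert 0.0 <= float(np.mean(pvals < 0.01)) <= 0.03
    assert kstest(pvals, "uniform").statistic < 0.1


def test_s_x2_detects_non_graded_item():
    """A bell-shaped (non-monotone) response process cannot be expressed by
    any graded item and is flagged with high power."""
    spec = CohortSpec(seed=1, n_persons=1000, n_dichotomous=6, n_polytomous=14)
    hits = 0
    for s in range(5):
        rng = np.random.default_rng(500 + s)
        bank = make_item_bank(spec, rng)
        th = rng.normal(size=1000)
        resp = simulate_responses(bank, th, rng)
        p = 0.15 + 0.75 * np.exp(-th ** 2)
        codes = resp.codes.copy()
        codes[:, 0] = (rng.uniform(size=1000) < p).astype(int)
        resp = ResponseMatrix(resp.person_ids, resp.item_ids, codes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est, _ = fit_model(resp, "GRM")
            res = s_x2_screen(resp, est)
        hits += float(res.table.set_index("item_id").loc["i01", "p"]) < 0.01
    assert hits >= 4


# -- step 5: discrimination --------------------------------------------------

def test_discrimination_band():
    items = [ItemParameters("lo", 2, 0.3, (0.0,)),
             ItemParameters("mid", 2, 0.57, (0.0,)),
             ItemParameters("edge", 2, 0.5, (0.0,)),
             ItemParameters("hi", 2, 2.37, (0.0,)),
             ItemParameters("vhi", 2, 2.6, (0.0,))]
    removed, flags = discrimination_screen(ItemBank(items))
    assert removed == ["lo"]
    assert flags["edge"] == "ok"          # boundary retained (strict inequality)
    assert flags["hi"] == "ok" and flags["vhi"] == "high"


# -- step 6: DIF -------------------------------------------------------------

def test_dif_null_and_invariances(clean_cohort, calibrated_clean):
    _, _, thetas = calibrated_clean
    resp = clean_cohort.responses
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = dif_screen(resp, resp.groups, thetas)
        swapped = dif_screen(resp, 1 - resp.groups, thetas)
    assert (res.table["delta_r2"] >= 0).all()       # nested models
    assert res.table["delta_r2"].max() <= 0.02      # no DIF planted
    assert np.allclose(res.table["delta_r2"], swapped.table["delta_r2"],
                       atol=1e-5)


def test_dif_power_on_shifted_item():
    detected = 0
    _, bank0 = planted_defect_design(seed=0)
    for s in range(10):
        spec = CohortSpec(seed=900 + s, n_persons=500, n_dichotomous=6,
                          n_polytomous=14, dif_items=(("i16", 0.75),))
        cohort = generate_cohort(spec, bank=bank0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est, _ = fit_model(cohort.responses, "GRM")
            th = eap_scores(cohort.responses, est)
            res = dif_screen(cohort.responses, cohort.responses.groups, th)
        detected += "i16" in res.removed
    assert detected >= 8


def test_dif_constant_group_raises(clean_cohort, calibrated_clean):
    _, _, thetas = calibrated_clean
    with pytest.raises(ScreeningError):
        dif_screen(clean_cohort.responses,
                   np.zeros(clean_cohort.responses.n_persons), thetas)


# -- full battery ------------------------------------------------------------

def test_clean_pool_is_fixed_point(clean_cohort, calibrated_clean):
    bank, _, _ = calibrated_clean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = screen_pool(clean_cohort.responses, bank,
                             groups=clean_cohort.responses.groups)
    assert report.removals == [] and report.n_passes == 1
    assert report.surviving.item_ids == clean_cohort.responses.item_ids


def test_planted_defects_removed_under_their_labels():
    spec, bank0 = planted_defect_design(seed=301)
    cohort = generate_cohort(spec, bank=bank0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bank, _ = fit_model(cohort.responses, "GRM")
        report = screen_pool(cohort.responses, bank,
                             groups=cohort.responses.groups)
    by_step = report.removed_by_step()
    assert by_step["unidimensionality"] == ["i03"]
    assert by_step["local_dependence"] in (["i10"], ["i11"])
    assert by_step["dif"] == ["i16"]
    # partition invariant
    surviving = set(report.surviving.item_ids)
    removed = set(report.removed_ids)
    assert removed | surviving == set(report.input_items)
    assert not removed & surviving
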