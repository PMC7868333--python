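"""Adaptive-test loop: EAP scoring, MFI selection, SE stopping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catdev.calibration import QuadraturePrior
from catdev.cat_engine import (CATConfig, ThetaEstimate, administer,
                               eap_estimate, select_first_item,
                               select_next_item, simulate_cat, stop_check)
from catdev.errors import MissingItemError
from catdev.irt_models import MISSING, ItemBank, ItemParameters, item_information
from catdev.synthetic_data import CohortSpec, make_item_bank, simulate_responses


# -- starting item -----------------------------------------------------------

def test_first_item_singleton_and_determinism(pub_bank):
    single = ItemBank([pub_bank["2"]])
    assert select_first_item(single, np.random.default_rng(0)) == "2"
    draws = [select_first_item(pub_bank, np.random.default_rng(42))
             for _ in range(5)]
    assert len(set(draws)) == 1


def test_first_item_uniformity():
    bank = ItemBank([ItemParameters(f"i{j}", 2, 1.0, (0.0,)) for j in range(10)])
    rng = np.random.default_rng(7)
    counts = np.zeros(10)
    for _ in range(10_000):
        counts[bank.position(select_first_item(bank, rng))] += 1
    freqs = counts / 10_000
    assert np.all((freqs >= 0.08) & (freqs <= 0.12))


def test_first_item_empty_bank_raises(pub_bank):
    with pytest.raises(MissingItemError):
        select_first_item(pub_bank, np.random.default_rng(0), candidates=[])


# -- EAP estimation ----------------------------------------------------------

def test_eap_empty_pattern_is_prior_mean(pub_bank):
    est = eap_estimate({}, pub_bank)
    assert est.theta == pytest.approx(0.0, abs=1e-12)
    assert est.information == 0.0 and not est.se_defined
    assert est.se == np.inf


def test_eap_sign_of_evidence():
    bank = ItemBank([ItemParameters("x", 2, 1.2, (0.0,))])
    assert eap_estimate({"x": 1}, bank).theta > 0
    assert eap_estimate({"x": 0}, bank).theta < 0


def test_eap_matches_dense_grid_oracle(pub_bank):
    from scipy.stats import norm
    from catdev.irt_models import _probs_grid
    pattern = {"2": 1, "87": 3, "98": 2, "100": 1, "9": 0}
    est = eap_estimate(pattern, pub_bank)
    z = np.linspace(-4, 4, 10_001)
    w = norm.pdf(z)
    L = np.ones_like(z)
    for iid, c in pattern.items():
        L *= _probs_grid(z, pub_bank[iid])[:, c]
    oracle = float((z * L * w).sum() / (L * w).sum())
    assert est.theta == pytest.approx(oracle, abs=1e-3)


def test_theta_estimate_identities():
    est = ThetaEstimate(theta=0.5, information=10.0, n_administered=12)
    assert est.se == pytest.approx(1 / np.sqrt(10))
    assert est.reliability == pytest.approx(1 - est.se ** 2)
    assert est.reliability == pytest.approx(0.9, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(codes=st.lists(st.integers(0, 1), min_size=1, max_size=11))
def test_eap_bounded_by_grid(pub_bank, codes):
    ids = pub_bank.item_ids[:len(codes)]
    est = eap_estimate(dict(zip(ids, codes)), pub_bank)
    assert -4.0 <= est.theta <= 4.0


# -- item selection ----------------------------------------------------------

def test_mfi_prefers_dominant_item():
    bank = ItemBank([ItemParameters("weak", 2, 0.58, (3.0,)),
                     ItemParameters("strong", 2, 2.19, (0.1,))])
    assert select_next_item(0.0, bank, set()) == "strong"


def test_mfi_equals_exhaustive_scan(pub_bank):
    rng = np.random.default_rng(3)
    for _ in range(20):
        theta = float(rng.uniform(-3, 3))
        used = set(rng.choice(pub_bank.item_ids, size=rng.integers(0, 20),
                              replace=False))
        got = select_next_item(theta, pub_bank, used)
        brute = max((i for i in pub_bank.item_ids if i not in used),
                    key=lambda i: item_information(theta, pub_bank[i]))
        assert got == brute


def test_mfi_tie_break_and_exhaustion():
    a = ItemParameters("first", 2, 1.3, (0.2,))
    b = ItemParameters("second", 2, 1.3, (0.2,))
    bank = ItemBank([a, b])
    assert select_next_item(0.0, bank, set()) == "first"
    assert select_next_item(0.0, bank, {"first", "second"}) is None


# -- stopping ----------------------------------------------------------------

def test_stop_check_rules():
    cfg = CATConfig(se_threshold=0.316, max_items=50)
    met = ThetaEstimate(0.0, 1 / 0.30 ** 2, 12)
    assert stop_check(met, cfg, remaining=10) == (True, "se_met")
    long = ThetaEstimate(0.0, 1 / 0.6 ** 2, 50)
    assert stop_check(long, cfg, remaining=10) == (True, "max_items")
    keep = ThetaEstimate(0.0, 1 / 0.40 ** 2, 10)
    assert stop_check(keep, cfg, remaining=5) == (False, None)
    assert stop_check(keep, cfg, remaining=0) == (True, "pool_exhausted")


# -- full administration -----------------------------------------------------

@pytest.fixture(scope="module")
def cohort_90():
    spec = CohortSpec(seed=13, n_persons=40)
    rng = np.random.default_rng(13)
    bank = make_item_bank(spec, rng)
    thetas = rng.normal(size=40)
    return bank, simulate_responses(bank, thetas, rng)


def test_unattainable_threshold_exhausts_pool(pub_bank):
    vec = [1] * 11 + [2] * 10
    cfg = CATConfig(se_threshold=1e-6, max_items=100, seed=0)
    rec = administer(vec, pub_bank, cfg)
    assert rec.stop_reason == "pool_exhausted"
    assert len(rec.administered) == 21
    assert len(set(rec.administered)) == 21


def test_information_strictly_accumulates(pub_bank):
    vec = [1] * 11 + [4] * 10       # highest categories on the 5-point items
    cfg = CATConfig(se_threshold=None, max_items=21, seed=1)
    rec = administer(vec, pub_bank, cfg)
    infos = [e.information for e in rec.interim]
    assert np.all(np.diff(infos) > 0)
    assert len(rec.interim) == len(rec.administered)


def test_administer_deterministic(cohort_90):
    bank, resp = cohort_90
    cfg = CATConfig(se_threshold=0.316, seed=9)
    r1 = administer(resp.codes[0], bank, cfg, rng=np.random.default_rng(9))
    r2 = administer(resp.codes[0], bank, cfg, rng=np.random.default_rng(9))
    assert r1.administered == r2.administered
    assert r1.final.theta == r2.final.theta


def test_se_met_implies_target_reliability(cohort_90):
    bank, resp = cohort_90
    cfg = CATConfig(se_threshold=0.447, seed=2)
    for rec in simulate_cat(resp, bank, cfg):
        if rec.stop_reason == "se_met":
            assert rec.final.reliability >= 0.80
        assert len(set(rec.administered)) == len(rec.administered)


def test_full_pool_matches_batch_eap(cohort_90):
    bank, resp = cohort_90
    cfg = CATConfig(se_threshold=None, max_items=len(bank), seed=3)
    rec = administer(resp.codes[5], bank, cfg, rng=np.random.default_rng(3))
    direct = eap_estimate(dict(zip(resp.item_ids, resp.codes[5])), bank)
    assert rec.final.theta == pytest.approx(direct.theta, abs=1e-10)
    assert rec.final.information == pytest.approx(direct.information, rel=1e-9)


def test_missingness_flag(pub_bank):
    vec = [MISSING] * 21
    for pos in range(5):
        vec[pos] = 1
    cfg = CATConfig(se_threshold=None, max_items=21, seed=0)
    rec = administer(vec, pub_bank, cfg)
    assert rec.high_missingness
    assert len(rec.administered) == 5
    assert rec.stop_reason == "pool_exhausted"
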