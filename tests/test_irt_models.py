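"""Category probabilities, information, and likelihood for the four models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catdev.errors import InvalidItemError, InvalidResponseError, MissingItemError
from catdev.irt_models import (MISSING, ItemBank, ItemParameters,
                               category_probs, item_information,
                               response_loglik)
from catdev.irt_models import test_information as total_information

# -- strategies -------------------------------------------------------------

slopes = st.floats(0.2, 2.5)
thetas = st.floats(-4.0, 4.0)


@st.composite
def grm_items(draw, k_min=2, k_max=5):
    K = draw(st.integers(k_min, k_max))
    a = draw(slopes)
    b1 = draw(st.floats(-3.0, 2.0))
    gaps = [draw(st.floats(0.2, 1.5)) for _ in range(K - 2)]
    b = tuple(np.concatenate([[b1], b1 + np.cumsum(gaps)])) if K > 2 else (b1,)
    return ItemParameters("h", K, a, b)


# -- category probabilities --------------------------------------------------

def test_dichotomous_probability_at_threshold(pub_bank):
    it = pub_bank["2"]                      # a=0.58, b=-0.07
    p = category_probs(-0.07, it)
    assert p[1] == pytest.approx(0.5, abs=1e-12)
    assert category_probs(0.0, it)[1] == pytest.approx(0.5101, abs=1e-4)


def test_five_category_probs_are_cumulative_differences(pub_bank):
    it = pub_bank["87"]                     # a=1.17, b=(-1.04, .29, 1.74, 3.76)
    p = category_probs(0.0, it)
    from scipy.special import expit
    star = expit(it.slope * (0.0 - np.array(it.thresholds)))
    expected = -np.diff(np.concatenate([[1.0], star, [0.0]]))
    assert p == pytest.approx(expected, abs=1e-12)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(item=grm_items(), theta=thetas)
def test_probability_simplex_grm(item, theta):
    p = category_probs(theta, item)
    assert np.all(p >= 0)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(item=grm_items(k_min=3), theta=thetas)
def test_grm_cumulative_monotonicity(item, theta):
    from scipy.special import expit
    star = expit(item.slope * (theta - np.array(item.thresholds)))
    assert np.all(np.diff(star) <= 1e-15)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(theta=thetas, a=slopes)
def test_pcm_equals_gpcm_with_unit_slope(theta, a):
    b = (-0.8, 0.1, 1.3)
    gpcm1 = ItemParameters("g", 4, 1.0, b, model="GPCM")
    pcm = ItemParameters("p", 4, 1.0, b, model="PCM")
    assert category_probs(theta, gpcm1) == pytest.approx(
        category_probs(theta, pcm), abs=1e-14)


def test_nrm_probabilities_normalize():
    it = ItemParameters("n", 4, model="NRM",
                        nrm_slopes=(0.0, 0.5, 1.1, 1.6),
                        nrm_intercepts=(0.0, 0.4, -0.2, -1.0))
    p = category_probs(0.7, it)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(p > 0)


def test_invalid_items_rejected():
    with pytest.raises(InvalidItemError):
        ItemParameters("x", 4, 1.0, (1.0, 0.5, 2.0))       # unordered
    with pytest.raises(InvalidItemError):
        ItemParameters("x", 1, 1.0, ())                    # K < 2
    with pytest.raises(InvalidItemError):
        ItemParameters("x", 3, 2.0, (0.0, 1.0), model="PCM")  # PCM slope != 1


# -- information -------------------------------------------------------------

def test_flat_item_carries_no_information():
    it = ItemParameters("z", 2, 0.0, (0.3,))
    for t in (-3.0, 0.0, 2.5):
        assert item_information(t, it) == pytest.approx(0.0, abs=1e-12)


def test_dichotomous_information_closed_form(pub_bank):
    it = pub_bank["2"]
    assert item_information(it.thresholds[0], it) == pytest.approx(
        0.58 ** 2 * 0.25, abs=1e-12)


@pytest.mark.parametrize("item_id", ["2", "9", "87", "94", "98"])
@pytest.mark.parametrize("theta", [-3.5, -1.0, 0.0, 1.4, 3.5])
def test_information_matches_central_difference(pub_bank, item_id, theta):
    it = pub_bank[item_id]
    h = 1e-5
    p0, p1 = category_probs(theta - h, it), category_probs(theta + h, it)
    pm = category_probs(theta, it)
    numeric = float(np.sum(((p1 - p0) / (2 * h)) ** 2 / pm))
    assert item_information(theta, it) == pytest.approx(numeric, abs=1e-6)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(a=slopes, b=st.floats(-2.0, 2.0), delta=st.floats(0.0, 3.0))
def test_information_symmetry_dichotomous(a, b, delta):
    it = ItemParameters("s", 2, a, (b,))
    assert item_information(b + delta, it) == pytest.approx(
        item_information(b - delta, it), rel=1e-9, abs=1e-12)


def test_test_information_additivity(pub_bank):
    theta = 1.0
    assert total_information(theta, pub_bank, []) == 0.0
    all_ids = pub_bank.item_ids
    brute = sum(item_information(theta, pub_bank[i]) for i in all_ids)
    assert total_information(theta, pub_bank, all_ids) == pytest.approx(brute)
    half = all_ids[:10]
    rest = all_ids[10:]
    assert (total_information(theta, pub_bank, half)
            + total_information(theta, pub_bank, rest)
            ) == pytest.approx(total_information(theta, pub_bank, all_ids))
    with pytest.raises(MissingItemError):
        total_information(theta, pub_bank, ["nope"])


def test_bank_vectorized_matches_per_item(pub_bank):
    grid = np.linspace(-4, 4, 9)
    P = pub_bank.prob_tensor(grid)
    for j, it in enumerate(pub_bank):
        assert P[:, j, :it.n_categories] == pytest.approx(
            np.vstack([category_probs(t, it) for t in grid]), abs=1e-12)
    info = pub_bank.information_at(0.8)
    assert info == pytest.approx(
        [item_information(0.8, it) for it in pub_bank], rel=1e-9)


# -- response log-likelihood -------------------------------------------------

def test_response_loglik(pub_bank):
    n = len(pub_bank)
    assert response_loglik([MISSING] * n, pub_bank, 0.3) == 0.0
    pattern = [MISSING] * n
    pattern[pub_bank.position("2")] = 1
    assert response_loglik(pattern, pub_bank, -0.07) == pytest.approx(np.log(0.5))
    pattern[pub_bank.position("87")] = 3
    pattern[pub_bank.position("98")] = 0
    total = sum(np.log(category_probs(0.9, pub_bank[i])[c])
                for i, c in [("2", 1), ("87", 3), ("98", 0)])
    assert response_loglik(pattern, pub_bank, 0.9) == pytest.approx(total)
    bad = [MISSING] * n
    bad[pub_bank.position("2")] = 5
    with pytest.raises(InvalidResponseError):
        response_loglik(bad, pub_bank, 0.0)


def test_duplicate_ids_rejected():
    it = ItemParameters("dup", 2, 1.0, (0.0,))
    with pytest.raises(InvalidItemError):
        ItemBank([it, it])
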