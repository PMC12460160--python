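"""Bayesian decoder closed forms, oracle equivalence, event scores and the
continuous-detection rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flightreplay import replay_bayes as rb


def product_form_oracle(counts, rates, tau):
    """Literal product-form posterior (no log space)."""
    f = np.maximum(np.asarray(rates, dtype=float), rb.RATE_FLOOR_HZ)
    post = np.prod(f ** np.asarray(counts)[:, None], axis=0) \
        * np.exp(-tau * rates.sum(axis=0))
    return post / post.sum()


# ---------------------------------------------------------------------------
# closed forms

def test_two_bin_one_spike_example():
    """One unit with f = [1, 3] Hz, tau = 20 ms, one spike:
    P ∝ [1·e^-0.02, 3·e^-0.06] ≈ [0.2576, 0.7424]."""
    rates = np.array([[1.0, 3.0]])
    p = rb.bayes_posterior(np.array([1.0]), rates, 0.02)
    expected = np.array([np.exp(-0.02), 3 * np.exp(-0.06)])
    expected /= expected.sum()
    np.testing.assert_allclose(p, expected, rtol=1e-12)
    np.testing.assert_allclose(p, [0.2576, 0.7424], atol=5e-5)


def test_two_bin_no_spike_example():
    rates = np.array([[1.0, 3.0]])
    p = rb.bayes_posterior(np.array([0.0]), rates, 0.02)
    expected = np.array([np.exp(-0.02), np.exp(-0.06)])
    expected /= expected.sum()
    np.testing.assert_allclose(p, expected, rtol=1e-12)


def test_constant_rates_uniform_posterior():
    rates = np.full((4, 30), 2.5)
    for n in ([0, 0, 0, 0], [3, 1, 0, 2]):
        p = rb.bayes_posterior(np.array(n, dtype=float), rates, 0.02)
        np.testing.assert_allclose(p, np.full(30, 1 / 30), rtol=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_log_space_equals_product_form(seed):
    rng = np.random.default_rng(seed)
    n_u = int(rng.integers(1, 8))
    n_b = int(rng.integers(2, 15))
    rates = rng.uniform(0, 10, (n_u, n_b))
    counts = rng.poisson(1.0, n_u).astype(float)
    p = rb.bayes_posterior(counts, rates, 0.02)
    np.testing.assert_allclose(p, product_form_oracle(counts, rates, 0.02),
                               atol=1e-10)


def test_uniform_posterior_spread_closed_form():
    """Discrete uniform over 30 bin centres: spread = sqrt(899/10800)."""
    P = np.full((5, 30), 1 / 30)
    s = rb.posterior_spread(P)
    np.testing.assert_allclose(s, np.sqrt(899 / 10800), rtol=1e-12)
    assert s[0] == pytest.approx(0.2885, abs=5e-5)


# ---------------------------------------------------------------------------
# decoding

def test_decode_columns_sum_to_one_and_mirror_counts():
    rng = np.random.default_rng(0)
    rates = rng.uniform(0, 8, (6, 30))
    resp = rb.SpatialResponseSet(np.arange(6), rates, 0, 10.0)
    trains = {i: np.sort(rng.uniform(0, 30, 40)) for i in range(6)}
    post = rb.decode_windows(trains, resp, np.arange(0, 29, 0.005), 0.02)
    np.testing.assert_allclose(post.P.sum(axis=1), 1.0, atol=1e-9)
    assert (post.P >= 0).all()


def test_silent_epoch_constant_posterior():
    rng = np.random.default_rng(1)
    rates = rng.uniform(0, 8, (6, 30))
    resp = rb.SpatialResponseSet(np.arange(6), rates, 0, 10.0)
    trains = {i: np.empty(0) for i in range(6)}
    post = rb.decode_windows(trains, resp, np.arange(0, 1, 0.005), 0.02)
    expected = rb.bayes_posterior(np.zeros(6), rates, 0.02)
    for row in post.P:
        np.testing.assert_allclose(row, expected, rtol=1e-9)


def test_single_field_spike_concentrates_posterior():
    rates = np.zeros((1, 30))
    rates[0, 12] = 8.0               # single-bin field
    resp = rb.SpatialResponseSet(np.array([0]), rates, 0, 10.0)
    post = rb.decode_windows({0: np.array([0.05])}, resp,
                             np.array([0.04]), 0.02)
    assert post.argmax[0] == 12
    assert post.P[0, 12] > 0.9


# ---------------------------------------------------------------------------
# event scores

def _delta_diagonal(n=30, reverse=False):
    P = np.full((n, n), 1e-12)
    for i in range(n):
        P[i, n - 1 - i if reverse else i] = 1.0
    return P / P.sum(axis=1, keepdims=True)


def test_scores_identity_diagonal():
    w, s, spread, cov = rb.event_scores(_delta_diagonal())
    assert w == pytest.approx(1.0, abs=1e-6)
    assert s == pytest.approx(1.0, abs=1e-6)
    assert cov == pytest.approx(1.0, abs=0.05)
    assert spread == pytest.approx(0.0, abs=1e-4)


def test_scores_reversed_diagonal_antisymmetric():
    w, s, spread, cov = rb.event_scores(_delta_diagonal(reverse=True))
    assert w == pytest.approx(-1.0, abs=1e-6)
    assert cov == pytest.approx(1.0, abs=0.05)


def test_wcorr_reduces_to_pearson_for_delta_columns():
    rng = np.random.default_rng(2)
    n = 20
    pos = rng.integers(0, 30, n)
    P = np.full((n, 30), 1e-12)
    P[np.arange(n), pos] = 1.0
    P /= P.sum(axis=1, keepdims=True)
    w = rb.weighted_correlation(P)
    r = np.corrcoef(np.arange(n), pos)[0, 1]
    assert w == pytest.approx(r, abs=1e-6)


def test_wcorr_zero_for_uniform():
    P = np.full((12, 30), 1 / 30)
    assert rb.weighted_correlation(P) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# continuous detection rules

def _post_from_P(P, step=0.005):
    return rb.PosteriorMatrix(times=np.arange(len(P)) * step + 0.01,
                              P=P, n_spikes=np.ones(len(P), dtype=int),
                              length_m=10.0)


def test_uniform_posterior_masked_by_peak_rule():
    # spread 0.2885 < 0.3 but max = mean fails the 3x-average rule
    post = _post_from_P(np.full((100, 30), 1 / 30))
    assert rb.segment_candidates(post) == []


def test_short_island_and_merge_rules():
    n = 200
    P = np.full((n, 30), 1 / 30)
    # two high-confidence islands, 60 ms apart -> merged into one segment
    for i0 in (50, 82):              # 20 bins = 100 ms each, gap 12 bins
        for k in range(20):
            P[i0 + k] = 1e-6
            P[i0 + k, (k * 3 // 2) % 30] = 1.0
    P /= P.sum(axis=1, keepdims=True)
    segs = rb.segment_candidates(_post_from_P(P))
    assert len(segs) == 1
    a, b = segs[0]
    assert a == 50 and b == 102
    # a 4-bin (20 ms < 25 ms) island alone is excluded
    P2 = np.full((n, 30), 1 / 30)
    for k in range(4):
        P2[100 + k] = 1e-6
        P2[100 + k, 5] = 1.0
    P2 /= P2.sum(axis=1, keepdims=True)
    assert rb.segment_candidates(_post_from_P(P2)) == []


def test_refine_deterministic_and_spans_linear_core():
    rng_p = np.random.default_rng(3)
    n = 80
    P = np.full((n, 30), 1e-6)
    for i in range(n):
        P[i, int(i * 29 / (n - 1))] = 1.0
    P += rng_p.uniform(0, 1e-4, P.shape)
    P /= P.sum(axis=1, keepdims=True)
    post = _post_from_P(P)
    seg = rb.segment_candidates(post)[0]
    r1 = rb.refine_event(post, seg, np.random.default_rng(7))
    r2 = rb.refine_event(post, seg, np.random.default_rng(7))
    assert r1 == r2
    i0, i1 = r1
    assert (i1 - i0) >= 0.5 * (seg[1] - seg[0])


def test_shuffles_preserve_column_sums_and_gate_diagonal():
    P = _delta_diagonal(40)
    # smooth the diagonal a little so circular shifts can't recreate it
    from scipy.ndimage import gaussian_filter1d
    P = gaussian_filter1d(P, 1.5, axis=1, mode="wrap")
    P /= P.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(4)
    p_col, p_time = rb.shuffle_significance(P, rng, n_shuffle=100)
    assert p_col <= 0.01 and p_time <= 0.01


def test_shuffle_null_calibrated_on_noise_posteriors():
    """Events made of random confident columns: both shuffle p values are
    approximately uniform (fraction < 0.05 within [0.02, 0.10])."""
    rng = np.random.default_rng(5)
    n_sig_col = n_sig_time = 0
    N = 200
    for _ in range(N):
        n = 30
        pos = rng.integers(0, 30, n)
        P = np.full((n, 30), 1e-3)
        P[np.arange(n), pos] = 1.0
        P /= P.sum(axis=1, keepdims=True)
        p_col, p_time = rb.shuffle_significance(P, rng, n_shuffle=40)
        n_sig_col += p_col < 0.05
        n_sig_time += p_time < 0.05
    assert 0.0 <= n_sig_col / N <= 0.10
    assert 0.0 <= n_sig_time / N <= 0.10


def test_decoded_speed_is_length_over_duration():
    assert rb.decoded_replay_speed(10.0, 0.4) == pytest.approx(25.0)
    assert rb.decoded_replay_speed(5.0, 0.4) == pytest.approx(12.5)
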