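import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wnphase.errors import InvalidInputError
from wnphase.phase_opposition import (
    correct_multiple,
    grand_average_pos,
    itpc,
    largest_cluster_latency,
    median_latency_ci,
    phase_binned_performance,
    pos,
    surrogate_pos,
    surrogate_pos_samples,
)


# ---------------------------------------------------------------------------
# ITPC and POS
# ---------------------------------------------------------------------------

def test_itpc_endpoints_and_null_expectation(rng):
    assert itpc(np.full(50, 1.3)) == pytest.approx(1.0)
    assert itpc(np.array([0.0, np.pi] * 25)) == pytest.approx(0.0, abs=1e-12)
    # Rayleigh null: E[ITPC] ~ sqrt(pi)/(2 sqrt(n)); oracle = direct simulation
    n, reps = 1000, 3000
    vals = np.abs(np.exp(1j * rng.uniform(-np.pi, np.pi, (reps, n))).mean(axis=1))
    expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
    se = vals.std() / np.sqrt(reps)
    assert abs(vals.mean() - expected) < 3 * se


def test_pos_endpoints():
    n = 200
    phases = np.r_[np.zeros(n // 2), np.full(n // 2, np.pi)]
    labels = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
    assert pos(phases, labels) == pytest.approx(2.0)
    assert pos(np.full(n, 0.4), labels) == pytest.approx(0.0, abs=1e-12)


def test_pos_null_is_centred_on_its_permutation_mean(rng):
    """Under the null the observed POS is exchangeable with its surrogates,
    so POS minus the surrogate mean averages ~0 (raw POS itself carries a
    positive finite-sample offset of order 1/sqrt(n))."""
    reps, n = 2000, 100
    labels = np.zeros(n, bool)
    labels[: n // 2] = True
    phases = rng.uniform(-np.pi, np.pi, (n, reps))
    res = surrogate_pos(phases, labels, n_perm=400, seed=3)
    centred = np.asarray(res.pos) - np.asarray(res.surrogate_mean)
    se = centred.std() / np.sqrt(reps)
    assert abs(centred.mean()) < 3 * se
    # and the raw null mean matches the Rayleigh prediction, not zero
    pred = np.sqrt(np.pi) / 2 * (2 / np.sqrt(n / 2) - 2 / np.sqrt(n))
    assert np.asarray(res.pos).mean() == pytest.approx(pred, rel=0.1)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(rot=st.floats(-np.pi, np.pi), seed=st.integers(0, 10 ** 6))
def test_itpc_rotation_and_pos_label_swap(rot, seed):
    rng = np.random.default_rng(seed)
    phases = rng.uniform(-np.pi, np.pi, 60)
    labels = rng.random(60) < 0.5
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    assert itpc(phases + rot) == pytest.approx(itpc(phases), abs=1e-10)
    assert pos(phases, labels) == pytest.approx(pos(phases, ~labels), abs=1e-12)


# ---------------------------------------------------------------------------
# Surrogates
# ---------------------------------------------------------------------------

def test_surrogate_pos_perfect_opposition_is_extreme():
    n = 400
    phases = np.r_[np.zeros(n // 2), np.full(n // 2, np.pi)]
    labels = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
    res = surrogate_pos(phases, labels, n_perm=1000, seed=0)
    assert res.p < 1e-6
    assert res.pos == pytest.approx(2.0)


def test_surrogate_pos_calibration_under_null():
    """Type-I error = alpha +/- 1% and z ~ N(0, 1) across null datasets."""
    reps, n = 2000, 150
    rng = np.random.default_rng(99)
    labels = np.zeros(n, bool)
    labels[: n // 2] = True
    zs, ps = [], []
    for block in range(2):
        phases = rng.uniform(-np.pi, np.pi, (n, reps // 2))
        res = surrogate_pos(phases, labels, n_perm=500, seed=block)
        zs.append(np.asarray(res.z))
        ps.append(np.asarray(res.p))
    zs, ps = np.concatenate(zs), np.concatenate(ps)
    assert -0.1 < zs.mean() < 0.1
    assert 0.9 < zs.std() < 1.1
    assert abs((ps < 0.05).mean() - 0.05) <= 0.01


def test_surrogate_pos_power_at_injected_modulation():
    """Cosine-modulated outcomes at n=500: z > 3 in >= 90% of datasets."""
    n, reps = 500, 60
    rng = np.random.default_rng(5)
    hits = 0
    for i in range(reps):
        phases = rng.uniform(-np.pi, np.pi, n)
        labels = rng.random(n) < 0.5 * (1 + 0.4 * np.cos(phases))
        if labels.all() or not labels.any():
            continue
        res = surrogate_pos(phases, labels, n_perm=500, seed=i)
        hits += res.z > 3
    assert hits >= 0.9 * reps


def test_grand_average_reduces_to_single_subject():
    rng = np.random.default_rng(11)
    phases = rng.uniform(-np.pi, np.pi, 300)
    labels = rng.random(300) < 0.5 * (1 + 0.4 * np.cos(phases))
    obs, surr = surrogate_pos_samples(phases, labels, n_perm=800, seed=1)
    single = surrogate_pos(phases, labels, n_perm=800, seed=1)
    grand = grand_average_pos([obs], [surr], n_resample=20000, seed=2)
    assert float(grand.z) == pytest.approx(float(single.z), abs=0.25)


def test_grand_average_gains_over_single_subjects():
    """Aggregating subjects sharing an effect beats every single subject."""
    rng = np.random.default_rng(21)
    wins = 0
    runs = 10
    for r in range(runs):
        obs_list, surr_list, zs = [], [], []
        for s in range(8):
            phases = rng.uniform(-np.pi, np.pi, 150)
            labels = rng.random(150) < 0.5 * (1 + 0.25 * np.cos(phases))
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            obs, surr = surrogate_pos_samples(phases, labels, n_perm=300,
                                              seed=100 * r + s)
            zs.append(float(surrogate_pos(phases, labels, n_perm=300,
                                          seed=100 * r + s).z))
            obs_list.append(obs)
            surr_list.append(surr)
        grand = grand_average_pos(obs_list, surr_list, n_resample=5000,
                                  seed=r)
        wins += float(grand.z) > max(zs)
    assert wins >= 0.8 * runs


# ---------------------------------------------------------------------------
# Corrections, clusters, CIs
# ---------------------------------------------------------------------------

def _bh_reference(p, alpha):
    """Brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = np.flatnonzero(p[order] <= thresh)
    mask = np.zeros(m, bool)
    if passed.size:
        mask[order[: passed[-1] + 1]] = True
    return mask


def test_bonferroni_threshold_and_degenerate_masks():
    p = np.full(170, 2.95e-4)
    assert not correct_multiple(p, "bonferroni", 0.05).any()
    p = np.full(170, 2.93e-4)
    assert correct_multiple(p, "bonferroni", 0.05).all()
    assert not correct_multiple(np.ones(40), "fdr_bh", 0.05).any()


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=300),
       st.sampled_from([0.01, 0.05, 0.1]))
def test_fdr_matches_brute_force_bh(p, alpha):
    p = np.asarray(p)
    assert np.array_equal(correct_multiple(p, "fdr_bh", alpha),
                          _bh_reference(p, alpha))


def _brute_force_cluster(mask, times):
    best = (0, None)
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            if j - i > best[0]:
                best = (j - i, float(np.mean(times[i:j])))
            i = j
        else:
            i += 1
    return best[1]


def test_largest_cluster_examples():
    t = np.arange(0, 100, 2.0)
    mask = (t >= 30) & (t <= 50)
    assert largest_cluster_latency(mask, t) == pytest.approx(40.0)
    mask = ((t >= 0) & (t < 10)) | ((t >= 40) & (t < 58))
    assert largest_cluster_latency(mask, t) == pytest.approx(np.mean(t[(t >= 40) & (t < 58)]))
    assert np.isnan(largest_cluster_latency(np.zeros_like(t, bool), t))


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.lists(st.booleans(), min_size=1, max_size=60))
def test_largest_cluster_matches_enumeration(bits):
    mask = np.asarray(bits, bool)
    times = np.arange(mask.size) * 5.0 - 100.0
    expected = _brute_force_cluster(mask, times)
    got = largest_cluster_latency(mask, times)
    if expected is None:
        assert np.isnan(got)
    else:
        assert got == pytest.approx(expected)


def test_median_ci_frozen_values():
    d = median_latency_ci(np.full(30, 12.5))
    assert (d.ci_low, d.median, d.ci_high) == (12.5, 12.5, 12.5)
    # 1..100 with type-7 quartiles: q1=25.75, q2=50.5, q3=75.25
    d = median_latency_ci(np.arange(1.0, 101.0))
    assert d.median == pytest.approx(50.5)
    half = 1.7 * 1.25 * (75.25 - 25.75) / (1.35 * 10.0)
    assert d.ci_low == pytest.approx(50.5 - half)
    assert d.ci_high == pytest.approx(50.5 + half)
    assert half == pytest.approx(7.7917, abs=1e-4)
    with pytest.raises(InvalidInputError):
        median_latency_ci(np.array([1.0]))


# ---------------------------------------------------------------------------
# Phase-binned performance
# ---------------------------------------------------------------------------

def test_phase_binning_null_and_recovery(rng):
    n = 40_000
    phases = rng.uniform(-np.pi, np.pi, n)
    flat = rng.random(n) < 0.5
    curve = phase_binned_performance(phases, flat)
    assert curve.bin_centers.size == 11
    assert curve.cosine_amp_percent < 2.0
    assert np.nanmean(curve.normalized_hit_ratio) == pytest.approx(1.0, abs=0.05)
    # generative recovery: P(hit) = 0.5 (1 + 0.4 cos(theta)) -> 40% modulation
    hits = rng.random(n) < 0.5 * (1 + 0.4 * np.cos(phases))
    curve = phase_binned_performance(phases, hits)
    assert curve.cosine_amp_percent == pytest.approx(40.0, rel=0.3)
    assert abs(curve.cosine_phase0) < 0.5
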