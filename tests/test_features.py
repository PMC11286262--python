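"""The 12 spike-train parameters, their oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spikesig as sg
from spikesig.core_io import SpikeTrain
from spikesig.features import (
    InsufficientDataError,
    autocorrelogram,
    cv,
    cv2,
    interburst_pause,
    isi_fraction_above,
    isi_sequence,
    mean_ifr,
    median_ifr,
    mode_fraction,
    rhythmicity,
    skewness_stat,
)

isi_lists = st.lists(st.floats(0.5, 500.0, allow_nan=False), min_size=2,
                     max_size=60)


# ---------------------------------------------------------------------------
# scalar ISI features
# ---------------------------------------------------------------------------

def test_isi_sequence_in_ms():
    t = SpikeTrain("c", np.array([0.010, 0.020, 0.040]))
    np.testing.assert_allclose(isi_sequence(t), [10.0, 20.0])
    t2 = SpikeTrain("c", np.array([0.0, 30.0]), duration=30.0)
    np.testing.assert_allclose(isi_sequence(t2), [30000.0])
    with pytest.raises(InsufficientDataError):
        isi_sequence(SpikeTrain("c", np.array([1.0])))


@pytest.mark.parametrize("n_spikes,expected", [(2400, 80.0), (0, 0.0), (90, 3.0)])
def test_firing_rate(n_spikes, expected):
    t = SpikeTrain("c", np.linspace(0.01, 29.99, n_spikes), duration=30.0)
    assert sg.firing_rate(t) == pytest.approx(expected)


def test_ifr_small_cases():
    assert mean_ifr([10.0, 20.0]) == pytest.approx(75.0)
    assert median_ifr([10.0, 20.0]) == pytest.approx(75.0)
    assert median_ifr([10.0, 20.0, 40.0]) == pytest.approx(50.0)


def test_ifr_matches_elementwise_oracle():
    rng = np.random.default_rng(1)
    isis = rng.gamma(2.0, 10.0, 1000)  # ms
    inv = np.array([1000.0 / x for x in isis])  # explicit elementwise oracle
    assert mean_ifr(isis) == pytest.approx(inv.mean())
    assert median_ifr(isis) == pytest.approx(np.median(inv))


def test_cv_cases():
    assert cv([10.0] * 8) == 0.0
    # sample SD of [10,20,10,20] = sqrt(100/3), mean 15
    assert cv([10.0, 20.0, 10.0, 20.0]) == pytest.approx(
        np.sqrt(100.0 / 3.0) / 15.0, abs=1e-12)


def test_cv_exponential_limit():
    rng = np.random.default_rng(12345)
    isis = rng.exponential(12.0, 100_000)
    assert cv(isis) == pytest.approx(1.0, abs=0.02)


def test_cv2_cases():
    assert cv2([10.0] * 5) == 0.0
    assert cv2([10.0, 20.0, 10.0, 20.0]) == pytest.approx(2.0 / 3.0)


@settings(derandomize=True, max_examples=50)
@given(isi_lists)
def test_cv2_equals_pairwise_oracle(isis):
    acc = [2.0 * abs(isis[i] - isis[i - 1]) / (isis[i] + isis[i - 1])
           for i in range(1, len(isis))]
    assert cv2(isis) == pytest.approx(float(np.mean(acc)))
    assert 0.0 <= cv2(isis) < 2.0


def test_skewness_stat():
    assert skewness_stat(80.0, 80.0) == 0.0
    assert skewness_stat(100.0, 30.0) == pytest.approx(140.0 / 130.0)
    # antisymmetric under exchange of the two rates
    assert skewness_stat(30.0, 100.0) == pytest.approx(-140.0 / 130.0)
    with pytest.raises(ValueError):
        skewness_stat(0.0, 0.0)


def test_isi_fraction_above_strict():
    isis = [10.0, 20.0, 30.0, 40.0]
    assert isi_fraction_above(isis, 25.0) == 50.0
    assert isi_fraction_above(isis, 100.0) == 0.0
    assert isi_fraction_above(isis, 0.0) == 100.0
    assert isi_fraction_above([10.0, 25.0], 25.0) == 0.0  # strict >


def test_interburst_pause_filter_then_mean():
    isis = [10.0] * 9 + [1000.0]  # mean 109, cutoff 545
    assert interburst_pause(isis) == pytest.approx(1000.0)
    assert interburst_pause([12.0] * 20) == 0.0
    assert interburst_pause([10.0, 10.0, 10.0, 100.0]) == 0.0  # cutoff 162.5


def test_mode_fraction_1ms_bins():
    assert mode_fraction([10.2, 10.9, 20.0, 30.0]) == 50.0
    assert mode_fraction([7.5] * 6) == 100.0
    assert mode_fraction([10.0, 20.0]) == 50.0  # tie -> smallest bin, still 50%


# ---------------------------------------------------------------------------
# autocorrelogram
# ---------------------------------------------------------------------------

def ac_pair_oracle(timestamps_s, bin_ms=5.0, max_lag_ms=1000.0):
    """O(n^2) double-loop pair counting."""
    t = np.asarray(timestamps_s) * 1000.0
    n_bins = int(max_lag_ms / bin_ms)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(len(t)):
        for j in range(i + 1, len(t)):
            lag = t[j] - t[i]
            if lag >= max_lag_ms:
                break
            counts[int(lag // bin_ms)] += 1
    return counts


def test_autocorrelogram_two_spikes():
    ac = autocorrelogram(SpikeTrain("c", np.array([0.0, 0.012])))
    assert ac.counts[2] == 1  # bin [10, 15) ms
    assert ac.counts.sum() == 1
    assert ac.lags_ms.size == 200


@pytest.mark.parametrize("maker", [
    lambda rng: np.sort(rng.uniform(0, 30, 2000)),                    # Poisson
    lambda rng: np.cumsum(rng.gamma(3, 0.012 / 3, 1500))[:1200],      # gamma renewal
    lambda rng: np.arange(1, 1800) * 0.0167,                          # periodic
])
def test_autocorrelogram_equals_pair_oracle(maker):
    ts = maker(np.random.default_rng(3))
    ts = ts[ts < 30.0]
    ac = autocorrelogram(SpikeTrain("c", ts))
    np.testing.assert_array_equal(ac.counts, ac_pair_oracle(ts))


def test_autocorrelogram_tail_statistics_definition():
    rng = np.random.default_rng(9)
    ts = np.sort(rng.uniform(0, 30, 1200))
    ac = autocorrelogram(SpikeTrain("c", ts))
    tail = ac.counts[192:200].astype(float)
    assert ac.baseline == pytest.approx(tail.mean())
    assert ac.tail_sd == pytest.approx(tail.std(ddof=1))
    # homogeneous Poisson: tail bins hover around baseline
    assert np.all(np.abs(tail - ac.baseline) <= 4 * ac.tail_sd + 1e-9)


# ---------------------------------------------------------------------------
# rhythmicity
# ---------------------------------------------------------------------------

def rhythmicity_oracle(ac, mean_isi_ms):
    """Independent re-implementation of the peak/trough walk."""
    lags, counts = list(ac.lags_ms), list(ac.counts.astype(float))
    base, sd = ac.baseline, ac.tail_sd

    def arg_best(lo, hi, lo_open, want_max):
        cand = [k for k, l in enumerate(lags)
                if (l > lo if lo_open else l >= lo) and l <= hi]
        if not cand:
            return None
        key = (max if want_max else min)(cand, key=lambda k: counts[k])
        # ties resolved to the lowest lag, as argmax/argmin do
        best = [k for k in cand if counts[k] == counts[key]]
        return min(best)

    cand = [k for k, l in enumerate(lags) if 10.0 <= l < 1.5 * mean_isi_ms]
    if not cand:
        return 0.0, 0
    peak = max(cand, key=lambda k: (counts[k], -k))
    peak = min(k for k in cand if counts[k] == counts[peak])
    lag1 = lags[peak]
    z = abs(ac.n_spikes - base)
    total, n_acc = 0.0, 0
    while True:
        a = counts[peak] - base
        trough = arg_best(lags[peak], lags[peak] + lag1, True, want_max=False)
        if trough is None:
            break
        b = base - counts[trough]
        ok = (a + b > 4 * sd) or (counts[peak] > base + 2 * sd
                                  and counts[trough] < base - 2 * sd)
        if not ok:
            break
        n_acc += 1
        total += a + b
        nxt = arg_best(lags[trough], lags[peak] + lag1 + 10.0, True, want_max=True)
        if nxt is None:
            break
        peak = nxt
    return (total / z if z > 0 else 0.0), n_acc


def _train(kind, seed=5):
    rng = np.random.default_rng(seed)
    if kind == "regular25":
        ts = np.cumsum(rng.gamma(40.0, 0.040 / 40, 2000))
    elif kind == "ataxia":
        return sg.generate_train("ataxia", seed=seed)
    elif kind == "tremor":
        return sg.generate_train("tremor", seed=seed)
    elif kind == "poisson":
        ts = np.sort(rng.uniform(0, 30, 2400))
    return SpikeTrain(kind, ts[ts < 30.0], duration=30.0)


@pytest.mark.parametrize("kind", ["regular25", "ataxia", "tremor", "poisson"])
def test_rhythmicity_equals_independent_oracle(kind):
    tr = _train(kind)
    ac = autocorrelogram(tr)
    mean_isi = float(np.mean(isi_sequence(tr)))
    ri, n_peaks, _ = rhythmicity(ac, mean_isi)
    ri_o, n_o = rhythmicity_oracle(ac, mean_isi)
    assert n_peaks == n_o
    assert ri == pytest.approx(ri_o)


def test_rhythmicity_flat_autocorrelogram():
    ac = sg.Autocorrelogram(5.0, np.arange(200) * 5.0,
                            np.full(200, 40), 40.0, 0.0, 1200)
    ri, n, pts = rhythmicity(ac, 25.0)
    assert (ri, n) == (0.0, 0)


def test_rhythmicity_empty_first_window_flagged():
    ac = sg.Autocorrelogram(5.0, np.arange(200) * 5.0,
                            np.full(200, 40), 40.0, 1.0, 1200)
    ri, n, pts = rhythmicity(ac, 6.0)  # 1.5 * 6 ms = 9 ms <= 10 ms
    assert (ri, n) == (0.0, 0)
    assert pts.flagged


def test_rhythmicity_regular_train_finds_period_peaks():
    tr = _train("regular25", seed=11)
    ac = autocorrelogram(tr)
    mean_isi = float(np.mean(isi_sequence(tr)))
    ri, n_peaks, pts = rhythmicity(ac, mean_isi)
    assert n_peaks >= 3
    assert ri > 0
    accepted = [p for p, a in zip(pts.peaks, pts.accepted) if a]
    # first accepted peak within one bin of the 40-ms period
    assert abs(accepted[0][0] - 40.0) <= 5.0
    # peak spacing near the period
    spacings = np.diff([p[0] for p in accepted[:3]])
    assert np.all(np.abs(spacings - 40.0) <= 10.0)


def test_rhythmicity_noise_free_periodic_train_tail_is_not_noise(regular_train):
    # A noise-free periodic train keeps full-height correlation at 1-s lags,
    # so the tail SD is of the order of the peaks themselves and the
    # acceptance rule cannot fire. This freezes that boundary behavior.
    ac = autocorrelogram(regular_train)
    ri, n, _ = rhythmicity(ac, 15.625)
    assert ac.tail_sd > ac.baseline / 2
    assert (ri, n) == (0.0, 0)


# ---------------------------------------------------------------------------
# featurize
# ---------------------------------------------------------------------------

def test_featurize_regular_train_closed_forms(regular_train):
    f = sg.featurize(regular_train)
    assert f.firing_rate == pytest.approx(64.0)
    assert f.cv == pytest.approx(0.0, abs=1e-9)
    assert f.cv2 == pytest.approx(0.0, abs=1e-9)
    assert f.skewness == pytest.approx(0.0, abs=1e-9)
    assert f.isi25 == 0.0
    assert f.isi100 == 0.0
    assert f.interburst_pause == 0.0
    assert f.mode_fraction == 100.0


def test_featurize_matches_componentwise_oracle():
    tr = sg.generate_train("dystonia", seed=1)
    f = sg.featurize(tr)
    isis = isi_sequence(tr)
    assert f.firing_rate == pytest.approx(sg.firing_rate(tr))
    assert f.mean_ifr == pytest.approx(mean_ifr(isis))
    assert f.median_ifr == pytest.approx(median_ifr(isis))
    assert f.cv == pytest.approx(cv(isis))
    assert f.cv2 == pytest.approx(cv2(isis))
    assert f.skewness == pytest.approx(
        skewness_stat(median_ifr(isis), sg.firing_rate(tr)))
    assert f.isi25 == pytest.approx(isi_fraction_above(isis, 25.0))
    assert f.isi100 == pytest.approx(isi_fraction_above(isis, 100.0))
    assert f.interburst_pause == pytest.approx(interburst_pause(isis))
    assert f.mode_fraction == pytest.approx(mode_fraction(isis))
    ri, n_peaks, _ = rhythmicity(autocorrelogram(tr), float(np.mean(isis)))
    assert f.rhythmicity_index == pytest.approx(ri)
    assert f.oscillation_peaks == n_peaks


def test_featurize_requires_30s_unless_overridden():
    ts = np.linspace(0.01, 9.99, 500)
    tr = SpikeTrain("c", ts, duration=10.0)
    with pytest.raises(ValueError, match="duration"):
        sg.featurize(tr)
    f = sg.featurize(tr, require_30s=False)
    assert f.firing_rate == pytest.approx(50.0)


def test_time_shift_invariance():
    tr = sg.generate_train("control", seed=2)
    ts = tr.timestamps[tr.timestamps < 29.8]  # room to shift within duration
    base = SpikeTrain(tr.cell_id, ts, 30.0)
    shifted = SpikeTrain(tr.cell_id, ts + 0.1, 30.0)
    f0 = sg.featurize(base).values()
    f1 = sg.featurize(shifted).values()
    # firing rate unchanged (same count), all ISI features identical
    np.testing.assert_allclose(f1, f0, rtol=1e-12)


def test_isi_halving_scale_check():
    tr = sg.generate_train("control", seed=4)
    half = SpikeTrain(tr.cell_id, tr.timestamps / 2.0, tr.duration / 2.0)
    isis, isis_h = isi_sequence(tr), isi_sequence(half)
    assert np.mean(isis_h) == pytest.approx(np.mean(isis) / 2)
    assert mean_ifr(isis_h) == pytest.approx(2 * mean_ifr(isis))
    assert median_ifr(isis_h) == pytest.approx(2 * median_ifr(isis))
    assert sg.firing_rate(half) == pytest.approx(2 * sg.firing_rate(tr), rel=1e-3)
    for fn in (cv, cv2):
        assert fn(isis_h) == pytest.approx(fn(isis))
    assert skewness_stat(median_ifr(isis_h), 2 * sg.firing_rate(tr)) == \
        pytest.approx(skewness_stat(median_ifr(isis), sg.firing_rate(tr)), abs=1e-9)


@settings(derandomize=True, max_examples=60)
@given(isi_lists)
def test_scalar_feature_invariants(isis):
    a = np.asarray(isis)
    assert isi_fraction_above(a, 100.0) <= isi_fraction_above(a, 25.0)
    assert 0.0 <= cv2(a) < 2.0
    assert cv(a) >= 0.0
    assert 0.0 < mode_fraction(a) <= 100.0
    s = skewness_stat(median_ifr(a), mean_ifr(a))
    assert -2.0 < s < 2.0
    for fn in (mean_ifr, median_ifr, cv, cv2, interburst_pause, mode_fraction):
        assert np.isfinite(fn(a))
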