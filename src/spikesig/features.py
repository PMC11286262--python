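"""The 12 spike-train parameters.

Ten scalar statistics are computed directly from the interspike-interval (ISI)
sequence; the remaining two (rhythmicity index and oscillation-peak count) come
from an autocorrelogram-based oscillation analysis.

Units: timestamps enter in seconds; ISIs are carried in milliseconds;
instantaneous firing rates (IFR = 1/ISI) are in Hz; the ISI-fraction features
(`isi25`, `isi100`, `mode_fraction`) are percentages 0-100.

Definitions
-----------
firing_rate        spike count / recording duration (spikes/s)
mean_ifr           mean(1/ISI) (Hz)
median_ifr         median(1/ISI) (Hz)
cv                 stdev(ISI) / mean(ISI)  (sample SD, n-1)
cv2                mean over consecutive pairs of 2|ISI_n - ISI_{n-1}| / (ISI_n + ISI_{n-1})
skewness           2 (median_ifr - firing_rate) / (median_ifr + firing_rate)
isi25, isi100      % of ISIs strictly greater than 25 ms / 100 ms
interburst_pause   mean of ISIs exceeding 5x the mean ISI (ms); 0 if none
mode_fraction      % of ISIs falling in the modal 1-ms histogram bin
rhythmicity_index  sum of accepted autocorrelogram peak heights + trough depths,
                   normalized by |n_spikes - baseline|
oscillation_peaks  number of accepted autocorrelogram peaks

The `skewness` here is not the statistical third moment: it contrasts the
typical instantaneous rate (median IFR) against the mean rate and is large and
positive for bursty trains. Likewise `mode_fraction` is a modal mass fraction,
not the statistical kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import FeatureVector, SpikeTrain, validate_train

__all__ = [
    "InsufficientDataError",
    "ISISequence",
    "Autocorrelogram",
    "PeakTroughSet",
    "isi_sequence",
    "firing_rate",
    "mean_ifr",
    "median_ifr",
    "cv",
    "cv2",
    "skewness_stat",
    "isi_fraction_above",
    "interburst_pause",
    "mode_fraction",
    "autocorrelogram",
    "rhythmicity",
    "featurize",
]

MS_PER_S = 1000.0


class InsufficientDataError(ValueError):
    """Too few spikes/intervals for the requested statistic."""


def _as_isi_array(isis) -> np.ndarray:
    a = np.asarray(isis, dtype=float)
    if a.size == 0:
        raise InsufficientDataError("empty ISI sequence")
    if np.any(a <= 0):
        raise ValueError("non-positive ISI")
    return a


#: Alias used in type hints: an ISI sequence is a 1-D float array in ms.
ISISequence = np.ndarray


def isi_sequence(train: SpikeTrain) -> np.ndarray:
    """Interspike intervals in milliseconds."""
    if train.n_spikes < 2:
        raise InsufficientDataError(
            f"cell {train.cell_id!r}: {train.n_spikes} spike(s), need >= 2")
    return np.diff(train.timestamps) * MS_PER_S


def firing_rate(train: SpikeTrain) -> float:
    """Mean firing rate: spike count over recording duration (spikes/s)."""
    if train.duration <= 0:
        raise ValueError("non-positive duration")
    return train.n_spikes / train.duration


def mean_ifr(isis) -> float:
    """Mean instantaneous firing rate, mean(1/ISI), in Hz."""
    a = _as_isi_array(isis)
    return float(np.mean(MS_PER_S / a))


def median_ifr(isis) -> float:
    """Median instantaneous firing rate, median(1/ISI), in Hz."""
    a = _as_isi_array(isis)
    return float(np.median(MS_PER_S / a))


def cv(isis) -> float:
    """Coefficient of variation of the ISIs (sample SD over mean)."""
    a = _as_isi_array(isis)
    if a.size < 2:
        raise InsufficientDataError("CV needs >= 2 intervals")
    return float(np.std(a, ddof=1) / np.mean(a))


def cv2(isis) -> float:
    """Local irregularity: mean of 2|ISI_n - ISI_{n-1}| / (ISI_n + ISI_{n-1}).

    Rate-robust; 0 for a regular train, ~1 for a Poisson train, < 2 always.
    """
    a = _as_isi_array(isis)
    if a.size < 2:
        raise InsufficientDataError("CV2 needs >= 2 intervals")
    x, y = a[1:], a[:-1]
    return float(np.mean(2.0 * np.abs(x - y) / (x + y)))


def skewness_stat(median_ifr_hz: float, firing_rate_hz: float) -> float:
    """2 (median IFR - firing rate) / (median IFR + firing rate), in (-2, 2)."""
    denom = median_ifr_hz + firing_rate_hz
    if denom == 0:
        raise ValueError("median IFR + firing rate is zero")
    return 2.0 * (median_ifr_hz - firing_rate_hz) / denom


def isi_fraction_above(isis, threshold_ms: float) -> float:
    """Percent of ISIs strictly greater than ``threshold_ms``."""
    a = _as_isi_array(isis)
    return float(100.0 * np.mean(a > threshold_ms))


def interburst_pause(isis) -> float:
    """Mean of ISIs exceeding 5x the mean ISI (ms); 0.0 when none qualify."""
    a = _as_isi_array(isis)
    cut = 5.0 * np.mean(a)
    sel = a[a > cut]
    return float(np.mean(sel)) if sel.size else 0.0


def mode_fraction(isis) -> float:
    """Percent of ISIs in the modal 1-ms bin [k, k+1) ms; ties -> smallest bin."""
    a = _as_isi_array(isis)
    bins = np.floor(a).astype(np.int64)
    counts = np.bincount(bins)
    return float(100.0 * counts.max() / a.size)


# ---------------------------------------------------------------------------
# Autocorrelogram and oscillation analysis
# ---------------------------------------------------------------------------

@dataclass
class Autocorrelogram:
    """Forward-lag spike-pair histogram with tail-noise statistics.

    counts[k] is the number of ordered spike pairs (i < j) whose lag falls in
    [k*bin, (k+1)*bin) ms. The baseline and tail SD are taken over the bins
    covering the 960-1000 ms tail window, the reference region for noise.
    """

    bin_ms: float
    lags_ms: np.ndarray          # bin left edges
    counts: np.ndarray
    baseline: float
    tail_sd: float
    n_spikes: int


def autocorrelogram(
    train: SpikeTrain,
    bin_ms: float = 5.0,
    max_lag_ms: float = 1000.0,
    tail_window_ms: tuple[float, float] = (960.0, 1000.0),
) -> Autocorrelogram:
    """Pair-count autocorrelogram of all spikes at forward lags.

    Raw counts, no normalization: the oscillation-acceptance thresholds are
    count-relative. O(n * k) where k is the number of spikes within the lag
    window of each spike.
    """
    if train.n_spikes < 2:
        raise InsufficientDataError("autocorrelogram needs >= 2 spikes")
    t_ms = train.timestamps * MS_PER_S
    n_bins = int(round(max_lag_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    # For each spike, the slice of later spikes within max_lag.
    hi = np.searchsorted(t_ms, t_ms + max_lag_ms, side="left")
    counts = np.zeros(n_bins, dtype=np.int64)
    n = t_ms.size
    for i in range(n):
        j = hi[i]
        if j > i + 1:
            d = t_ms[i + 1:j] - t_ms[i]
            counts += np.histogram(d, bins=edges)[0]
    lags = edges[:-1]
    in_tail = (lags >= tail_window_ms[0]) & (lags < tail_window_ms[1])
    tail = counts[in_tail].astype(float)
    baseline = float(tail.mean())
    tail_sd = float(tail.std(ddof=1)) if tail.size > 1 else 0.0
    return Autocorrelogram(bin_ms, lags, counts, baseline, tail_sd, n)


@dataclass
class PeakTroughSet:
    """Alternating peak/trough candidates from the oscillation walk.

    peaks/troughs are (lag_ms, height) pairs where height is count - baseline
    for peaks and baseline - count for troughs; ``accepted[i]`` marks whether
    the i-th peak/trough pair passed the noise-acceptance rule. ``flagged`` is
    set when the first-peak search window was empty.
    """

    peaks: list[tuple[float, float]]
    troughs: list[tuple[float, float]]
    accepted: list[bool]
    flagged: bool = False


def rhythmicity(ac: Autocorrelogram, mean_isi_ms: float
                ) -> tuple[float, int, PeakTroughSet]:
    """Iterative peak/trough detection and the rhythmicity index.

    Procedure (lag values are bin left edges):

    * first peak: highest bin with lag in [10 ms, 1.5 x mean ISI);
    * trough after a peak at lag L_n: lowest bin with lag in (L_n, L_n + L_1];
    * next peak after a trough at lag T: highest bin with lag in
      (T, L_n + L_1 + 10 ms];
    * a peak/trough pair is accepted if a_i + b_i > 4 x tail SD, or if the
      peak exceeds baseline + 2 SD and the trough is below baseline - 2 SD,
      where a_i = peak count - baseline and b_i = baseline - trough count;
    * detection stops at the first rejected pair or when a search window
      runs past the 1 s lag range.

    Returns (rhythmicity_index, n_accepted_peaks, PeakTroughSet). The index is
    the sum of accepted (a_i + b_i) divided by z = |n_spikes - baseline|.
    """
    if mean_isi_ms <= 0:
        raise ValueError("mean ISI must be positive")
    lags, counts = ac.lags_ms, ac.counts.astype(float)
    base, sd = ac.baseline, ac.tail_sd
    pts = PeakTroughSet([], [], [])

    def highest(mask: np.ndarray) -> int | None:
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return None
        return int(idx[np.argmax(counts[idx])])

    def lowest(mask: np.ndarray) -> int | None:
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return None
        return int(idx[np.argmin(counts[idx])])

    first = highest((lags >= 10.0) & (lags < 1.5 * mean_isi_ms))
    if first is None:
        pts.flagged = True
        return 0.0, 0, pts

    z = abs(ac.n_spikes - base)
    total = 0.0
    n_accepted = 0
    lag1 = lags[first]
    peak = first
    while True:
        lag_peak = lags[peak]
        a_i = counts[peak] - base
        trough = lowest((lags > lag_peak) & (lags <= lag_peak + lag1))
        if trough is None:
            break  # window ran past the 1 s range
        lag_trough = lags[trough]
        b_i = base - counts[trough]
        pts.peaks.append((float(lag_peak), float(a_i)))
        pts.troughs.append((float(lag_trough), float(b_i)))
        ok = (a_i + b_i > 4.0 * sd) or (
            counts[peak] > base + 2.0 * sd and counts[trough] < base - 2.0 * sd)
        pts.accepted.append(bool(ok))
        if not ok:
            break
        n_accepted += 1
        total += a_i + b_i
        nxt = highest((lags > lag_trough) & (lags <= lag_peak + lag1 + 10.0))
        if nxt is None:
            break
        peak = nxt

    ri = float(total / z) if z > 0 else 0.0
    return ri, n_accepted, pts


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def featurize(train: SpikeTrain, require_30s: bool = True) -> FeatureVector:
    """Compute all 12 parameters for one validated spike train."""
    violations = validate_train(train, require_30s=require_30s)
    if violations:
        raise ValueError(f"cell {train.cell_id!r}: " + "; ".join(violations))
    isis = isi_sequence(train)
    rate = firing_rate(train)
    med = median_ifr(isis)
    ac = autocorrelogram(train)
    ri, n_peaks, _ = rhythmicity(ac, float(np.mean(isis)))
    return FeatureVector(
        cell_id=train.cell_id,
        group_label=train.group_label,
        firing_rate=rate,
        mean_ifr=mean_ifr(isis),
        median_ifr=med,
        cv=cv(isis),
        cv2=cv2(isis),
        skewness=skewness_stat(med, rate),
        isi25=isi_fraction_above(isis, 25.0),
        isi100=isi_fraction_above(isis, 100.0),
        interburst_pause=interburst_pause(isis),
        mode_fraction=mode_fraction(isis),
        rhythmicity_index=ri,
        oscillation_peaks=float(n_peaks),
    )
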