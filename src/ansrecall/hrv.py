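"""R-peak detection, NN-interval construction, and HRV indices.

Time-domain indices follow the classical statistical definitions (mean,
standard deviation, root-mean-square of successive differences, proportion
of successive differences above 50 ms).  Frequency-domain indices integrate
a Welch periodogram of the evenly resampled tachogram over the VLF
(0.003-0.04 Hz), LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands, with
normalized powers relative to total power minus VLF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

__all__ = [
    "NNSeries",
    "HRVIndices",
    "detect_r_peaks",
    "build_nn_series",
    "time_domain_indices",
    "frequency_domain_indices",
    "hrv_indices",
    "VLF_BAND",
    "LF_BAND",
    "HF_BAND",
]

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

REFRACTORY_S = 0.2


@dataclass
class NNSeries:
    """Beat times with the interval series and per-interval exclusion flags."""

    beat_times_s: np.ndarray
    nn_ms: np.ndarray
    excluded: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.nn_ms = np.asarray(self.nn_ms, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.nn_ms.size != self.beat_times_s.size - 1:
            raise ValueError("nn_ms must have one entry per beat pair")
        if self.excluded.size != self.nn_ms.size:
            raise ValueError("excluded flags must match nn_ms")
        if np.any(self.nn_ms[~self.excluded] <= 0):
            raise ValueError("retained intervals must be positive")

    @property
    def retained_ms(self) -> np.ndarray:
        return self.nn_ms[~self.excluded]

    def restrict(self, start_s: float, end_s: float) -> "NNSeries":
        """Sub-series of beats falling inside ``[start_s, end_s)``."""
        mask = (self.beat_times_s >= start_s) & (self.beat_times_s < end_s)
        beats = self.beat_times_s[mask]
        if beats.size < 2:
            raise ValueError("fewer than 2 beats in the requested window")
        i0 = int(np.argmax(mask))
        return NNSeries(beats, self.nn_ms[i0:i0 + beats.size - 1],
                        self.excluded[i0:i0 + beats.size - 1])


@dataclass(frozen=True)
class HRVIndices:
    avnn: float
    sdnn: float
    rmssd: float
    pnn50: float
    lf_norm: float
    hf_norm: float
    lf_hf: float


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs_hz: float) -> np.ndarray:
    """Locate R peaks with a band-pass/derivative/energy detector.

    Pipeline: zero-phase 5-15 Hz band-pass, squared derivative, 150 ms
    moving-window integration, adaptive-threshold peak picking with a
    200 ms refractory period, then localization of each beat at the
    band-passed maximum inside the candidate window.  Returns peak times in
    seconds.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs_hz < 100:
        raise ValueError("fs_hz must be >= 100")
    if ecg.size < 2 * fs_hz:
        raise ValueError("signal too short: need at least 2 s")
    if ecg.std() == 0:
        raise ValueError("no beats detected: flat signal")

    sos = signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs_hz,
                        output="sos")
    band = signal.sosfiltfilt(sos, ecg)
    deriv = np.gradient(band) * fs_hz
    energy = deriv ** 2
    win = max(1, int(round(0.15 * fs_hz)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    height = 0.2 * np.percentile(integ, 99)
    if height <= 0:
        raise ValueError("no beats detected: no energy above threshold")
    cand, _ = signal.find_peaks(integ, height=height,
                                distance=max(1, int(REFRACTORY_S * fs_hz)))
    if cand.size == 0:
        raise ValueError("no beats detected")

    half = int(round(0.1 * fs_hz))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(band), c + half + 1)
        peaks.append(lo + int(np.argmax(band[lo:hi])))
    peaks = np.unique(peaks)
    # enforce refractory after localization
    kept = [int(peaks[0])]
    for p in peaks[1:]:
        if (p - kept[-1]) / fs_hz >= REFRACTORY_S:
            kept.append(int(p))
        elif band[p] > band[kept[-1]]:
            kept[-1] = int(p)
    return np.asarray(kept) / fs_hz


def build_nn_series(beat_times_s: np.ndarray,
                    ectopic_rel_threshold: float = 0.2) -> NNSeries:
    """Interval series with ectopic-beat exclusion.

    An interval is compared against the running median of the last five
    retained intervals (falling back to the global median early on); when it
    deviates by more than ``ectopic_rel_threshold`` relative, its terminal
    beat is treated as ectopic and both intervals sharing that beat are
    flagged excluded.
    """
    beats = np.asarray(beat_times_s, dtype=float)
    if beats.size < 3:
        raise ValueError("need at least 3 beats")
    nn = np.diff(beats) * 1000.0
    if np.any(nn <= 0):
        raise ValueError("beat times must be strictly increasing")
    excluded = np.zeros(nn.size, dtype=bool)
    global_med = float(np.median(nn))
    retained: list[float] = []
    for i, x in enumerate(nn):
        if excluded[i]:
            continue
        ref = float(np.median(retained[-5:])) if retained else global_med
        if abs(x - ref) > ectopic_rel_threshold * ref:
            excluded[i] = True
            if i + 1 < nn.size:
                excluded[i + 1] = True
        else:
            retained.append(float(x))
    return NNSeries(beats, nn, excluded)


# ---------------------------------------------------------------------------
# Indices
# ---------------------------------------------------------------------------

def _successive_diffs(nn: NNSeries) -> np.ndarray:
    """Differences between originally adjacent retained intervals."""
    keep = ~nn.excluded
    pair_ok = keep[1:] & keep[:-1]
    return np.diff(nn.nn_ms)[pair_ok]


def time_domain_indices(nn: NNSeries) -> tuple[float, float, float, float]:
    """(avnn, sdnn, rmssd, pnn50) over retained intervals.

    pnn50 is the proportion of successive-interval differences whose
    absolute value exceeds 50 ms, among pairs of adjacent retained
    intervals; sdnn uses the n-1 denominator.
    """
    x = nn.retained_ms
    if x.size < 2:
        raise ValueError("need at least 2 retained intervals")
    avnn = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    d = _successive_diffs(nn)
    if d.size == 0:
        raise ValueError("no adjacent retained interval pairs")
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    pnn50 = float(np.mean(np.abs(d) > 50.0))
    return avnn, sdnn, rmssd, pnn50


def frequency_domain_indices(nn: NNSeries, resample_hz: float = 4.0,
                             min_span_s: float = 45.0
                             ) -> tuple[float, float, float]:
    """(lf_norm, hf_norm, lf_hf) from the resampled tachogram.

    The retained tachogram is cubic-interpolated onto an even grid and its
    Welch periodogram (single full-length segment) integrated per band.
    Normalized powers are band power over total power minus VLF, times 100.
    One-minute epochs give a frequency resolution of ~0.017 Hz, so VLF
    content is poorly resolved; the normalization still subtracts the
    estimated VLF power.

    ``min_span_s`` guards against epochs too short for the LF band; an
    epoch of nominal length 60 s yields a beat span slightly below 60 s,
    hence the default is below the nominal epoch length.
    """
    keep = ~nn.excluded
    times = nn.beat_times_s[1:][keep]
    values = nn.nn_ms[keep]
    if times.size < 4:
        raise ValueError("too few retained intervals for spectral analysis")
    span = times[-1] - times[0]
    if span < min_span_s:
        raise ValueError(f"epoch too short for spectral analysis: "
                         f"{span:.1f} s < {min_span_s} s")
    grid = np.arange(times[0], times[-1], 1.0 / resample_hz)
    tck = interpolate.CubicSpline(times, values)
    tach = tck(grid)
    tach = tach - tach.mean()

    freqs, psd = signal.welch(tach, fs=resample_hz, nperseg=len(tach),
                              detrend="constant")

    def band_power(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], freqs[m]))

    total = float(np.trapezoid(psd, freqs))
    vlf = band_power(*VLF_BAND)
    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    denom = total - vlf
    # powers are in ms^2; anything below this floor is numerical residue
    floor = 1e-10
    if denom <= floor:
        raise ValueError("no power outside the VLF band")
    if hf <= floor:
        raise ValueError("HF power numerically zero; lf_hf undefined")
    return 100.0 * lf / denom, 100.0 * hf / denom, lf / hf


def hrv_indices(nn: NNSeries, resample_hz: float = 4.0,
                min_span_s: float = 45.0) -> HRVIndices:
    avnn, sdnn, rmssd, pnn50 = time_domain_indices(nn)
    lf_norm, hf_norm, lf_hf = frequency_domain_indices(
        nn, resample_hz=resample_hz, min_span_s=min_span_s)
    return HRVIndices(avnn=avnn, sdnn=sdnn, rmssd=rmssd, pnn50=pnn50,
                      lf_norm=lf_norm, hf_norm=hf_norm, lf_hf=lf_hf)
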