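"""Electrodermal activity decomposition: tonic level and phasic responses.

The tonic skin-conductance level is the 0.1 Hz low-pass of the trace; its
epoch mean is the ``mean_scl`` index.  Phasic skin-conductance responses
are counted by downsampling to 20 Hz, differentiating, and convolving with
a 20-point Bartlett window — local maxima of the resulting spiky signal
above threshold are SCR events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["EDAFeatures", "extract_scl", "detect_scrs", "eda_features"]

SCR_RATE_HZ = 20
BARTLETT_POINTS = 20
# group delay of first-difference (0.5 sample) + Bartlett centre (9.5 samples)
_PIPELINE_DELAY_SAMPLES = 10.0


@dataclass(frozen=True)
class EDAFeatures:
    mean_scl: float
    ns_scr: int
    scr_onsets_s: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.ns_scr != len(self.scr_onsets_s):
            raise ValueError("ns_scr must equal the number of onsets")


def extract_scl(eda: np.ndarray, fs_hz: float) -> tuple[np.ndarray, float]:
    """Tonic component via a zero-phase 4th-order 0.1 Hz low-pass.

    Returns the filtered trace and its mean over the epoch.  The zero-phase
    (forward-backward) filter keeps the tonic estimate aligned with the
    epoch, and scipy's odd-reflection padding limits edge transients on
    epochs short relative to the 0.1 Hz cut-off.
    """
    eda = np.asarray(eda, dtype=float)
    if fs_hz < 20:
        raise ValueError("fs_hz must be >= 20")
    if eda.size < 10 * fs_hz:
        raise ValueError("epoch too short: need at least 10 s")
    sos = signal.butter(4, 0.1, btype="lowpass", fs=fs_hz, output="sos")
    tonic = signal.sosfiltfilt(sos, eda)
    return tonic, float(np.mean(tonic))


def _spiky_signal(eda: np.ndarray, fs_hz: float) -> np.ndarray:
    """Downsample to 20 Hz, differentiate, convolve with a Bartlett window."""
    fs_int = int(round(fs_hz))
    if abs(fs_hz - fs_int) > 1e-9:
        raise ValueError("fs_hz must be an integer number of Hz")
    if fs_int == SCR_RATE_HZ:
        x20 = np.asarray(eda, dtype=float)
    else:
        x20 = signal.resample_poly(np.asarray(eda, dtype=float),
                                   SCR_RATE_HZ, fs_int, padtype="line")
    d = np.diff(x20)
    return np.convolve(d, np.bartlett(BARTLETT_POINTS), mode="full")


def detect_scrs(eda: np.ndarray, fs_hz: float, threshold: float | None = None,
                min_separation_s: float = 1.0
                ) -> tuple[np.ndarray, int]:
    """Count skin-conductance responses in an epoch.

    ``threshold`` applies to the spiky (decimate/differentiate/Bartlett)
    signal; when omitted it adapts to the trace as
    ``max(0.01, 3 * scaled MAD of the spiky signal)``.  Events closer than
    ``min_separation_s`` are merged.  Returns onset times (seconds) and the
    event count.
    """
    eda = np.asarray(eda, dtype=float)
    if fs_hz < 20:
        raise ValueError("fs_hz must be >= 20")
    if eda.size < 5 * fs_hz:
        raise ValueError("epoch too short: need at least 5 s")
    if threshold is not None and threshold <= 0:
        raise ValueError("threshold must be positive")

    spiky = _spiky_signal(eda, fs_hz)
    if threshold is None:
        mad = float(np.median(np.abs(spiky - np.median(spiky))))
        threshold = max(0.01, 3.0 * 1.4826 * mad)

    distance = max(1, int(round(min_separation_s * SCR_RATE_HZ)))
    peaks, _ = signal.find_peaks(spiky, height=threshold, distance=distance)
    onsets = (peaks - (_PIPELINE_DELAY_SAMPLES - 1.0)) / SCR_RATE_HZ
    onsets = np.clip(onsets, 0.0, eda.size / fs_hz)
    return onsets, int(onsets.size)


def eda_features(eda: np.ndarray, fs_hz: float,
                 threshold: float | None = None,
                 min_separation_s: float = 1.0) -> EDAFeatures:
    """Per-epoch mean SCL and SCR count."""
    _, mean_scl = extract_scl(eda, fs_hz)
    onsets, ns_scr = detect_scrs(eda, fs_hz, threshold=threshold,
                                 min_separation_s=min_separation_s)
    return EDAFeatures(mean_scl=mean_scl, ns_scr=ns_scr,
                       scr_onsets_s=tuple(float(o) for o in onsets))
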