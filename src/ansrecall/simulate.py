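"""Synthetic biosignals and indicator tables with known ground truth.

Everything downstream of raw acquisition can be exercised against the
generators in this module: NN-interval series with controllable spectral
content, ECG traces with beats at prescribed times, EDA traces with a tonic
ramp plus discrete skin-conductance responses, and subject-by-spot indicator
tables drawn from a latent path model with known loadings and path
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plspm import PathModelSpec

__all__ = [
    "Epoch",
    "StimulusSchedule",
    "RawRecording",
    "LatentGroundTruth",
    "default_schedule",
    "generate_nn_series",
    "generate_ecg",
    "generate_eda",
    "generate_indicator_table",
]

EMOTIONS = ("rational", "disgust", "anger", "surprise", "sadness", "baseline")


@dataclass(frozen=True)
class Epoch:
    label: str
    emotion: str
    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")
        if self.duration_s <= 0:
            raise ValueError("epoch duration must be > 0")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered, non-overlapping presentation epochs."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        eps = self.epochs
        if not eps:
            raise ValueError("schedule needs at least one epoch")
        for a, b in zip(eps, eps[1:]):
            if b.start_s < a.end_s - 1e-12:
                raise ValueError(f"epochs {a.label!r} and {b.label!r} overlap")
        if any(b.start_s < a.start_s for a, b in zip(eps, eps[1:])):
            raise ValueError("epochs must be ordered by start time")

    @property
    def total_duration_s(self) -> float:
        return self.epochs[-1].end_s

    @property
    def spots(self) -> tuple[Epoch, ...]:
        return tuple(e for e in self.epochs if e.emotion != "baseline")

    def to_jsonable(self) -> list[dict]:
        return [
            {"label": e.label, "emotion": e.emotion, "start_s": e.start_s,
             "duration_s": e.duration_s}
            for e in self.epochs
        ]

    @classmethod
    def from_jsonable(cls, items: Sequence[Mapping]) -> "StimulusSchedule":
        return cls(tuple(Epoch(d["label"], d["emotion"], float(d["start_s"]),
                               float(d["duration_s"])) for d in items))


def default_schedule(spot_duration_s: float = 60.0,
                     baseline_s: float = 60.0) -> StimulusSchedule:
    """One baseline minute followed by six one-minute spots.

    Spot order: rational, disgust, anger, surprise, sadness, rational.
    """
    order = ["rational", "disgust", "anger", "surprise", "sadness", "rational"]
    epochs = [Epoch("baseline", "baseline", 0.0, baseline_s)]
    t = baseline_s
    seen: dict[str, int] = {}
    for emo in order:
        seen[emo] = seen.get(emo, 0) + 1
        label = emo if order.count(emo) == 1 else f"{emo}_{seen[emo]}"
        epochs.append(Epoch(label, emo, t, spot_duration_s))
        t += spot_duration_s
    return StimulusSchedule(tuple(epochs))


@dataclass
class RawRecording:
    """Synchronized single- or multi-channel recording."""

    channels: dict[str, np.ndarray]
    fs_hz: float
    schedule: StimulusSchedule | None = None
    units: dict[str, str] = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        n = max(len(v) for v in self.channels.values())
        return n / self.fs_hz


# ---------------------------------------------------------------------------
# NN-interval / ECG generation
# ---------------------------------------------------------------------------

def generate_nn_series(duration_s: float, mean_rr_ms: float,
                       lf_amp_ms: float = 0.0, hf_amp_ms: float = 0.0,
                       lf_freq_hz: float = 0.1, hf_freq_hz: float = 0.25,
                       jitter_sd_ms: float = 0.0, seed: int = 0):
    """Beat times whose intervals are a mean plus LF/HF sinusoids plus jitter.

    Returns an :class:`ansrecall.hrv.NNSeries` spanning at least
    ``duration_s`` seconds.  The additive-sinusoid model concentrates
    tachogram power at the two modulation frequencies, which gives the
    spectral indices an analytic oracle.
    """
    from .hrv import NNSeries

    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if mean_rr_ms <= 0:
        raise ValueError("mean_rr_ms must be > 0")
    if mean_rr_ms <= 2.0 * (abs(lf_amp_ms) + abs(hf_amp_ms)):
        raise ValueError("modulation amplitude too large for mean RR")
    if not (0.04 <= lf_freq_hz <= 0.15):
        raise ValueError("lf_freq_hz must lie in the 0.04-0.15 Hz band")
    if not (0.15 <= hf_freq_hz <= 0.4):
        raise ValueError("hf_freq_hz must lie in the 0.15-0.4 Hz band")

    rng = np.random.default_rng(seed)
    # first beat one nominal interval in, so a QRS template fits the trace
    times = [mean_rr_ms / 1000.0]
    while times[-1] < duration_s:
        t = times[-1]
        rr = (mean_rr_ms
              + lf_amp_ms * np.sin(2 * np.pi * lf_freq_hz * t)
              + hf_amp_ms * np.sin(2 * np.pi * hf_freq_hz * t))
        if jitter_sd_ms > 0:
            rr += rng.normal(0.0, jitter_sd_ms)
        if rr <= 0:
            raise ValueError("generated a non-positive interval; "
                             "reduce modulation or jitter")
        times.append(t + rr / 1000.0)
    beat_times = np.asarray(times)
    nn_ms = np.diff(beat_times) * 1000.0
    return NNSeries(beat_times_s=beat_times, nn_ms=nn_ms,
                    excluded=np.zeros(nn_ms.size, dtype=bool))


def _qrs_template(fs_hz: float, amplitude_mv: float) -> np.ndarray:
    """Triphasic QRS-like wavelet: narrow positive R flanked by Q/S dips."""
    half = int(round(0.08 * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    r = np.exp(-0.5 * (t / 0.012) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.035) / 0.010) ** 2)
    s = -0.20 * np.exp(-0.5 * ((t - 0.035) / 0.010) ** 2)
    return amplitude_mv * (r + q + s)


def generate_ecg(nn, fs_hz: float = 1000.0, amplitude_mv: float = 1.0,
                 noise_sd_mv: float = 0.0, seed: int = 0) -> np.ndarray:
    """Place one QRS template at every beat time; trace in mV.

    The trace covers the last beat plus one second.  Only the R-wave needs
    to be morphologically faithful: the contract is that a detector can
    localize each beat to within a few milliseconds.
    """
    if fs_hz < 100:
        raise ValueError("fs_hz must be >= 100 for R-peak localization")
    beat_times = np.asarray(nn.beat_times_s, dtype=float)
    if beat_times.size == 0:
        raise ValueError("empty NN series")

    n = int(np.ceil((beat_times[-1] + 1.0) * fs_hz))
    trace = np.zeros(n)
    tpl = _qrs_template(fs_hz, amplitude_mv)
    half = len(tpl) // 2
    centers = np.round(beat_times * fs_hz).astype(int)
    for c in centers:
        lo, hi = c - half, c + half + 1
        tlo, thi = max(0, -lo), len(tpl) - max(0, hi - n)
        trace[max(0, lo):min(n, hi)] += tpl[tlo:thi]
    if noise_sd_mv > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd_mv, size=n)
    return trace


# ---------------------------------------------------------------------------
# EDA generation
# ---------------------------------------------------------------------------

def _scr_waveform(t: np.ndarray, amplitude_us: float, rise_s: float,
                  decay_s: float) -> np.ndarray:
    """Bi-exponential sudomotor impulse response, peak-normalized."""
    w = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_s)
                 - np.exp(-np.maximum(t, 0) / rise_s), 0.0)
    t_peak = np.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return amplitude_us * w / peak


def generate_eda(duration_s: float, scl_level_us: float = 2.0,
                 drift_us_per_min: float = 0.0,
                 scr_events: Sequence[tuple[float, float, float, float]] = (),
                 fs_hz: float = 1000.0, noise_sd_us: float = 0.0,
                 seed: int = 0) -> np.ndarray:
    """Tonic ramp plus bi-exponential SCRs plus white noise, in µS.

    ``scr_events`` is a list of ``(onset_s, amplitude_us, rise_s, decay_s)``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    trace = scl_level_us + drift_us_per_min * t / 60.0
    for onset_s, amplitude_us, rise_s, decay_s in scr_events:
        if amplitude_us <= 0:
            raise ValueError("SCR amplitude must be > 0")
        if not (0 <= onset_s < duration_s):
            raise ValueError("SCR onset outside the trace")
        if not rise_s < decay_s:
            raise ValueError("SCR rise time must be shorter than decay time")
        trace = trace + _scr_waveform(t - onset_s, amplitude_us, rise_s,
                                      decay_s)
    if noise_sd_us > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd_us, size=n)
    if np.any(trace <= 0):
        raise ValueError("generated non-positive conductance; "
                         "check levels, drift and noise")
    return trace


# ---------------------------------------------------------------------------
# Indicator tables from a known latent model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentGroundTruth:
    """Known measurement loadings and structural coefficients.

    ``loadings`` and ``noise_sd`` map manifest-variable name to value;
    ``path_coefficients`` maps ``(source_lv, target_lv)`` to a standardized
    coefficient.  Endogenous latent disturbances are scaled so every latent
    variable has unit theoretical variance, keeping the coefficients
    interpretable as standardized regression weights.
    """

    loadings: Mapping[str, float]
    path_coefficients: Mapping[tuple[str, str], float]
    noise_sd: Mapping[str, float]
    n_subjects: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        for mv, lo in self.loadings.items():
            if abs(lo) > 1:
                raise ValueError(f"|loading| > 1 for {mv!r}")
        for mv, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"negative noise_sd for {mv!r}")


def generate_indicator_table(truth: LatentGroundTruth, spec: PathModelSpec,
                             return_latents: bool = False):
    """Draw an indicator table whose latent structure is exactly ``truth``.

    Exogenous latent scores are independent standard normals; each
    endogenous latent is the coefficient-weighted sum of its parents plus a
    disturbance whose variance tops the systematic variance up to one.
    Manifest variables are ``loading * latent + noise``.  A balanced gender
    column is appended.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_subjects
    order = spec.topological_order()

    for mv in spec.all_mvs():
        if mv not in truth.loadings or mv not in truth.noise_sd:
            raise ValueError(f"missing loading or noise_sd for MV {mv!r}")

    latents: dict[str, np.ndarray] = {}
    cov = pd.DataFrame(np.eye(len(order)), index=order, columns=order)
    for lv in order:
        parents = spec.predecessors(lv)
        if not parents:
            latents[lv] = rng.standard_normal(n)
            continue
        beta = np.array([truth.path_coefficients.get((p, lv), 0.0)
                         for p in parents])
        c_par = cov.loc[list(parents), list(parents)].to_numpy()
        var_sys = float(beta @ c_par @ beta)
        if var_sys > 1.0 + 1e-9:
            raise ValueError(
                f"path coefficients into {lv!r} imply variance {var_sys:.3f}"
                " > 1; cannot keep latent scores standardized")
        disturbance_sd = np.sqrt(max(0.0, 1.0 - var_sys))
        score = sum(b * latents[p] for b, p in zip(beta, parents))
        latents[lv] = score + disturbance_sd * rng.standard_normal(n)
        # book-keep the model-implied covariance for downstream latents
        for other in order:
            if other == lv:
                continue
            c = float(sum(b * cov.loc[p, other]
                          for b, p in zip(beta, parents)))
            cov.loc[lv, other] = cov.loc[other, lv] = c

    data = {}
    for lv, mvs in spec.blocks.items():
        for mv in mvs:
            noise = truth.noise_sd[mv] * rng.standard_normal(n)
            data[mv] = truth.loadings[mv] * latents[lv] + noise
    table = pd.DataFrame(data, columns=list(spec.all_mvs()))
    table["gender"] = np.where(np.arange(n) % 2 == 0, "F", "M")

    if return_latents:
        return table, pd.DataFrame(latents)
    return table
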