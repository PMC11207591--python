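"""Sliding-window sEMG features: iEMG, RMS, WL, SE, MF, MPF.

Windows of 256 ms advanced by 56 ms (256/56 samples at 1000 Hz).  For a
window x_1..x_N:

* iEMG = (1/N) sum |x_i|        (per-unit-time integrated amplitude; with
  the 1/N factor this is the mean rectified amplitude)
* RMS  = sqrt((1/N) sum x_i^2)
* WL   = sum_{i=1}^{N-1} |x_{i+1} - x_i|   (waveform length)
* SE   = -sum p_k log2 p_k over an equal-width amplitude histogram
  (Shannon entropy, bits)
* MF   = the frequency splitting the power spectral density into two equal
  halves (median frequency)
* MPF  = sum f PSD(f) / sum PSD(f)  (mean power frequency)

Time-domain features are computed on the rectified, MVC-normalized stage;
spectral features on the filtered, unrectified stage of the same span,
because rectification folds the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigError, StageError
from .preprocess import SignalSegment

__all__ = [
    "WindowingConfig",
    "SignalWindow",
    "PowerSpectrum",
    "FEATURE_NAMES",
    "slide_windows",
    "iemg",
    "rms",
    "wl",
    "shannon_entropy",
    "power_spectrum",
    "median_frequency",
    "mean_power_frequency",
    "window_features",
    "extract_features",
]

FEATURE_NAMES = ("iemg", "rms", "wl", "se", "mf", "mpf")


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window geometry in milliseconds (256 ms window, 56 ms step)."""

    window_ms: float = 256.0
    step_ms: float = 56.0

    def __post_init__(self) -> None:
        if not (self.window_ms > self.step_ms > 0):
            raise ConfigError("need window_ms > step_ms > 0")

    def window_samples(self, rate: float) -> int:
        return int(round(self.window_ms * rate / 1000.0))

    def step_samples(self, rate: float) -> int:
        return int(round(self.step_ms * rate / 1000.0))


@dataclass(frozen=True)
class SignalWindow:
    """One analysis window cut from a segment, keeping its source stage."""

    x: np.ndarray
    rate: float
    stage: str
    start: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=np.float64))

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density on an ascending frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=np.float64)
        p = np.asarray(self.psd, dtype=np.float64)
        if f.shape != p.shape:
            raise ConfigError("freqs and psd must have the same shape")
        if p.size and p.min() < 0:
            raise ConfigError("psd must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "psd", p)


def slide_windows(
    seg: SignalSegment, cfg: WindowingConfig | None = None
) -> list[SignalWindow]:
    """Cut overlapping windows starting at 0, step, 2*step, ...

    The number of full windows is floor((L - W) / S) + 1; a trailing span
    shorter than the window is dropped.  A segment shorter than one window
    yields an empty list.
    """
    cfg = cfg or WindowingConfig()
    w = cfg.window_samples(seg.rate)
    s = cfg.step_samples(seg.rate)
    if len(seg) < w:
        return []
    starts = range(0, len(seg) - w + 1, s)
    return [
        SignalWindow(x=seg.samples[i : i + w], rate=seg.rate, stage=seg.stage, start=i)
        for i in starts
    ]


def _nonempty(x: np.ndarray, op: str) -> np.ndarray:
    if x.size == 0:
        raise ConfigError(f"{op} is undefined on an empty window")
    return x


def iemg(w: SignalWindow | np.ndarray) -> float:
    """Mean rectified amplitude over the window (integrated EMG per sample)."""
    x = _nonempty(np.abs(np.asarray(getattr(w, "x", w), dtype=float)), "iemg")
    return float(x.mean())


def rms(w: SignalWindow | np.ndarray) -> float:
    """Root-mean-square amplitude of the window."""
    x = _nonempty(np.asarray(getattr(w, "x", w), dtype=float), "rms")
    return float(np.sqrt(np.mean(x * x)))


def wl(w: SignalWindow | np.ndarray) -> float:
    """Waveform length: cumulative absolute first difference."""
    x = _nonempty(np.asarray(getattr(w, "x", w), dtype=float), "wl")
    return float(np.abs(np.diff(x)).sum())


def shannon_entropy(w: SignalWindow | np.ndarray, bins: int = 64) -> float:
    """Shannon entropy (bits) of the window's amplitude histogram.

    Equal-width bins over [min(x), max(x)]; probabilities are bin counts / N;
    empty bins contribute nothing (0 log 0 := 0).  A constant window occupies
    a single bin and has zero entropy.
    """
    if bins < 2:
        raise ConfigError("bins must be >= 2")
    x = _nonempty(np.asarray(getattr(w, "x", w), dtype=float), "shannon_entropy")
    if np.ptp(x) == 0.0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(x.min(), x.max()))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def power_spectrum(w: SignalWindow | np.ndarray, rate: float | None = None) -> PowerSpectrum:
    """Hann-tapered one-sided periodogram of the window.

    A single taper is used rather than segment averaging: a 256-sample window
    is too short to subdivide without destroying frequency resolution
    (rate / N per bin).
    """
    x = _nonempty(np.asarray(getattr(w, "x", w), dtype=float), "power_spectrum")
    fs = rate if rate is not None else getattr(w, "rate", 1000.0)
    freqs, psd = sps.periodogram(x, fs=fs, window="hann", detrend=False)
    return PowerSpectrum(freqs=freqs, psd=psd)


def median_frequency(s: PowerSpectrum) -> float:
    """Frequency below which half of the total spectral power lies.

    Linear interpolation of the cumulative power between grid frequencies.
    Undefined (error) for an all-zero spectrum.
    """
    total = s.psd.sum()
    if total <= 0:
        raise ConfigError("median frequency is undefined for zero total power")
    cum = np.cumsum(s.psd)
    return float(np.interp(total / 2.0, cum, s.freqs))


def mean_power_frequency(s: PowerSpectrum) -> float:
    """Power-weighted mean frequency of the spectrum."""
    total = s.psd.sum()
    if total <= 0:
        raise ConfigError("mean power frequency is undefined for zero total power")
    return float((s.freqs * s.psd).sum() / total)


def window_features(
    normalized: SignalSegment,
    filtered: SignalSegment,
    cfg: WindowingConfig | None = None,
    entropy_bins: int = 64,
) -> pd.DataFrame:
    """All six features for every window of one channel's segment pair.

    ``normalized`` and ``filtered`` must cover the same span of the same
    channel; time-domain features are read off the normalized stage and
    spectral features off the filtered stage.
    """
    if normalized.stage != "normalized":
        raise StageError("time-domain source must be at the normalized stage")
    if filtered.stage != "filtered":
        raise StageError("spectral source must be at the filtered stage")
    if len(normalized) != len(filtered):
        raise ConfigError("segment pair must cover the same span")
    cfg = cfg or WindowingConfig()
    rows = []
    for wn, wf in zip(slide_windows(normalized, cfg), slide_windows(filtered, cfg)):
        spec = power_spectrum(wf)
        rows.append(
            {
                "window_start": wn.start,
                "iemg": iemg(wn),
                "rms": rms(wn),
                "wl": wl(wn),
                "se": shannon_entropy(wn, bins=entropy_bins),
                "mf": median_frequency(spec),
                "mpf": mean_power_frequency(spec),
            }
        )
    return pd.DataFrame(
        rows, columns=["window_start", *FEATURE_NAMES]
    )


def extract_features(
    channels: dict[str, Sequence[tuple[SignalSegment, SignalSegment]]],
    cfg: WindowingConfig | None = None,
    entropy_bins: int = 64,
) -> pd.DataFrame:
    """Feature table across channels: one row per window position.

    ``channels`` maps a channel name to its (normalized, filtered) segment
    pairs; the k-th pair of every channel must come from the same contraction
    so windows align.  Columns are ``<channel>_<feature>`` for the six
    features of each channel, plus ``percent_mvc`` (the segment's force
    label) and ``window_start``.
    """
    cfg = cfg or WindowingConfig()
    names = list(channels)
    if not names:
        return pd.DataFrame()
    n_segs = {ch: len(pairs) for ch, pairs in channels.items()}
    if len(set(n_segs.values())) != 1:
        raise ConfigError(f"channels have unequal segment counts: {n_segs}")
    blocks = []
    for k in range(n_segs[names[0]]):
        per_channel = []
        label = None
        for ch in names:
            norm, filt = channels[ch][k]
            tab = window_features(norm, filt, cfg, entropy_bins)
            tab = tab.set_index("window_start")
            tab.columns = [f"{ch}_{c}" for c in tab.columns]
            per_channel.append(tab)
            label = norm.force_label if label is None else label
            if norm.force_label != label:
                raise ConfigError("channels disagree on the segment force label")
        block = pd.concat(per_channel, axis=1, join="inner").reset_index()
        block["percent_mvc"] = label
        blocks.append(block)
    out = pd.concat(blocks, ignore_index=True)
    feature_cols = [c for c in out.columns if c not in ("window_start", "percent_mvc")]
    return out[feature_cols + ["percent_mvc", "window_start"]]
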