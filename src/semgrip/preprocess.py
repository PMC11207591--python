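"""Segmentation, filtering, rectification and MVC normalization of sEMG.

The preprocessing chain is: reconstruct (protocol module), segment by
manually calibrated start/end points, zero-phase band-pass filter 20-490 Hz
(4th-order Butterworth), full-wave rectify, and normalize each sample by the
subject's maximum-voluntary-contraction (MVC) amplitude:

    semg_nor = semg_task / semg_mvc * 100   [% MVC]

where ``semg_mvc`` is the maximum of the rectified, filtered MVC trial for
that subject and channel.  Both the rectified-normalized and the filtered
(unrectified) version of every segment are retained: spectral features need
an unrectified spectrum, while amplitude features use the normalized one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, StageError
from .protocol import AdcConfig, RawRecording, counts_to_millivolts

__all__ = [
    "STAGES",
    "ContinuousSignal",
    "SegmentAnnotation",
    "NormalizationContext",
    "SignalSegment",
    "PreprocessResult",
    "segment",
    "design_bandpass",
    "bandpass_gain",
    "bandpass_filter",
    "rectify",
    "mvc_peak",
    "normalize_mvc",
    "preprocess_channel",
    "preprocess_recording",
    "detect_onsets",
]

#: Pipeline stages in order; a segment only moves forward through them.
STAGES = ("raw", "filtered", "rectified", "normalized")


@dataclass(frozen=True)
class ContinuousSignal:
    """A reconstructed, baseline-removed sample series for one channel (mV)."""

    samples: np.ndarray
    rate: float = 1000.0
    channel: str = "ch1"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ConfigError("rate must be positive")
        if not np.all(np.isfinite(samples)):
            raise ConfigError("signal contains non-finite values")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class SegmentAnnotation:
    """Half-open sample span [start, end) with its force label in %MVC."""

    start: int
    end: int
    force_label: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ConfigError(f"need 0 <= start < end, got [{self.start}, {self.end})")


@dataclass(frozen=True)
class NormalizationContext:
    """Per-subject, per-channel MVC amplitude reference (mV)."""

    semg_mvc: float
    subject: str | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        if not (self.semg_mvc > 0):
            raise ConfigError("semg_mvc must be > 0")


@dataclass(frozen=True)
class SignalSegment:
    """A contraction's samples at one pipeline stage.

    ``stage`` is one of raw / filtered / rectified / normalized; normalized
    samples are in %MVC and non-negative.
    """

    samples: np.ndarray
    rate: float
    stage: str = "raw"
    force_label: float | None = None
    channel: str = "ch1"
    start: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64)
        )

    def __len__(self) -> int:
        return self.samples.size


def _require_stage(seg: SignalSegment, allowed: Sequence[str], op: str) -> None:
    if seg.stage not in allowed:
        raise StageError(
            f"{op} expects a segment at stage {'/'.join(allowed)}, "
            f"got {seg.stage!r}"
        )


def segment(
    sig: ContinuousSignal, annotations: Iterable[SegmentAnnotation]
) -> list[SignalSegment]:
    """Cut raw segments out of a continuous signal at annotated spans."""
    out = []
    for ann in annotations:
        if ann.end > len(sig):
            raise ConfigError(
                f"annotation [{ann.start}, {ann.end}) exceeds signal "
                f"length {len(sig)}"
            )
        out.append(
            SignalSegment(
                samples=sig.samples[ann.start : ann.end],
                rate=sig.rate,
                stage="raw",
                force_label=ann.force_label,
                channel=sig.channel,
                start=ann.start,
            )
        )
    return out


def design_bandpass(
    low: float = 20.0, high: float = 490.0, order: int = 4, rate: float = 1000.0
) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass prototype."""
    if not (0 < low < high):
        raise ConfigError("need 0 < low < high")
    if high >= rate / 2:
        raise ConfigError(f"high cutoff {high} must be below Nyquist {rate / 2}")
    return sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")


def bandpass_gain(
    freq: float,
    low: float = 20.0,
    high: float = 490.0,
    order: int = 4,
    rate: float = 1000.0,
) -> float:
    """Effective amplitude gain of the zero-phase stage at one frequency.

    Forward-backward filtering applies the filter twice, so the net gain is
    the squared magnitude response of the one-pass design.
    """
    sos = design_bandpass(low, high, order, rate)
    _, h = sps.sosfreqz(sos, worN=[freq], fs=rate)
    return float(np.abs(h[0]) ** 2)


def bandpass_filter(
    seg: SignalSegment,
    low: float = 20.0,
    high: float = 490.0,
    order: int = 4,
) -> SignalSegment:
    """Zero-phase 4th-order Butterworth band-pass, 20-490 Hz by default.

    Realized as forward-backward second-order sections with odd-reflection
    padding, so the output has no phase lag and the same length as the input.
    """
    _require_stage(seg, ("raw",), "bandpass_filter")
    sos = design_bandpass(low, high, order, rate=seg.rate)
    padlen = 3 * (order + 1)
    if len(seg) <= padlen:
        raise ConfigError(
            f"segment of {len(seg)} samples is too short for the "
            f"{padlen}-sample filter padding"
        )
    filtered = sps.sosfiltfilt(sos, seg.samples, padtype="odd", padlen=padlen)
    return replace(seg, samples=filtered, stage="filtered")


def rectify(seg: SignalSegment) -> SignalSegment:
    """Full-wave rectification: elementwise absolute value."""
    _require_stage(seg, ("filtered",), "rectify")
    return replace(seg, samples=np.abs(seg.samples), stage="rectified")


def mvc_peak(
    trials: SignalSegment | Sequence[SignalSegment],
    subject: str | None = None,
) -> NormalizationContext:
    """MVC amplitude reference: the maximum of the rectified MVC trial(s).

    Several trials are treated as one concatenated recording (the maximum
    over all of them).
    """
    if isinstance(trials, SignalSegment):
        trials = [trials]
    if not trials:
        raise ConfigError("mvc_peak needs at least one trial")
    peak = -np.inf
    channel = trials[0].channel
    for t in trials:
        _require_stage(t, ("rectified",), "mvc_peak")
        if len(t) == 0:
            raise ConfigError("empty MVC trial")
        peak = max(peak, float(t.samples.max()))
    return NormalizationContext(semg_mvc=peak, subject=subject, channel=channel)


def normalize_mvc(seg: SignalSegment, ctx: NormalizationContext) -> SignalSegment:
    """Express rectified amplitude as a percentage of the MVC reference."""
    _require_stage(seg, ("rectified",), "normalize_mvc")
    return replace(
        seg, samples=seg.samples / ctx.semg_mvc * 100.0, stage="normalized"
    )


@dataclass
class PreprocessResult:
    """Outputs of the per-channel pipeline.

    ``normalized`` feeds the amplitude (time-domain) features; ``filtered``
    keeps the same spans unrectified for spectral features.
    """

    normalized: list[SignalSegment]
    filtered: list[SignalSegment]
    context: NormalizationContext


def preprocess_channel(
    sig: ContinuousSignal,
    annotations: Sequence[SegmentAnnotation],
    mvc_annotations: Sequence[SegmentAnnotation],
    low: float = 20.0,
    high: float = 490.0,
    order: int = 4,
    subject: str | None = None,
) -> PreprocessResult:
    """Run segment -> filter -> rectify -> normalize for one channel.

    The MVC reference is computed from the rectified, filtered MVC
    annotations of the same channel before the task segments are normalized.
    """
    if not mvc_annotations:
        raise ConfigError("at least one MVC annotation is required")
    mvc_rect = [
        rectify(bandpass_filter(s, low, high, order))
        for s in segment(sig, mvc_annotations)
    ]
    ctx = mvc_peak(mvc_rect, subject=subject)
    filtered = [
        bandpass_filter(s, low, high, order) for s in segment(sig, annotations)
    ]
    normalized = [normalize_mvc(rectify(f), ctx) for f in filtered]
    return PreprocessResult(normalized=normalized, filtered=filtered, context=ctx)


def preprocess_recording(
    recording: RawRecording,
    annotations: dict[bytes, Sequence[SegmentAnnotation]],
    mvc_annotations: dict[bytes, Sequence[SegmentAnnotation]],
    adc: AdcConfig | None = None,
    channel_names: dict[bytes, str] | None = None,
    **kwargs,
) -> dict[str, PreprocessResult]:
    """Preprocess every annotated MAC stream of a reconstructed recording."""
    adc = adc or AdcConfig()
    channel_names = channel_names or {}
    out: dict[str, PreprocessResult] = {}
    for mac, anns in annotations.items():
        name = channel_names.get(mac, mac.hex())
        sig = ContinuousSignal(
            samples=counts_to_millivolts(recording.streams[mac], adc),
            rate=recording.sample_rate,
            channel=name,
        )
        out[name] = preprocess_channel(
            sig, anns, mvc_annotations.get(mac, ()), **kwargs
        )
    return out


def detect_onsets(
    sig: ContinuousSignal,
    threshold_mv: float,
    min_duration_s: float = 0.5,
) -> list[SegmentAnnotation]:
    """Optional amplitude-threshold onset helper (plumbing, not the primary
    path: segment boundaries are normally calibrated manually).

    Marks spans where the rectified signal's 100 ms moving average exceeds
    ``threshold_mv`` for at least ``min_duration_s``.  Labels are set to NaN;
    the caller assigns force levels.
    """
    w = max(int(round(0.1 * sig.rate)), 1)
    env = np.convolve(np.abs(sig.samples), np.ones(w) / w, mode="same")
    active = env > threshold_mv
    runs: list[tuple[int, int]] = []
    in_run = False
    start = 0
    for i, a in enumerate(active):
        if a and not in_run:
            in_run, start = True, i
        elif not a and in_run:
            in_run = False
            runs.append((start, i))
    if in_run:
        runs.append((start, len(active)))
    min_len = int(min_duration_s * sig.rate)
    return [
        SegmentAnnotation(start=s, end=e, force_label=float("nan"))
        for s, e in runs
        if e - s >= min_len
    ]
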