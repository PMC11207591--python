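"""Synthetic sEMG sessions emulating the grip-force acquisition protocol.

The surrogate signal model is the standard stochastic one for surface EMG:
band-limited (20-490 Hz) Gaussian noise whose amplitude is modulated by
muscle activation.  Activation follows a power law of relative grip force,

    A(level) = (level / 100) ** gamma,      gamma = 1.5 by default,

interpolating between a linear and a strongly nonlinear force-amplitude
relationship.  Each contraction gets 200 ms onset/offset ramps; a broadband
noise floor and an optional 50 Hz line component are added; the analog
signal is offset to the 1.65 V hardware baseline and quantized by the
12-bit, 3.3 V ADC at 1000 Hz; the codes are packetized into the transfer
protocol, one emulated terminal (MAC) per channel.

A default session holds one maximum-voluntary-contraction trial followed by
contractions at every configured force level (100, 80, 60, 40 %MVC),
separated by rest gaps that contain only baseline plus the noise floor.
Ground truth (analog signal, labels, annotations) is kept alongside the
packet stream so every pipeline stage is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .features import WindowingConfig, extract_features
from .grip_model import Dataset
from .preprocess import ContinuousSignal, SegmentAnnotation, preprocess_channel
from .protocol import AdcConfig, Packet, ProtocolConfig, counts_to_millivolts, encode_packet

__all__ = [
    "SynthConfig",
    "SyntheticRecording",
    "generate_contraction",
    "generate_session",
    "generate_feature_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``mvc_amplitude_v`` is the analog RMS amplitude (volts) of the shaped
    noise at 100 %MVC, sized so the waveform uses most of the ADC span
    without frequent clipping.  ``force_levels`` lists the contraction
    levels in order; the first 100 %MVC trial doubles as the normalization
    reference.  Rest gaps are baseline + noise floor only.
    """

    channels: int = 2
    rate: float = 1000.0
    duration_s: float = 3.0
    rest_s: float = 1.0
    force_levels: tuple[float, ...] = (100.0, 80.0, 60.0, 40.0)
    gamma: float = 1.5
    noise_floor: float = 0.02
    powerline_amp: float = 0.0
    ramp_ms: float = 200.0
    mvc_amplitude_v: float = 0.30
    band: tuple[float, float] = (20.0, 490.0)
    adc: AdcConfig = field(default_factory=AdcConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ConfigError("gamma must be > 0")
        if any(not (0 < lv <= 100) for lv in self.force_levels):
            raise ConfigError("force levels must lie in (0, 100]")
        if self.channels < 1:
            raise ConfigError("need at least one channel")
        if self.duration_s < 2.0:
            raise ConfigError("contractions should last at least 2 s")


def _band_limited_noise(
    n: int, rate: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to ``band`` by FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    shaped = np.fft.irfft(spec, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def generate_contraction(
    level: float, cfg: SynthConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Analog contraction signal, shape (channels, samples), volts, no offset.

    Channels are independent draws from the same activation model (two
    synergist forearm muscles driven by the same grip).
    """
    if level <= 0:
        raise ConfigError("force level must be positive")
    rng = rng or np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate))
    amp = cfg.mvc_amplitude_v * (level / 100.0) ** cfg.gamma
    ramp_n = int(round(cfg.ramp_ms * cfg.rate / 1000.0))
    env = np.ones(n)
    if ramp_n > 0:
        env[:ramp_n] = np.linspace(0.0, 1.0, ramp_n, endpoint=False)
        env[-ramp_n:] = np.linspace(1.0, 0.0, ramp_n)
    out = np.empty((cfg.channels, n))
    t = np.arange(n) / cfg.rate
    for ch in range(cfg.channels):
        activation = amp * env * _band_limited_noise(n, cfg.rate, cfg.band, rng)
        floor = cfg.noise_floor * cfg.mvc_amplitude_v * rng.standard_normal(n)
        line = cfg.powerline_amp * cfg.mvc_amplitude_v * np.sin(2 * np.pi * 50.0 * t)
        out[ch] = activation + floor + line
    return out


def _rest(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(round(cfg.rest_s * cfg.rate))
    return cfg.noise_floor * cfg.mvc_amplitude_v * rng.standard_normal((cfg.channels, n))


def _quantize(analog_v: np.ndarray, adc: AdcConfig) -> np.ndarray:
    codes = np.round((analog_v + adc.baseline) / adc.vref * adc.max_code)
    return np.clip(codes, 0, adc.max_code).astype(np.uint16)


def _channel_mac(ch: int) -> bytes:
    return bytes([0x5E, 0x36, 0x00, 0x00, 0x00, ch + 1])


@dataclass
class SyntheticRecording:
    """A full emulated session: ground truth, codes, annotations, packets."""

    analog_v: np.ndarray  # (channels, samples), volts, baseline-free
    codes: np.ndarray  # (channels, samples), 12-bit ADC codes
    annotations: list[SegmentAnnotation]  # shared across channels
    packets: list[Packet]
    macs: list[bytes]
    cfg: SynthConfig

    @property
    def mvc_annotations(self) -> list[SegmentAnnotation]:
        return [a for a in self.annotations if a.force_label == 100.0]

    def channel_signal(self, ch: int) -> ContinuousSignal:
        """Reconstructed mV signal (baseline removed) for one channel."""
        return ContinuousSignal(
            samples=counts_to_millivolts(self.codes[ch], self.cfg.adc),
            rate=self.cfg.rate,
            channel=f"ch{ch + 1}",
        )

    def packet_stream(self) -> bytes:
        return b"".join(encode_packet(p, self.cfg.protocol) for p in self.packets)

    def annotations_frame(self) -> pd.DataFrame:
        rows = [
            {"channel": f"ch{ch + 1}", "start": a.start, "end": a.end,
             "percent_mvc": a.force_label}
            for ch in range(self.cfg.channels)
            for a in self.annotations
        ]
        return pd.DataFrame(rows)


def generate_session(cfg: SynthConfig | None = None) -> SyntheticRecording:
    """Emulate one recording session and its protocol packet stream.

    Layout: rest, then for each configured force level (MVC trial first) a
    contraction followed by a rest gap.  Annotations mark each contraction's
    half-open sample span with its %MVC label.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    chunks: list[np.ndarray] = [_rest(cfg, rng)]
    annotations: list[SegmentAnnotation] = []
    cursor = chunks[0].shape[1]
    for level in cfg.force_levels:
        burst = generate_contraction(level, cfg, rng)
        annotations.append(
            SegmentAnnotation(start=cursor, end=cursor + burst.shape[1], force_label=level)
        )
        chunks.append(burst)
        cursor += burst.shape[1]
        gap = _rest(cfg, rng)
        chunks.append(gap)
        cursor += gap.shape[1]
    analog = np.concatenate(chunks, axis=1)

    spp = cfg.protocol.samples_per_packet
    pad = (-analog.shape[1]) % spp
    if pad:  # pad the tail rest with baseline so packets are full
        analog = np.pad(analog, ((0, 0), (0, pad)))
    codes = _quantize(analog, cfg.adc)

    packets: list[Packet] = []
    macs = [_channel_mac(ch) for ch in range(cfg.channels)]
    n_frames = codes.shape[1] // spp
    for frame in range(n_frames):  # interleave channels as the radio would
        for ch in range(cfg.channels):
            packets.append(
                Packet(
                    mac=macs[ch],
                    frame_seq=frame,
                    samples=codes[ch, frame * spp : (frame + 1) * spp],
                )
            )
    return SyntheticRecording(
        analog_v=analog, codes=codes, annotations=annotations,
        packets=packets, macs=macs, cfg=cfg,
    )


def generate_feature_dataset(
    n_sessions: int = 2,
    cfg: SynthConfig | None = None,
    windowing: WindowingConfig | None = None,
    entropy_bins: int = 64,
) -> Dataset:
    """Desk-scale labeled dataset: preprocess + feature-extract synthetic
    sessions into one table (one row per window, columns per channel).

    Session k is generated with a child seed derived from ``cfg.seed`` so
    the whole dataset is reproducible from one integer.
    """
    cfg = cfg or SynthConfig()
    windowing = windowing or WindowingConfig()
    tables = []
    subjects = []
    for k in range(n_sessions):
        scfg = replace(cfg, seed=(cfg.seed * 1_000_003 + k) % 2**31)
        rec = generate_session(scfg)
        channels = {}
        for ch in range(scfg.channels):
            res = preprocess_channel(
                rec.channel_signal(ch),
                annotations=rec.annotations,
                mvc_annotations=rec.mvc_annotations,
                low=scfg.band[0],
                high=scfg.band[1],
                subject=f"s{k}",
            )
            channels[f"ch{ch + 1}"] = list(zip(res.normalized, res.filtered))
        table = extract_features(channels, windowing, entropy_bins)
        tables.append(table)
        subjects.extend([f"s{k}"] * len(table))
    full = pd.concat(tables, ignore_index=True)
    ds = Dataset.from_feature_table(full)
    ds.subjects = pd.Series(subjects, index=ds.X.index)
    return ds
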