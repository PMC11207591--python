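"""Bit-exact codec for the wireless acquisition terminal's transfer protocol.

Each acquisition terminal streams 12-bit ADC codes over Bluetooth in fixed
116-byte packets: a 2-byte packet header, a 4-byte frame header carrying the
frame sequence counter, the terminal's 6-byte MAC address, fifty 16-bit
samples (100 bytes), a 2-byte end-of-data flag, and a 2-byte packet trailer.
One packet every 50 ms gives 20 packets/s x 50 samples = 1000 samples/s per
terminal.  One terminal carries one sEMG channel, identified by its MAC.

The magic byte values and the sample/frame-header endianness are not fixed by
the hardware description, so they are configurable on
:class:`ProtocolConfig`; the defaults here are declared conventions, chosen
so the codec is deterministic and round-trip testable.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FrameSyncError, PacketLengthError, SampleRangeError

__all__ = [
    "ProtocolConfig",
    "AdcConfig",
    "Packet",
    "RawRecording",
    "encode_packet",
    "decode_packet",
    "decode_stream",
    "reconstruct_streams",
    "counts_to_volts",
    "counts_to_millivolts",
    "total_gain",
    "recording_to_frame",
]

MAC_LEN = 6


def format_mac(mac: bytes) -> str:
    """Colon-separated hex MAC, e.g. ``5e:36:00:00:00:01``."""
    return ":".join(f"{b:02x}" for b in mac)

#: Two-stage analog amplification of the acquisition front end
#: (instrumentation amplifier x inverting/filter stage).
STAGE_GAINS: tuple[float, float] = (45.0, 25.0)


def total_gain(stages: Sequence[float] = STAGE_GAINS) -> float:
    """Total analog gain of the front end: the product of the stage gains."""
    return float(np.prod(np.asarray(stages, dtype=float)))


@dataclass(frozen=True)
class ProtocolConfig:
    """Layout of one transfer-protocol frame.

    The serialized length is ``2 + 4 + 6 + samples_per_packet *
    bytes_per_sample + 2 + 2`` = 116 bytes with the defaults.
    """

    header_magic: bytes = b"\xaa\x55"
    trailer_magic: bytes = b"\x0d\x0a"
    end_flag_magic: bytes = b"\xff\xff"
    frame_header_len: int = 4
    samples_per_packet: int = 50
    bytes_per_sample: int = 2
    packet_period_ms: int = 50
    sample_rate: int = 1000

    def __post_init__(self) -> None:
        for name in ("header_magic", "trailer_magic", "end_flag_magic"):
            if len(getattr(self, name)) != 2:
                raise ConfigError(f"{name} must be exactly 2 bytes")
        if self.frame_header_len != 4:
            raise ConfigError("frame_header_len must be 4 bytes")
        packets_per_second = 1000.0 / self.packet_period_ms
        if self.samples_per_packet * packets_per_second != self.sample_rate:
            raise ConfigError(
                "samples_per_packet x packets_per_second must equal sample_rate: "
                f"{self.samples_per_packet} x {packets_per_second} != {self.sample_rate}"
            )

    @property
    def packet_length(self) -> int:
        """Serialized frame length in bytes (116 with the defaults)."""
        return (
            len(self.header_magic)
            + self.frame_header_len
            + MAC_LEN
            + self.samples_per_packet * self.bytes_per_sample
            + len(self.end_flag_magic)
            + len(self.trailer_magic)
        )

    @property
    def packets_per_second(self) -> float:
        return 1000.0 / self.packet_period_ms


@dataclass(frozen=True)
class AdcConfig:
    """On-chip successive-approximation converter parameters.

    The analog baseline sits at vref/2 (1.65 V) so the alternating sEMG
    waveform is entirely positive at the converter input; reconstruction
    subtracts it again.
    """

    bits: int = 12
    vref: float = 3.3
    baseline: float = 1.65

    def __post_init__(self) -> None:
        if self.bits < 1:
            raise ConfigError("bits must be >= 1")
        if not np.isclose(self.baseline, self.vref / 2):
            raise ConfigError("baseline must equal vref / 2")

    @property
    def levels(self) -> int:
        """Number of distinguishable codes, 2**bits (4096 for 12 bits)."""
        return 2 ** self.bits

    @property
    def max_code(self) -> int:
        return self.levels - 1

    @property
    def lsb_volts(self) -> float:
        """One least-significant-bit step in volts."""
        return self.vref / self.max_code


@dataclass(frozen=True)
class Packet:
    """One decoded protocol frame: terminal MAC, sequence number, ADC codes."""

    mac: bytes
    frame_seq: int
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.mac) != MAC_LEN:
            raise ConfigError(f"mac must be exactly {MAC_LEN} bytes")
        if self.frame_seq < 0:
            raise ConfigError("frame_seq must be non-negative")
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.uint16)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Packet):
            return NotImplemented
        return (
            self.mac == other.mac
            and self.frame_seq == other.frame_seq
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class RawRecording:
    """Per-MAC reconstructed code streams with a report of lost frames.

    ``gaps[mac]`` lists inclusive ``(first_missing, last_missing)`` frame
    sequence ranges; gaps are reported, never filled.
    """

    streams: dict[bytes, np.ndarray]
    frame_seqs: dict[bytes, np.ndarray]
    gaps: dict[bytes, list[tuple[int, int]]]
    sample_rate: int = 1000


def _check_samples(samples: np.ndarray, cfg: ProtocolConfig, adc_max: int = 4095) -> np.ndarray:
    arr = np.asarray(samples)
    if arr.ndim != 1 or arr.shape[0] != cfg.samples_per_packet:
        raise ConfigError(
            f"expected {cfg.samples_per_packet} samples, got shape {arr.shape}"
        )
    if arr.min() < 0 or arr.max() > adc_max:
        raise SampleRangeError(
            f"ADC codes must lie in [0, {adc_max}]; "
            f"got range [{arr.min()}, {arr.max()}]"
        )
    return arr.astype(np.uint16)


def encode_packet(packet: Packet, cfg: ProtocolConfig | None = None) -> bytes:
    """Serialize one packet to its fixed-length wire format.

    Layout: header magic, little-endian uint32 frame sequence, MAC, fifty
    little-endian uint16 samples, end-of-data flag, trailer magic.
    """
    cfg = cfg or ProtocolConfig()
    samples = _check_samples(packet.samples, cfg)
    if packet.frame_seq > 0xFFFFFFFF:
        raise ConfigError("frame_seq does not fit in the 4-byte frame header")
    out = b"".join(
        (
            cfg.header_magic,
            struct.pack("<I", packet.frame_seq),
            packet.mac,
            samples.astype("<u2").tobytes(),
            cfg.end_flag_magic,
            cfg.trailer_magic,
        )
    )
    assert len(out) == cfg.packet_length
    return out


def decode_packet(buf: bytes, cfg: ProtocolConfig | None = None) -> Packet:
    """Parse one packet from the head of ``buf``, validating all magics."""
    cfg = cfg or ProtocolConfig()
    n = cfg.packet_length
    if len(buf) < n:
        raise PacketLengthError(f"need {n} bytes, got {len(buf)}")
    if buf[:2] != cfg.header_magic:
        raise FrameSyncError(
            f"bad packet header {buf[:2]!r}, expected {cfg.header_magic!r}"
        )
    frame_seq = struct.unpack_from("<I", buf, 2)[0]
    mac = bytes(buf[6:12])
    payload_end = 12 + cfg.samples_per_packet * cfg.bytes_per_sample
    samples = np.frombuffer(buf[12:payload_end], dtype="<u2").astype(np.uint16)
    if buf[payload_end : payload_end + 2] != cfg.end_flag_magic:
        raise FrameSyncError("bad end-of-data flag")
    if buf[payload_end + 2 : payload_end + 4] != cfg.trailer_magic:
        raise FrameSyncError("bad packet trailer")
    if samples.max(initial=0) > 4095:
        raise SampleRangeError("decoded sample exceeds 12-bit range")
    return Packet(mac=mac, frame_seq=frame_seq, samples=samples)


def decode_stream(buf: bytes, cfg: ProtocolConfig | None = None) -> list[Packet]:
    """Split a byte stream into consecutive packets and decode each one."""
    cfg = cfg or ProtocolConfig()
    n = cfg.packet_length
    if len(buf) % n != 0:
        raise PacketLengthError(
            f"stream length {len(buf)} is not a multiple of the "
            f"{n}-byte packet length"
        )
    return [decode_packet(buf[i : i + n], cfg) for i in range(0, len(buf), n)]


def reconstruct_streams(
    packets: Iterable[Packet], sample_rate: int = 1000
) -> RawRecording:
    """Group packets by MAC and splice their samples in frame order.

    Packets may arrive interleaved across terminals and out of order.  Within
    each MAC the samples are concatenated by ascending frame sequence; a
    duplicated frame sequence keeps its first occurrence; missing sequence
    numbers are reported as inclusive gap ranges and never interpolated.
    """
    by_mac: dict[bytes, dict[int, np.ndarray]] = {}
    for p in packets:
        by_mac.setdefault(p.mac, {}).setdefault(p.frame_seq, p.samples)
    streams: dict[bytes, np.ndarray] = {}
    frame_seqs: dict[bytes, np.ndarray] = {}
    gaps: dict[bytes, list[tuple[int, int]]] = {}
    for mac, frames in by_mac.items():
        seqs = np.array(sorted(frames), dtype=np.int64)
        streams[mac] = np.concatenate([frames[s] for s in seqs])
        frame_seqs[mac] = seqs
        mac_gaps: list[tuple[int, int]] = []
        for prev, nxt in zip(seqs[:-1], seqs[1:]):
            if nxt > prev + 1:
                mac_gaps.append((int(prev) + 1, int(nxt) - 1))
        gaps[mac] = mac_gaps
    return RawRecording(
        streams=streams, frame_seqs=frame_seqs, gaps=gaps, sample_rate=sample_rate
    )


def counts_to_volts(samples: np.ndarray, adc: AdcConfig | None = None) -> np.ndarray:
    """Map ADC codes to volts and remove the vref/2 baseline.

    ``v = code / (2**bits - 1) * vref - baseline``, so code 0 maps to
    -baseline and full scale maps exactly to +baseline.  The mapping is
    affine and strictly increasing in the code.
    """
    adc = adc or AdcConfig()
    codes = np.asarray(samples)
    if codes.size and (codes.min() < 0 or codes.max() > adc.max_code):
        raise SampleRangeError(
            f"ADC codes must lie in [0, {adc.max_code}]"
        )
    return codes.astype(np.float64) / adc.max_code * adc.vref - adc.baseline


def counts_to_millivolts(samples: np.ndarray, adc: AdcConfig | None = None) -> np.ndarray:
    """Same mapping as :func:`counts_to_volts`, reported in millivolts."""
    return counts_to_volts(samples, adc) * 1000.0


def recording_to_frame(
    recording: RawRecording, adc: AdcConfig | None = None
) -> pd.DataFrame:
    """Tabulate a reconstructed recording: one row per retained sample.

    Columns: ``mac`` (colon-separated hex), ``frame_seq``, ``sample_index``
    (within the spliced stream), ``code``, ``millivolts``.
    """
    adc = adc or AdcConfig()
    parts = []
    for mac, codes in recording.streams.items():
        seqs = recording.frame_seqs[mac]
        per_frame = codes.size // max(len(seqs), 1)
        parts.append(
            pd.DataFrame(
                {
                    "mac": format_mac(mac),
                    "frame_seq": np.repeat(seqs, per_frame),
                    "sample_index": np.arange(codes.size),
                    "code": codes.astype(int),
                    "millivolts": counts_to_millivolts(codes, adc),
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=["mac", "frame_seq", "sample_index", "code", "millivolts"]
        )
    return pd.concat(parts, ignore_index=True)
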