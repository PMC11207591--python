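"""Agreement metrics between two acquisition systems recording the same
muscle: envelope smoothing, lag alignment, the cross-correlation coefficient
(CCC), and relative agreement between RMS amplitudes.

CCC is the Pearson-type coefficient

    CCC = (n sum xy - sum x sum y)
          / sqrt((n sum x^2 - (sum x)^2) (n sum y^2 - (sum y)^2)),

bounded in [-1, 1].  Relative agreement compares RMS amplitudes against a
reference system's RMS y:

    1 - RE = (1 - |x - y| / y) * 100  [%].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "PairedSeries",
    "envelope",
    "align",
    "ccc",
    "relative_agreement",
    "summarize_ccc",
]


@dataclass(frozen=True)
class PairedSeries:
    """Two equal-length processed series plus the lag used to align them."""

    x: np.ndarray
    y: np.ndarray
    lag: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if x.shape != y.shape or x.ndim != 1:
            raise ConfigError("x and y must be equal-length 1-D series")
        if x.size < 2:
            raise ConfigError("paired series need at least 2 samples")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ConfigError("paired series must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size


def envelope(samples: np.ndarray, rate: float = 1000.0, window_ms: float = 100.0) -> np.ndarray:
    """Centered moving-average envelope of a rectified-normalized signal.

    The window is forced to an odd sample count so the average is centered;
    edges use a shrinking window (normalized by the actual overlap), keeping
    the output within [min, max] of the input.
    """
    x = np.asarray(samples, dtype=np.float64)
    w = int(round(window_ms * rate / 1000.0))
    w = max(w + (1 - w % 2), 1)  # odd
    kernel = np.ones(w)
    smoothed = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return smoothed / norm


def align(x: np.ndarray, y: np.ndarray, max_lag: int | None = None) -> PairedSeries:
    """Shift ``y`` by the lag maximizing its cross-correlation with ``x``.

    A positive lag means ``y`` trails ``x`` by that many samples.  Both
    series are mean-centered before correlating; the overlapping region
    (length n - |lag|) is returned.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1:
        raise ConfigError("align expects 1-D series")
    xc = x - x.mean()
    yc = y - y.mean()
    # corr[k] pairs y[n + lag] with x[n]: a positive lag means y trails x
    corr = np.correlate(yc, xc, mode="full")
    lags = np.arange(-(x.size - 1), y.size)
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        corr, lags = corr[keep], lags[keep]
    lag = int(lags[np.argmax(corr)])
    if lag >= 0:
        xs, ys = x, y[lag:]
    else:
        xs, ys = x[-lag:], y
    n = min(xs.size, ys.size)
    return PairedSeries(x=xs[:n], y=ys[:n], lag=lag)


def ccc(p: PairedSeries) -> float:
    """Cross-correlation coefficient of an aligned pair, in [-1, 1]."""
    n = p.n
    sx, sy = p.x.sum(), p.y.sum()
    sxx, syy = np.dot(p.x, p.x), np.dot(p.y, p.y)
    sxy = np.dot(p.x, p.y)
    var_x = n * sxx - sx * sx
    var_y = n * syy - sy * sy
    if var_x <= 0 or var_y <= 0:
        raise ConfigError("CCC is undefined when either series has zero variance")
    return float((n * sxy - sx * sy) / np.sqrt(var_x * var_y))


def relative_agreement(x_rms: float, y_rms: float) -> float:
    """Relative agreement (1 - RE) in percent; ``y_rms`` is the reference."""
    if y_rms <= 0:
        raise ConfigError("reference RMS must be positive")
    return (1.0 - abs(x_rms - y_rms) / y_rms) * 100.0


def summarize_ccc(values: np.ndarray) -> dict[str, float]:
    """Max / min / mean / sample standard deviation of repeated CCC values.

    The standard deviation uses the n-1 (sample) convention; a single value
    yields sd 0 by convention.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ConfigError("summarize_ccc needs at least one value")
    return {
        "max": float(v.max()),
        "min": float(v.min()),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
    }
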