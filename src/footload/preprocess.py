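"""Signal conditioning: zero-lag critically damped low-pass filtering and
static-offset removal.

The low-pass filter is the classical biomechanics realization: a critically
damped analog prototype (repeated real pole, hence no overshoot or ringing on
transients) discretized with the bilinear transform and applied forward and
backward, which doubles the order and cancels the phase shift.  The cutoff is
corrected for the repeated passes so that the *net* -3 dB point sits at the
requested frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_formats import ParameterError

__all__ = ["FilterSpec", "critically_damped_lowpass", "remove_static_offset"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter parameters (defaults: 4th order, zero lag, 20 Hz)."""

    cutoff: float = 20.0
    order: int = 4
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be positive")
        if self.order <= 0 or self.order % 2:
            raise ParameterError("order must be a positive even integer")


def _design(fs: float, spec: FilterSpec):
    """Digital coefficients of one pass of the critically damped filter.

    Critical damping means a repeated real pole.  Each pass cascades
    ``order/passes`` identical first-order sections ``(1-p)/(1 - p z^-1)``
    whose pole ``p`` is real and positive, so the impulse response is
    nonnegative and step inputs can never overshoot (a bilinear-transform
    realization loses this property at cutoffs that are a large fraction of
    the sampling rate, because the mapped pole changes sign).

    The pole is placed so that the *net* response of all ``order`` poles
    across all passes is exactly -3 dB at the requested cutoff: with
    q = 2^(-1/order), solving |H_1(e^{jw})|^2 = q for one section gives the
    quadratic (1-q) p^2 - 2 (1 - q cos w) p + (1-q) = 0, whose root in (0, 1)
    is used.  This plays the role of the usual cutoff-correction factor for
    cascaded forward-backward passes.
    """
    if spec.cutoff >= fs / 2:
        raise ParameterError(
            f"cutoff {spec.cutoff} Hz must be below the Nyquist frequency {fs / 2} Hz"
        )
    passes = 2 if spec.zero_lag else 1
    n_poles = spec.order // passes
    w = 2.0 * np.pi * spec.cutoff / fs          # cutoff, rad/sample
    q = 2.0 ** (-1.0 / spec.order)              # per-pole power gain at cutoff
    c = 1.0 - q * np.cos(w)
    p = (c - np.sqrt(c * c - (1.0 - q) ** 2)) / (1.0 - q)
    b, a = [1.0], [1.0]
    for _ in range(n_poles):
        b = np.polymul(b, [1.0 - p])
        a = np.polymul(a, [1.0, -p])
    return b, a


def critically_damped_lowpass(
    x: np.ndarray, fs: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Apply the zero-lag critically damped low-pass filter to a series.

    Returns a series of the same length with unit DC gain and (for
    ``zero_lag=True``) zero net phase shift.  Being critically damped, the
    filter does not overshoot on step inputs, which matters for signals whose
    zero crossings mark gait events.
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("input series must be 1-D")
    if len(x) < 10:
        raise ParameterError("input series must have at least 10 samples")
    b, a = _design(fs, spec)
    if spec.zero_lag:
        return signal.filtfilt(b, a, x)
    return signal.lfilter(b, a, x)


def remove_static_offset(
    x: np.ndarray, fs: float, static_window_s: float = 1.0
) -> tuple[np.ndarray, float]:
    """Subtract the mean over the initial stationary interval.

    A recording is assumed to begin with the subject standing still for at
    least ``static_window_s``; the window mean captures the constant gravity
    projection on the sensor axis (plus any sensor bias), leaving the dynamic
    component.  Returns ``(offset-free series, offset)``.
    """
    x = np.asarray(x, dtype=float)
    n_window = int(round(static_window_s * fs))
    if n_window < 1 or n_window > len(x):
        raise ParameterError(
            f"static window of {static_window_s} s ({n_window} samples) does not fit "
            f"a series of {len(x)} samples"
        )
    offset = float(np.mean(x[:n_window]))
    return x - offset, offset
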