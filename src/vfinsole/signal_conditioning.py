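"""Conditioning of raw force-sensing-resistor (FSR) insole channels.

Thin-film FSRs are nonlinear, drift with use, and show load-history
(hysteresis) effects.  A voltage-to-force polynomial alone therefore does
not calibrate them well: each channel is mapped through a 4th-order
polynomial of the instantaneous reading plus a moving time-integral term
that compensates for hysteresis, and an additive offset.  The calibrated
series is then passed through a causal digital low-pass filter (20 Hz
default at 50 Hz sampling) to suppress sensor noise before any
derivative-based feature is computed downstream.

All operations are causal and sample-synchronous so the same code path is
valid for streaming use at the 20 ms frame rate of the insole hardware.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.integrate import cumulative_trapezoid

#: Fixed channel order; one FSR channel per anatomical insole area.
AREA_LABELS = ("A", "B", "C", "D", "E", "F")

#: Nominal sampling of the acquisition loop: 50 Hz, i.e. one frame per 20 ms.
NOMINAL_FS_HZ = 50.0

#: Relative tolerance on frame spacing before a series is rejected as
#: non-uniformly sampled.
UNIFORMITY_RTOL = 0.01


class NonUniformSamplingError(ValueError):
    """Raised when a time base deviates from uniform spacing beyond tolerance."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Voltage-to-force calibration for one FSR channel.

    The calibrated force is

        F[i] = poly(v[i]) + integral_gain * I[i] + offset,   clipped at 0,

    where ``poly`` is a 4th-order polynomial (coefficients in ascending
    power order, force units per voltage-unit powers) and ``I[i]`` is the
    trapezoidal moving integral of the voltage over ``integral_window``
    seconds ending at sample ``i`` (shorter at the start of the series).
    The integral term absorbs the slow, loading-history-dependent part of
    the sensor response (hysteresis compensation).
    """

    poly_coeffs: tuple[float, float, float, float, float]
    integral_gain: float = 0.0
    offset: float = 0.0
    integral_window: float = 1.0

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.poly_coeffs)
        if len(coeffs) != 5:
            raise ValueError(
                f"poly_coeffs must have exactly 5 entries, got {len(coeffs)}"
            )
        if not all(np.isfinite(coeffs)):
            raise ValueError("poly_coeffs must be finite")
        if not (self.integral_window > 0):
            raise ValueError("integral_window must be positive")
        object.__setattr__(self, "poly_coeffs", coeffs)

    @classmethod
    def identity(cls) -> "CalibrationCurve":
        """Unit passthrough: force equals the raw reading (already in N)."""
        return cls(poly_coeffs=(0.0, 1.0, 0.0, 0.0, 0.0))

    def to_dict(self) -> dict:
        return {
            "poly_coeffs": list(self.poly_coeffs),
            "integral_gain": self.integral_gain,
            "offset": self.offset,
            "integral_window_s": self.integral_window,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        allowed = {"poly_coeffs", "integral_gain", "offset", "integral_window_s"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown calibration key {sorted(unknown)[0]!r}")
        return cls(
            poly_coeffs=tuple(d["poly_coeffs"]),
            integral_gain=float(d.get("integral_gain", 0.0)),
            offset=float(d.get("offset", 0.0)),
            integral_window=float(d.get("integral_window_s", 1.0)),
        )


@dataclass(frozen=True)
class FsrFrame:
    """One 20 ms sample of the six insole channels.

    ``units`` tags whether ``channels`` holds raw ADC counts ("adc"),
    sensor voltages ("volt") or calibrated forces in newtons ("force").
    """

    t: float
    channels: tuple[float, ...]
    units: str = "adc"

    def __post_init__(self) -> None:
        ch = tuple(float(c) for c in self.channels)
        if len(ch) != 6:
            raise ValueError(f"expected 6 channels (areas A-F), got {len(ch)}")
        if any(c < 0 for c in ch):
            raise ValueError("channel values must be non-negative")
        object.__setattr__(self, "channels", ch)


def check_uniform_sampling(t: np.ndarray, rtol: float = UNIFORMITY_RTOL) -> float:
    """Validate a strictly increasing, uniformly spaced time base.

    Returns the nominal sample spacing.  Raises
    :class:`NonUniformSamplingError` naming the first offending gap.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("empty time series")
    if t.size == 1:
        return 0.0
    gaps = np.diff(t)
    if np.any(gaps <= 0):
        i = int(np.argmax(gaps <= 0))
        raise NonUniformSamplingError(
            f"time base not strictly increasing at index {i + 1} "
            f"(t[{i}]={t[i]:.6g}, t[{i + 1}]={t[i + 1]:.6g})"
        )
    dt = float(np.median(gaps))
    bad = np.abs(gaps - dt) > rtol * dt
    if np.any(bad):
        i = int(np.argmax(bad))
        raise NonUniformSamplingError(
            f"non-uniform sampling at index {i + 1}: gap {gaps[i]:.6g} s "
            f"deviates from nominal {dt:.6g} s beyond {rtol:.0%} tolerance"
        )
    return dt


def moving_integral(x: np.ndarray, dt: float, window: float) -> np.ndarray:
    """Trapezoidal integral of ``x`` over a trailing window of ``window`` s.

    The window is truncated at the start of the series (the integral covers
    whatever history exists), keeping the operation causal and the output
    aligned 1:1 with the input.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if window <= 0:
        raise ValueError("window must be positive")
    if x.size == 1 or dt == 0.0:
        return np.zeros_like(x)
    cum = np.concatenate([[0.0], cumulative_trapezoid(x, dx=dt)])
    w = max(int(round(window / dt)), 1)
    idx = np.arange(x.size)
    lo = np.maximum(idx - w, 0)
    return cum - cum[lo]


def calibrate_channel(
    t: np.ndarray, raw: np.ndarray, curve: CalibrationCurve
) -> np.ndarray:
    """Calibrate one raw FSR series to force units.

    Applies the 4th-order polynomial, the hysteresis-compensating moving
    integral term and the offset, then clips at zero (an FSR cannot report
    tension).  Deterministic: identical inputs yield identical outputs.
    """
    t = np.asarray(t, dtype=float)
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty series")
    if t.shape != raw.shape:
        raise ValueError("time and value series must have equal length")
    dt = check_uniform_sampling(t)
    out = np.polynomial.polynomial.polyval(raw, curve.poly_coeffs)
    if curve.integral_gain != 0.0:
        out = out + curve.integral_gain * moving_integral(
            raw, dt, curve.integral_window
        )
    out = out + curve.offset
    return np.maximum(out, 0.0)


def lowpass(series: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    """Causal 2nd-order Butterworth low-pass filter.

    Applied with :func:`scipy.signal.lfilter` (sample-by-sample, no
    zero-phase refiltering) so the same filter is realizable in a real-time
    loop.  DC gain is exactly 1.  The filter state is initialized to the
    steady state of the first sample, so a series that starts already
    loaded does not produce a spurious start-up transient.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if not (0.0 < cutoff < fs / 2.0):
        raise ValueError(
            f"cutoff must lie in (0, Nyquist); got {cutoff} Hz at fs={fs} Hz"
        )
    b, a = _sig.butter(2, cutoff, btype="low", fs=fs)
    zi = _sig.lfilter_zi(b, a) * series[0]
    out, _ = _sig.lfilter(b, a, series, axis=0, zi=zi)
    return out


def default_curves() -> dict[str, CalibrationCurve]:
    return {label: CalibrationCurve.identity() for label in AREA_LABELS}


@dataclass
class ConditioningConfig:
    """Per-channel calibration plus the shared low-pass stage."""

    curves: dict[str, CalibrationCurve] = field(default_factory=default_curves)
    cutoff_hz: float = 20.0
    fs_hz: float = NOMINAL_FS_HZ

    def __post_init__(self) -> None:
        missing = [a for a in AREA_LABELS if a not in self.curves]
        if missing:
            raise ValueError(f"missing calibration for channel(s) {missing}")

    def condition(self, t: np.ndarray, channels: np.ndarray) -> np.ndarray:
        """Calibrate and low-pass filter a six-channel series.

        ``channels`` is (n, 6) in fixed A-F order; returns the conditioned
        (n, 6) force array.  The sampling rate is taken from the time base.
        """
        channels = np.asarray(channels, dtype=float)
        if channels.ndim != 2 or channels.shape[1] != 6:
            raise ValueError(f"expected (n, 6) channel array, got {channels.shape}")
        t = np.asarray(t, dtype=float)
        dt = check_uniform_sampling(t)
        fs = 1.0 / dt if dt > 0 else self.fs_hz
        out = np.empty_like(channels)
        for j, label in enumerate(AREA_LABELS):
            cal = calibrate_channel(t, channels[:, j], self.curves[label])
            out[:, j] = lowpass(cal, self.cutoff_hz, fs)
        # the filter transient can undershoot slightly below zero
        return np.maximum(out, 0.0)

    def to_dict(self) -> dict:
        return {
            "calibration": {a: self.curves[a].to_dict() for a in AREA_LABELS},
            "filter": {"cutoff_hz": self.cutoff_hz, "fs_hz": self.fs_hz},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditioningConfig":
        allowed = {"calibration", "filter"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown conditioning key {sorted(unknown)[0]!r}")
        curves = default_curves()
        for label, sub in d.get("calibration", {}).items():
            if label not in AREA_LABELS:
                raise ValueError(f"unknown calibration channel {label!r}")
            curves[label] = CalibrationCurve.from_dict(sub)
        filt = d.get("filter", {})
        unknown = set(filt) - {"cutoff_hz", "fs_hz"}
        if unknown:
            raise ValueError(f"unknown filter key {sorted(unknown)[0]!r}")
        return cls(
            curves=curves,
            cutoff_hz=float(filt.get("cutoff_hz", 20.0)),
            fs_hz=float(filt.get("fs_hz", NOMINAL_FS_HZ)),
        )
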