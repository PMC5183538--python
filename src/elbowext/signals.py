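"""Torque and EMG conditioning and the measured torque-angle curve.

Torque traces are low-pass filtered (4th-order Butterworth, 5 Hz cutoff,
zero-phase), EMG is band-pass filtered (10-500 Hz), full-wave rectified,
smoothed with a centered 100 ms moving average and normalized to the MVC
peak. Per-angle MVC torque is the maximum 0.5 s plateau mean over the
trials at that angle, and the torque-angle relationship is the
lowest-order polynomial with R^2 > 0.9 (capped at order 3), resampled on
the 46-point optimization grid.

All filtering is forward-backward (``sosfiltfilt``), which doubles the
effective filter order but introduces no phase lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ValidationError

DEFAULT_RATE = 2000.0  # Hz
TORQUE_CUTOFF = 5.0  # Hz
EMG_BAND = (10.0, 500.0)  # Hz
EMG_WINDOW = 0.100  # s, moving-average envelope window
MVC_WINDOW = 0.5  # s, plateau window for MVC torque extraction


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled channel (torque in Nm or EMG in mV)."""

    samples: np.ndarray
    rate: float = DEFAULT_RATE
    label: str = ""

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1:
            raise ValidationError("samples must be 1-D")
        if not np.all(np.isfinite(x)):
            raise ValidationError("samples must be finite")
        if not self.rate > 0:
            raise ValidationError("sampling rate must be > 0")
        object.__setattr__(self, "samples", x)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate

    def __len__(self):
        return self.samples.size


@dataclass(frozen=True)
class PolyFit:
    """A selected torque-angle polynomial (coefficients lowest order first)."""

    coefficients: np.ndarray
    order: int
    r_squared: float
    meets_threshold: bool = True

    def __call__(self, theta) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(theta, dtype=float), self.coefficients)


def filter_torque(ts: TimeSeries, cutoff: float = TORQUE_CUTOFF) -> TimeSeries:
    """Zero-phase 4th-order Butterworth low-pass at ``cutoff`` Hz."""
    if not ts.rate > 2 * cutoff:
        raise ValidationError(f"cutoff {cutoff} Hz at or above Nyquist for rate {ts.rate} Hz")
    sos = sps.butter(4, cutoff, btype="low", fs=ts.rate, output="sos")
    return TimeSeries(sps.sosfiltfilt(sos, ts.samples), ts.rate, ts.label)


def process_emg(
    ts: TimeSeries, mvc_peak: float, band: tuple[float, float] = EMG_BAND
) -> TimeSeries:
    """Band-pass, rectify, 100 ms moving average, normalize by ``mvc_peak``."""
    if not mvc_peak > 0:
        raise ValidationError("MVC peak must be > 0")
    lo, hi = band
    if not ts.rate > 2 * hi:
        raise ValidationError(f"band edge {hi} Hz at or above Nyquist for rate {ts.rate} Hz")
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=ts.rate, output="sos")
    rectified = np.abs(sps.sosfiltfilt(sos, ts.samples))
    win = max(1, int(round(EMG_WINDOW * ts.rate)))
    kernel = np.ones(win) / win
    envelope = np.convolve(rectified, kernel, mode="same")
    return TimeSeries(envelope / mvc_peak, ts.rate, ts.label)


def extract_mvc_torque(ts: TimeSeries, window: float = MVC_WINDOW) -> float:
    """Peak 0.5 s sliding-window mean of a (filtered) contraction trace, Nm."""
    win = int(round(window * ts.rate))
    if ts.samples.size < win:
        raise ValidationError(
            f"trace of {ts.samples.size} samples shorter than the {window} s window"
        )
    means = np.convolve(ts.samples, np.ones(win) / win, mode="valid")
    return float(np.max(means))


def mvc_torque_from_trials(trials: list[TimeSeries], window: float = MVC_WINDOW) -> float:
    """Per-angle MVC torque: the maximum plateau value over repeated trials."""
    if not trials:
        raise ValidationError("need at least one trial")
    return max(extract_mvc_torque(t, window) for t in trials)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot <= 1e-12 * max(1.0, float(np.sum(y**2))):
        # constant data: define R^2 = 1 when the fit is (numerically) exact
        return 1.0 if ss_res <= 1e-12 * max(1.0, float(np.sum(y**2))) else 0.0
    return 1.0 - ss_res / ss_tot


def fit_torque_angle(
    theta,
    torque,
    r2_threshold: float = 0.9,
    max_order: int = 3,
    order: int | None = None,
) -> PolyFit:
    """Fit the torque-angle points with the lowest adequate polynomial.

    Orders 1, 2, ... are fit by least squares and the lowest one with
    R^2 > ``r2_threshold`` is selected, capped at ``max_order`` (the cap
    order is returned flagged when nothing passes). Passing ``order`` pins
    the order instead of selecting it.
    """
    th = np.asarray(theta, dtype=float)
    tq = np.asarray(torque, dtype=float)
    if th.ndim != 1 or th.shape != tq.shape:
        raise ValidationError("theta and torque must be 1-D arrays of equal length")
    if np.unique(th).size < 4:
        raise ValidationError("need at least 4 distinct joint angles")

    def fit_order(k: int) -> PolyFit:
        if th.size < k + 1:
            raise ValidationError(f"{th.size} points cannot determine an order-{k} polynomial")
        coeffs = np.polynomial.polynomial.polyfit(th, tq, k)
        r2 = _r_squared(tq, np.polynomial.polynomial.polyval(th, coeffs))
        return PolyFit(coeffs, k, r2)

    if order is not None:
        return fit_order(order)
    for k in range(1, max_order + 1):
        pf = fit_order(k)
        if pf.r_squared > r2_threshold:
            return pf
    return PolyFit(pf.coefficients, pf.order, pf.r_squared, meets_threshold=False)


def resample_torque_angle(pf: PolyFit, grid) -> np.ndarray:
    """Evaluate a fitted polynomial on a joint-angle grid (degrees)."""
    return pf(np.asarray(grid, dtype=float))
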