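"""Signal conditioning: mains-hum removal and low-pass filtering.

Force-plate channels are first cleaned of mains hum with a periodic median
filter (the phase-folded median waveform at the hum period is estimated over
the whole record and subtracted), then low-pass filtered with a zero-phase
Butterworth at 40 Hz. Marker channels receive only the Butterworth stage at
20 Hz. ``condition_plate`` / ``condition_markers`` enforce that order.

The periodic median filter estimates, for every phase of the hum period, the
median signal value across all periods. Because the median is robust, a
broadband signal riding on the hum barely perturbs the estimate, so the
subtraction removes the hum and its harmonics while leaving off-harmonic
power essentially untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .exceptions import ParameterError
from .types import ForcePlateRecord

__all__ = [
    "FilterConfig",
    "Signal",
    "periodic_median_filter",
    "butterworth_lowpass",
    "condition_plate",
    "condition_markers",
]


@dataclass
class FilterConfig:
    """Conditioning parameters.

    ``marker_cutoff`` / ``force_cutoff`` are the Butterworth corner
    frequencies (Hz) for marker and force channels; ``butter_order`` is the
    order per pass (an order-2 filter applied forward and backward has an
    effective order of 4); ``hum_freq`` the mains frequency removed from
    force channels.
    """

    marker_cutoff: float = 20.0
    force_cutoff: float = 40.0
    butter_order: int = 2
    zero_phase: bool = True
    hum_freq: float = 50.0

    def __post_init__(self):
        if self.marker_cutoff <= 0 or self.force_cutoff <= 0:
            raise ParameterError("cutoff frequencies must be positive")
        if self.butter_order < 1:
            raise ParameterError("butter_order must be >= 1")
        if self.hum_freq <= 0:
            raise ParameterError("hum_freq must be positive")


@dataclass
class Signal:
    """A single uniformly sampled channel."""

    samples: np.ndarray
    rate: float
    label: str = ""
    units: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if len(self.samples) < 2:
            raise ParameterError("signal must have length >= 2")


def periodic_median_filter(sig: Signal, hum_freq: float | None = None) -> Signal:
    """Subtract the phase-folded median waveform at the mains period.

    The waveform is estimated from the largest whole number of periods,
    de-meaned (so a constant signal passes unchanged), and subtracted
    sample-wise; length and rate are unchanged. Requires at least 3 hum
    periods of data. For rates that are not an integer multiple of
    ``hum_freq`` the waveform is estimated on a rounded-period phase grid and
    subtracted by linear phase interpolation.
    """
    if hum_freq is None:
        hum_freq = 50.0
    if hum_freq <= 0:
        raise ParameterError("hum_freq must be positive")
    x = sig.samples
    n = len(x)
    period = sig.rate / hum_freq
    if period <= 1:
        raise ParameterError("sampling rate must exceed the hum frequency")
    min_len = int(np.ceil(3 * period))
    if n < min_len:
        raise ParameterError(
            f"periodic median filter needs at least 3 hum periods "
            f"({min_len} samples at {sig.rate:g} Hz / {hum_freq:g} Hz); got {n}"
        )
    p = int(round(period))
    if abs(period - p) < 1e-9:
        # integer period: fold into (n_periods, p) and take column medians
        n_full = (n // p) * p
        folded = x[:n_full].reshape(-1, p)
        wave = np.median(folded, axis=0)
        wave -= wave.mean()
        reps = int(np.ceil(n / p))
        correction = np.tile(wave, reps)[:n]
    else:
        # non-integer period: truncate to whole periods, bin by nearest phase,
        # subtract by linear interpolation in phase
        n_full = int(np.floor(n / period) * period)
        idx = np.arange(n_full)
        phase_bin = np.round((idx % period) / period * p).astype(int) % p
        wave = np.empty(p)
        for b in range(p):
            vals = x[:n_full][phase_bin == b]
            wave[b] = np.median(vals) if len(vals) else 0.0
        wave -= wave.mean()
        grid = np.arange(p + 1)
        wave_ext = np.append(wave, wave[0])
        phase_all = (np.arange(n) % period) / period * p
        correction = np.interp(phase_all, grid, wave_ext)
    return replace(sig, samples=x - correction)


def butterworth_lowpass(
    sig: Signal, cutoff: float, order: int = 2, zero_phase: bool = True
) -> Signal:
    """Low-pass Butterworth filter; forward-backward when ``zero_phase``.

    Zero-phase application squares the magnitude response (gain 1/2 at the
    corner for order 2) and introduces no lag, which matters because the
    target-error metrics are temporal averages of distances. Edges are
    handled by reflective padding of roughly one settling length.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    if cutoff >= sig.rate / 2:
        raise ParameterError(
            f"cutoff {cutoff:g} Hz must be below the Nyquist frequency "
            f"{sig.rate / 2:g} Hz"
        )
    if order < 1:
        raise ParameterError("order must be >= 1")
    sos = sps.butter(order, cutoff, btype="low", fs=sig.rate, output="sos")
    x = sig.samples
    if zero_phase:
        settle = int(min(len(x) - 1, max(24, round(3 * sig.rate / cutoff))))
        y = sps.sosfiltfilt(sos, x, padtype="even", padlen=settle)
    else:
        y = sps.sosfilt(sos, x)
    return replace(sig, samples=y)


def condition_plate(plate: ForcePlateRecord, cfg: FilterConfig) -> ForcePlateRecord:
    """Condition all six plate channels: hum filter first, then Butterworth."""
    channels = {}
    for name in ("fx", "fy", "fz", "mx", "my", "mz"):
        s = Signal(getattr(plate, name), plate.rate, label=name)
        s = periodic_median_filter(s, cfg.hum_freq)
        s = butterworth_lowpass(s, cfg.force_cutoff, cfg.butter_order, cfg.zero_phase)
        channels[name] = s.samples
    return ForcePlateRecord(
        rate=plate.rate,
        plate_size=plate.plate_size,
        origin=plate.origin,
        yaw=plate.yaw,
        z0=plate.z0,
        label=plate.label,
        **channels,
    )


def condition_markers(
    markers: dict, rate: float, cfg: FilterConfig
) -> dict:
    """Low-pass each marker coordinate; no hum stage on kinematic data."""
    out = {}
    for name, traj in markers.items():
        traj = np.asarray(traj, dtype=float)
        cols = []
        for j in range(traj.shape[1]):
            s = Signal(traj[:, j], rate, label=f"{name}:{'xyz'[j]}")
            cols.append(
                butterworth_lowpass(
                    s, cfg.marker_cutoff, cfg.butter_order, cfg.zero_phase
                ).samples
            )
        out[name] = np.column_stack(cols)
    return out
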