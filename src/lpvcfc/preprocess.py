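"""Band-pass filtering and analytic-signal phase/amplitude extraction.

The filtering scheme is a two-way (forward-backward, zero net phase)
least-squares FIR band-pass.  The filter order follows the "three cycles
of the low cut-off" rule: ``round(3 * fs / low_cutoff)`` taps, so that
slower bands get proportionally longer filters.  Instantaneous phase and
amplitude come from the analytic signal (Hilbert transform).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt, firls, hilbert

from .core import BandSpec, TimeSeries

__all__ = [
    "PhaseSeries",
    "EnvelopeSeries",
    "fir_order_for_band",
    "design_bandpass_fir",
    "bandpass_twoway",
    "analytic_phase_amplitude",
    "dominant_subband",
    "normalize_envelope",
]


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phase in radians, wrapped to (-pi, pi]."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        # np.angle already lands in [-pi, pi]; fold the -pi endpoint over.
        arr = np.where(arr <= -np.pi, arr + 2 * np.pi, arr)
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class EnvelopeSeries:
    """Instantaneous amplitude (nonnegative) per sample."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if np.any(arr < 0):
            raise ValueError("envelope values must be nonnegative")
        object.__setattr__(self, "values", arr)


def fir_order_for_band(fs: float, low_cutoff: float, cycles: int = 3) -> int:
    """FIR order spanning ``cycles`` periods of the low cut-off frequency.

    Returns ``round(cycles * fs / low_cutoff)``.
    """
    if low_cutoff <= 0:
        raise ValueError("low_cutoff must be positive")
    return int(np.round(cycles * fs / low_cutoff))


def design_bandpass_fir(
    fs: float, band: BandSpec, order: int | None = None, transition: float = 0.25
) -> np.ndarray:
    """Design a linear-phase least-squares band-pass FIR filter.

    Transition bands extend 25% of each cut-off beyond the pass band
    edges (clamped to stay below Nyquist) and are fitted as explicit
    linear ramps.  The tap count is forced odd so the filter is type I
    (well-defined band-pass response), and the taps are rescaled so the
    response at the band center is exactly one: narrow bands combined
    with short filters otherwise bias the pass-band gain, which would
    leak band-dependent scale into downstream coupling estimates.
    """
    nyq = fs / 2.0
    if band.high >= nyq:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {nyq:g} Hz")
    if order is None:
        order = fir_order_for_band(fs, band.low)
    numtaps = int(order) + 1
    if numtaps % 2 == 0:
        numtaps += 1
    f1 = band.low * (1.0 - transition)
    f4 = band.high * (1.0 + transition)
    if f4 >= nyq:
        f4 = 0.5 * (band.high + nyq)
    bands = [0.0, f1, f1, band.low, band.low, band.high, band.high, f4, f4, nyq]
    desired = [0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
    taps = firls(numtaps, bands, desired, fs=fs)
    k = np.arange(numtaps) - (numtaps - 1) / 2
    center_gain = np.abs(np.sum(taps * np.exp(-2j * np.pi * band.center / fs * k)))
    return taps / center_gain


def _required_length(order: int) -> int:
    # two-way filtering needs comfortably more data than the filter span
    return 3 * order


def bandpass_twoway(
    x: TimeSeries,
    band: BandSpec,
    order: int | None = None,
    cap_order: bool = False,
) -> TimeSeries:
    """Zero-phase band-pass filter (forward-backward FIR).

    Parameters
    ----------
    x
        Input series (single channel).
    band
        Pass band in Hz; ``band.high`` must be below Nyquist.
    order
        Filter order; default is the three-cycle rule for ``band.low``.
    cap_order
        If True and the designed order is too long for the signal, shrink
        it to fit (with a warning) instead of raising.  Useful for short
        trials with slow bands, where the nominal delta-band filter would
        exceed the trial length.

    Returns
    -------
    TimeSeries of the same length with zero net phase distortion.
    """
    values = np.asarray(x.values, dtype=float)
    if values.ndim != 1:
        raise ValueError("bandpass_twoway expects a single-channel series")
    n = values.size
    if order is None:
        order = fir_order_for_band(x.fs, band.low)
    if _required_length(order) >= n:
        if not cap_order:
            raise ValueError(
                f"signal of {n} samples is too short for a filter of order {order} "
                f"(needs > {_required_length(order)}); pass cap_order=True to shrink"
            )
        capped = max(n // 3 - 1, 8)
        warnings.warn(
            f"filter order capped from {order} to {capped} to fit a {n}-sample signal",
            stacklevel=2,
        )
        order = capped
    taps = design_bandpass_fir(x.fs, band, order=order)
    padlen = min(3 * (len(taps) - 1), n - 1)
    filtered = filtfilt(taps, [1.0], values, padlen=padlen)
    return TimeSeries(filtered, x.fs)


def analytic_phase_amplitude(x: TimeSeries) -> tuple[PhaseSeries, EnvelopeSeries]:
    """Instantaneous phase and amplitude via the analytic signal.

    The phase is the angle and the envelope the magnitude of
    ``hilbert(x)``.  Both are per-sample series at the input rate.
    """
    values = np.asarray(x.values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("analytic_phase_amplitude expects a nonempty single-channel series")
    analytic = hilbert(values)
    return (
        PhaseSeries(np.angle(analytic), x.fs),
        EnvelopeSeries(np.abs(analytic), x.fs),
    )


def subband_candidates(band: BandSpec, step: float = 0.5, width: float = 1.0) -> list[BandSpec]:
    """Candidate sub-bands of ``width`` Hz stepped by ``step`` across ``band``."""
    if width > band.width + 1e-12:
        raise ValueError("sub-band width exceeds the band width")
    lows: list[float] = []
    lo = band.low
    while lo + width <= band.high + 1e-9:
        lows.append(lo)
        lo += step
    return [BandSpec(lo, min(lo + width, band.high)) for lo in lows]


def dominant_subband(
    x: TimeSeries,
    band: BandSpec,
    step: float = 0.5,
    width: float = 1.0,
    cap_order: bool = False,
) -> BandSpec:
    """Sub-band of ``band`` with the highest band-passed signal power.

    Scans ``width``-Hz windows placed at ``band.low, band.low + step, ...``
    and returns the one whose band-passed signal has maximal sample
    variance.  Ties break toward the lower band.  Used to pin the phase
    driver to the spectral peak of a wide low-frequency band.
    """
    candidates = subband_candidates(band, step=step, width=width)
    variances = [
        np.var(bandpass_twoway(x, cand, cap_order=cap_order).values) for cand in candidates
    ]
    return candidates[int(np.argmax(variances))]


def normalize_envelope(A: EnvelopeSeries | np.ndarray) -> np.ndarray:
    """Scale an envelope to unit Euclidean norm (the model target ``y``).

    Removes overall high-band power from the coupling estimate so that
    only the shape of the envelope matters.
    """
    values = A.values if isinstance(A, EnvelopeSeries) else np.asarray(A, dtype=float)
    norm = np.linalg.norm(values)
    if norm == 0:
        raise ValueError("cannot normalize an all-zero envelope")
    return values / norm
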