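"""Comodulograms: coupling maps over phase-band x amplitude-band grids.

A comodulogram evaluates one coupling estimator at every cell of a grid of
(phase band, amplitude band) pairs.  The default grids follow common EEG
practice: amplitude bands tile 20-80 Hz edge-to-edge in 2 Hz steps, phase
bands of 0.5 Hz width are centered on integer frequencies 2-10 Hz.
Batch maps are averaged element-wise and normalized by the global maximum
for cross-method comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lpvar
from .baselines import BASELINE_METHODS
from .cfc import CFCOptions, _trim_amount
from .core import BandSpec, TimeSeries
from .preprocess import (
    analytic_phase_amplitude,
    bandpass_twoway,
    fir_order_for_band,
    normalize_envelope,
)

__all__ = [
    "ComodulogramGrid",
    "bands_from_centers",
    "bands_from_edges",
    "make_band_grids",
    "compute_comodulogram",
    "average_and_normalize",
    "marginal_profiles",
]


@dataclass(frozen=True)
class ComodulogramGrid:
    """CFC values over ordered phase x amplitude band lists."""

    phase_bands: tuple[BandSpec, ...]
    amp_bands: tuple[BandSpec, ...]
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.phase_bands), len(self.amp_bands)):
            raise ValueError("values shape must match (n_phase_bands, n_amp_bands)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "phase_bands", tuple(self.phase_bands))
        object.__setattr__(self, "amp_bands", tuple(self.amp_bands))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def argmax_cell(self) -> tuple[BandSpec, BandSpec]:
        """(phase band, amplitude band) of the global maximum.

        Ties resolve toward the lower bands (first occurrence in
        row-major order).
        """
        i, j = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return self.phase_bands[i], self.amp_bands[j]


def bands_from_centers(start: float, stop: float, step: float, width: float) -> tuple[BandSpec, ...]:
    """Bands of ``width`` Hz centered at ``start, start+step, ..., stop``."""
    centers = np.arange(start, stop + step / 2, step)
    return tuple(BandSpec(c - width / 2, c + width / 2) for c in centers)


def bands_from_edges(start: float, stop: float, step: float, width: float) -> tuple[BandSpec, ...]:
    """Bands with low edges at ``start, start+step, ...`` while they fit in ``[start, stop]``."""
    if width > stop - start:
        raise ValueError("band width exceeds the covered range")
    lows = []
    lo = start
    while lo + width <= stop + 1e-9:
        lows.append(lo)
        lo += step
    return tuple(BandSpec(lo, lo + width) for lo in lows)


def make_band_grids(
    phase_range: tuple[float, float] = (2.0, 10.0),
    phase_step: float = 1.0,
    phase_width: float = 0.5,
    amp_range: tuple[float, float] = (20.0, 80.0),
    amp_step: float = 2.0,
    amp_width: float = 2.0,
) -> tuple[tuple[BandSpec, ...], tuple[BandSpec, ...]]:
    """Default comodulogram grids.

    Phase bands are centered on the stated frequencies (width 0.5 Hz
    around 2, 3, ..., 10 Hz -> 9 bands); amplitude bands tile the range
    edge-to-edge (20-22, 22-24, ..., 78-80 Hz -> 30 bands).
    """
    phase_bands = bands_from_centers(phase_range[0], phase_range[1], phase_step, phase_width)
    amp_bands = bands_from_edges(amp_range[0], amp_range[1], amp_step, amp_width)
    return phase_bands, amp_bands


def _band_series(x: TimeSeries, bands, want: str):
    """Band-pass each band once; return phase or envelope plus filter order."""
    out = []
    for band in bands:
        filtered = bandpass_twoway(x, band)
        P, A = analytic_phase_amplitude(filtered)
        order = fir_order_for_band(x.fs, band.low)
        out.append((P.values if want == "phase" else A.values, order))
    return out


def compute_comodulogram(
    x: TimeSeries,
    phase_bands,
    amp_bands,
    method: str = "lpvar",
    options: CFCOptions | None = None,
) -> ComodulogramGrid:
    """One coupling value per (phase band, amplitude band) cell.

    Each band is filtered once and the phase/envelope series reused across
    cells.  For the LPV-AR estimator, structure selection runs per cell
    (unless a fixed structure is supplied in ``options``) and per-cell
    permutation seeds derive from ``options.seed`` so the map is
    deterministic and independent of traversal order.
    """
    if options is None:
        options = CFCOptions()
    nyq = x.fs / 2
    for band in tuple(phase_bands) + tuple(amp_bands):
        if band.high >= nyq:
            raise ValueError(f"band {band} exceeds the Nyquist frequency")
    phases = _band_series(x, phase_bands, "phase")
    amps = _band_series(x, amp_bands, "envelope")
    n = x.n_samples
    seed_seq = np.random.SeedSequence(options.seed if options.seed is not None else 0)
    cell_seeds = seed_seq.spawn(len(phases) * len(amps))
    values = np.empty((len(phases), len(amps)))
    for i, (phase_full, order_L) in enumerate(phases):
        for j, (amp_full, order_H) in enumerate(amps):
            trim = 0
            if options.trim_edges:
                trim = _trim_amount(n, order_L, order_H)
            phase = phase_full[trim : n - trim]
            amp = amp_full[trim : n - trim]
            if method == "lpvar":
                y = normalize_envelope(amp)
                s = lpvar.build_scheduling(phase)
                rng = np.random.default_rng(cell_seeds[i * len(amps) + j])
                value, _, _ = lpvar.lpvar_cfc(
                    y,
                    s,
                    structure=options.structure,
                    p_grid=options.p_grid,
                    q_grid=options.q_grid,
                    lam_init=options.lam_init,
                    lam_grid=options.lam_grid,
                    n_permutations=options.n_permutations,
                    rng=rng,
                )
            else:
                value = float(BASELINE_METHODS[method](amp, phase))
            values[i, j] = value
    return ComodulogramGrid(tuple(phase_bands), tuple(amp_bands), values, method)


def average_and_normalize(maps: list[ComodulogramGrid]) -> ComodulogramGrid:
    """Element-wise mean across realizations, then division by the global max."""
    if not maps:
        raise ValueError("need at least one map")
    first = maps[0]
    for m in maps[1:]:
        if m.phase_bands != first.phase_bands or m.amp_bands != first.amp_bands:
            raise ValueError("maps must share identical band grids")
        if m.method != first.method:
            raise ValueError("maps must come from the same estimator")
    mean = np.mean([m.values for m in maps], axis=0)
    peak = mean.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero averaged map")
    return ComodulogramGrid(first.phase_bands, first.amp_bands, mean / peak, first.method)


def marginal_profiles(grid: ComodulogramGrid) -> tuple[np.ndarray, np.ndarray]:
    """Mean coupling along each axis, each normalized to its own maximum.

    Returns ``(phase_profile, amp_profile)``: the phase profile averages
    over amplitude bands (one value per phase band) and vice versa.
    """
    phase_profile = grid.values.mean(axis=1)
    amp_profile = grid.values.mean(axis=0)
    if phase_profile.max() > 0:
        phase_profile = phase_profile / phase_profile.max()
    if amp_profile.max() > 0:
        amp_profile = amp_profile / amp_profile.max()
    return phase_profile, amp_profile
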