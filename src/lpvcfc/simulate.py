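"""Seeded generators for coupled synthetic signals and labeled trials.

Two simulation sets emulate a narrowband low-frequency driver that
amplitude-modulates a high-frequency carrier in additive Gaussian noise:

* Set I (monophasic): the carrier amplitude is a logistic function of the
  driver, ``1 / (1 + exp(-3 x_L))`` — maximal at driver peaks only.
* Set II (biphasic): the same factor shifted by -0.5, so the carrier
  amplitude magnitude is maximal at both peaks and troughs of the driver.

The driver is band-limited white Gaussian noise (1 Hz band around ``f_L``)
rescaled to unit sample variance; the final signal is driver + modulated
carrier + white noise of standard deviation ``sigma_u``.

Everything is a pure function of its spec, including the seed.  Batches
derive per-realization seeds from the master seed with a documented
counter scheme (``(master * 1_000_003 + i) mod (2^31 - 1)``), so any
realization can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import BandSpec, TimeSeries
from .preprocess import bandpass_twoway

__all__ = [
    "SimulationSpec",
    "LabeledTrials",
    "generate_low_component",
    "generate_modulated_high",
    "generate_components",
    "generate_signal",
    "batch_realizations",
    "derive_seed",
    "generate_labeled_trials",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one coupled-signal realization.

    Defaults reproduce the reference simulation conditions: a 4 Hz driver
    modulating a 60 Hz carrier over 6 s at 240 Hz with noise sd 0.5.
    """

    coupling_set: str = "I"
    f_L: float = 4.0
    f_H: float = 60.0
    fs: float = 240.0
    duration: float = 6.0
    driver_bandwidth: float = 1.0
    sigma_u: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_set not in ("I", "II"):
            raise ValueError("coupling_set must be 'I' or 'II'")
        if not (0 < self.f_L < self.f_H < self.fs / 2):
            raise ValueError("frequencies must satisfy 0 < f_L < f_H < fs/2")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        n = self.duration * self.fs
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be a positive integer")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def driver_band(self) -> BandSpec:
        half = self.driver_bandwidth / 2.0
        return BandSpec(self.f_L - half, self.f_L + half)


def generate_low_component(spec: SimulationSpec, rng: np.random.Generator | None = None) -> TimeSeries:
    """Band-limited Gaussian driver at ``f_L``, unit sample variance.

    White Gaussian noise is band-passed to ``f_L +- bandwidth/2`` with the
    two-way FIR filter and rescaled so its sample variance is exactly one.
    """
    if spec.driver_band.high >= spec.fs / 2:
        raise ValueError("driver band exceeds the Nyquist frequency")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    white = TimeSeries(rng.standard_normal(spec.n_samples), spec.fs)
    x_L = bandpass_twoway(white, spec.driver_band).values
    std = x_L.std()
    if std == 0:
        raise ValueError("degenerate driver: zero variance after filtering")
    return TimeSeries(x_L / std, spec.fs)


def modulation_factor(x_L: np.ndarray, coupling_set: str) -> np.ndarray:
    """Instantaneous carrier amplitude as a function of the driver.

    Set I: logistic ``1/(1 + exp(-3 x_L))``, strictly in (0, 1).
    Set II: the same minus 0.5, strictly in (-0.5, 0.5).
    """
    factor = 1.0 / (1.0 + np.exp(-3.0 * np.asarray(x_L, dtype=float)))
    if coupling_set == "II":
        factor = factor - 0.5
    elif coupling_set != "I":
        raise ValueError("coupling_set must be 'I' or 'II'")
    return factor


def generate_modulated_high(x_L: TimeSeries, f_H: float, coupling_set: str = "I") -> TimeSeries:
    """Carrier at ``f_H`` amplitude-modulated by the driver ``x_L``."""
    if f_H >= x_L.fs / 2:
        raise ValueError("carrier frequency must lie below Nyquist")
    n = np.arange(x_L.n_samples)
    carrier = np.sin(2 * np.pi * f_H / x_L.fs * n)
    return TimeSeries(modulation_factor(x_L.values, coupling_set) * carrier, x_L.fs)


def generate_components(spec: SimulationSpec) -> tuple[TimeSeries, TimeSeries, TimeSeries]:
    """The three seeded components ``(x_L, x_H, u)`` of one realization."""
    rng = np.random.default_rng(spec.seed)
    x_L = generate_low_component(spec, rng=rng)
    x_H = generate_modulated_high(x_L, spec.f_H, spec.coupling_set)
    u = TimeSeries(spec.sigma_u * rng.standard_normal(spec.n_samples), spec.fs)
    return x_L, x_H, u


def generate_signal(spec: SimulationSpec) -> TimeSeries:
    """One realization ``x = x_H + x_L + u``."""
    x_L, x_H, u = generate_components(spec)
    return TimeSeries(x_H.values + x_L.values + u.values, spec.fs)


def derive_seed(master_seed: int, index: int) -> int:
    """Per-realization seed from a master seed: a fixed affine counter."""
    return (master_seed * 1_000_003 + index) % (2**31 - 1)


def batch_realizations(spec: SimulationSpec, n: int) -> list[TimeSeries]:
    """``n`` independent realizations; seeds derived from ``spec.seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        generate_signal(replace(spec, seed=derive_seed(spec.seed, i))) for i in range(n)
    ]


@dataclass(frozen=True)
class LabeledTrials:
    """Multi-channel labeled trials, shape ``(n_trials, n_channels, N)``."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def trial(self, i: int) -> TimeSeries:
        return TimeSeries(self.data[i], self.fs, channel_names=self.channel_names)


def generate_labeled_trials(
    n_classes: int,
    n_trials_per_class: int,
    n_channels: int,
    coupling_map: np.ndarray,
    seed: int = 0,
    f_L: float = 4.0,
    f_H: float = 60.0,
    fs: float = 240.0,
    duration: float = 3.0,
    sigma_u: float = 0.5,
    channel_names: tuple[str, ...] | None = None,
) -> LabeledTrials:
    """Synthetic multi-channel trials with class-dependent coupling gains.

    This is a synthetic stand-in for movement-attempt EEG: no real
    recordings are emulated, only the coupling structure that the decoding
    pipeline is meant to detect.  ``coupling_map[c, ch]`` in [0, 1] sets
    how strongly the ``f_L`` driver modulates the ``f_H`` carrier on
    channel ``ch`` for class ``c``: gain 1 is full monophasic (set I)
    modulation, gain 0 a constant-amplitude carrier (no coupling).  Each
    channel gets an independent driver and noise realization.

    Trials are returned in class-blocked order with integer labels
    ``0..n_classes-1``.
    """
    coupling_map = np.asarray(coupling_map, dtype=float)
    if coupling_map.shape != (n_classes, n_channels):
        raise ValueError(
            f"coupling_map must have shape ({n_classes}, {n_channels}), got {coupling_map.shape}"
        )
    if np.any(coupling_map < 0) or np.any(coupling_map > 1):
        raise ValueError("coupling gains must lie in [0, 1]")
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(n_channels))
    base = SimulationSpec(
        coupling_set="I", f_L=f_L, f_H=f_H, fs=fs, duration=duration, sigma_u=sigma_u
    )
    n = base.n_samples
    carrier = np.sin(2 * np.pi * f_H / fs * np.arange(n))
    n_trials = n_classes * n_trials_per_class
    data = np.empty((n_trials, n_channels, n))
    labels = np.empty(n_trials, dtype=int)
    t = 0
    for c in range(n_classes):
        for _ in range(n_trials_per_class):
            for ch in range(n_channels):
                sub_seed = derive_seed(seed, t * n_channels + ch)
                rng = np.random.default_rng(sub_seed)
                spec = replace(base, seed=sub_seed)
                x_L = generate_low_component(spec, rng=rng).values
                g = coupling_map[c, ch]
                # gain interpolates between constant amplitude 0.5 and
                # full logistic modulation; bounds stay in (0, 1)
                factor = g * modulation_factor(x_L, "I") + (1.0 - g) * 0.5
                u = sigma_u * rng.standard_normal(n)
                data[t, ch] = factor * carrier + x_L + u
            labels[t] = c
            t += 1
    return LabeledTrials(data, labels, fs, channel_names)
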