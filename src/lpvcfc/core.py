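"""Shared containers for sampled signals and frequency bands.

These are deliberately thin: a :class:`TimeSeries` is an array plus a
sampling rate, a :class:`BandSpec` is a pair of band edges in Hz.  All
estimators in the package operate on these two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "BandSpec", "NAMED_BANDS"]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values
        Samples, shape ``(N,)`` for a single channel or ``(n_channels, N)``
        for a multi-channel recording.
    fs
        Sampling rate in Hz, strictly positive.
    channel_names
        Optional channel labels for multi-channel data; length must match
        the leading axis of ``values``.
    """

    values: np.ndarray
    fs: float
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim not in (1, 2):
            raise ValueError("values must be 1-D (single channel) or 2-D (channels x samples)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("values must be finite")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.channel_names is not None:
            if arr.ndim != 2 or len(self.channel_names) != arr.shape[0]:
                raise ValueError("channel_names length must match number of channels")
            object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "values", arr)

    @property
    def n_samples(self) -> int:
        return self.values.shape[-1]

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[0]

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, name_or_index: str | int) -> "TimeSeries":
        """Extract one channel as a single-channel series."""
        if self.values.ndim == 1:
            raise ValueError("series is already single-channel")
        if isinstance(name_or_index, str):
            if self.channel_names is None:
                raise KeyError("series has no channel names")
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return TimeSeries(self.values[idx], self.fs)


@dataclass(frozen=True)
class BandSpec:
    """A frequency band ``[low, high]`` in Hz with an optional label."""

    low: float
    high: float
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band edges must satisfy 0 < low < high, got [{self.low}, {self.high}]")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, freq: float) -> bool:
        """True if ``freq`` lies in the closed interval [low, high]."""
        return self.low <= freq <= self.high

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = f" ({self.label})" if self.label else ""
        return f"[{self.low:g}, {self.high:g}] Hz{tag}"


#: Canonical EEG band definitions used for trial-feature extraction.
NAMED_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec(0.5, 3.0, "D"),
    "theta": BandSpec(4.0, 8.0, "T"),
    "alpha": BandSpec(8.5, 12.0, "A"),
    "beta": BandSpec(12.5, 30.0, "B"),
    "gamma": BandSpec(30.5, 60.0, "G"),
    "high_gamma": BandSpec(60.0, 70.0, "HG"),
}
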