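"""Reference phase-amplitude coupling measures: MVL, PLV, MI, GLM.

All four operate on the same inputs as the LPV-AR estimator — the
instantaneous low-band phase ``P_L`` and high-band amplitude ``A_H`` —
so every method sees identical band-passed, edge-trimmed series.

* MVL: magnitude of the mean complex vector ``A_H exp(j P_L)``.
* PLV: phase locking between ``P_L`` and the analytic phase of ``A_H``.
* MI: Kullback-Leibler divergence of the phase-binned mean amplitude
  distribution from uniform, normalized to [0, 1].
* GLM: variance in ``A_H`` explained by ``[cos P_L, sin P_L, 1]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import EnvelopeSeries, PhaseSeries

__all__ = [
    "PhaseBinDistribution",
    "GLMFit",
    "mvl",
    "plv",
    "plv_from_phases",
    "phase_bin_distribution",
    "modulation_index",
    "glm_index",
    "BASELINE_METHODS",
]


def _as_array(x) -> np.ndarray:
    if isinstance(x, (PhaseSeries, EnvelopeSeries)):
        return x.values
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class PhaseBinDistribution:
    """Normalized phase-binned mean-amplitude distribution.

    ``probs`` sums to one over the occupied bins; ``occupied`` marks bins
    that received at least one phase sample.
    """

    probs: np.ndarray
    bin_edges: np.ndarray
    occupied: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())


@dataclass(frozen=True)
class GLMFit:
    """Cosine/sine/intercept regression fit of the envelope on the phase."""

    w_glm: np.ndarray
    r2: float


def mvl(A, P) -> float:
    """Mean vector length: ``| mean( A(n) exp(j P(n)) ) |``.

    Zero under uniform radial symmetry (no coupling); grows with
    phase-clustered amplitude.  Scales linearly with the envelope.
    """
    A, P = _as_array(A), _as_array(P)
    if A.size == 0 or A.shape != P.shape:
        raise ValueError("amplitude and phase must be nonempty and equal-length")
    return float(np.abs(np.mean(A * np.exp(1j * P))))


def plv_from_phases(P_L, P_AH) -> float:
    """Phase-locking value ``| mean exp(j (P_L - P_AH)) |`` of two phase series."""
    P_L, P_AH = _as_array(P_L), _as_array(P_AH)
    if P_L.shape != P_AH.shape or P_L.size == 0:
        raise ValueError("phase series must be nonempty and equal-length")
    return float(np.abs(np.mean(np.exp(1j * (P_L - P_AH)))))


def plv(A, P, demean: bool = True) -> float:
    """Phase locking between the low-band phase and the envelope's phase.

    The envelope's own instantaneous phase is extracted with the analytic
    signal; by default the envelope is demeaned first, since a strictly
    positive envelope otherwise yields a degenerate (near-constant) phase.
    """
    A, P = _as_array(A), _as_array(P)
    if A.shape != P.shape or A.size == 0:
        raise ValueError("amplitude and phase must be nonempty and equal-length")
    centered = A - A.mean() if demean else A
    if np.allclose(centered, 0):
        raise ValueError("constant envelope has no analytic phase")
    P_AH = np.angle(hilbert(centered))
    return plv_from_phases(P, P_AH)


def phase_bin_distribution(A, P, n_bins: int = 18) -> PhaseBinDistribution:
    """Mean amplitude per phase bin, normalized to a distribution.

    The phase axis (-pi, pi] is split into ``n_bins`` equal left-open /
    right-closed bins.  Bins that receive no phase sample are excluded
    from the normalization with a warning.
    """
    A, P = _as_array(A), _as_array(P)
    if A.shape != P.shape or A.size == 0:
        raise ValueError("amplitude and phase must be nonempty and equal-length")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.digitize(P, edges, right=True) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=A, minlength=n_bins)
    occupied = counts > 0
    if not occupied.all():
        warnings.warn(
            f"{int((~occupied).sum())} of {n_bins} phase bins are empty; "
            "the distribution is normalized over occupied bins only",
            stacklevel=2,
        )
    means = np.zeros(n_bins)
    means[occupied] = sums[occupied] / counts[occupied]
    total = means[occupied].sum()
    if total <= 0:
        raise ValueError("mean amplitude is zero in every occupied bin")
    probs = np.zeros(n_bins)
    probs[occupied] = means[occupied] / total
    return PhaseBinDistribution(probs, edges, occupied)


def modulation_index(A, P, n_bins: int = 18) -> float:
    """Kullback-Leibler modulation index in [0, 1].

    ``MI = (log M - H(P)) / log M`` where ``H`` is the Shannon entropy of
    the phase-binned distribution and ``M`` the number of occupied bins
    (``M = n_bins`` when every bin receives samples).  Zero for a uniform
    distribution, one when all amplitude mass sits in a single bin.
    """
    dist = phase_bin_distribution(A, P, n_bins=n_bins)
    m = dist.n_occupied
    if m < 2:
        raise ValueError("modulation index needs at least two occupied phase bins")
    p = dist.probs[dist.occupied]
    h = -float(np.sum(np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)))
    return (np.log(m) - h) / np.log(m)


def glm_index(A, P) -> GLMFit:
    """Least-squares fit of ``A`` on ``[cos P, sin P, 1]``; index is R^2."""
    A, P = _as_array(A), _as_array(P)
    if A.shape != P.shape or A.size < 3:
        raise ValueError("need equal-length series with at least 3 samples")
    design = np.column_stack([np.cos(P), np.sin(P), np.ones_like(P)])
    w, _, _, _ = np.linalg.lstsq(design, A, rcond=None)
    resid = A - design @ w
    tss = float(np.sum((A - A.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero-variance amplitude: R^2 undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / tss
    return GLMFit(w, float(np.clip(r2, 0.0, 1.0)))


def _mi_value(A, P) -> float:
    return modulation_index(A, P)


def _glm_value(A, P) -> float:
    return glm_index(A, P).r2


#: Baseline estimators sharing the (envelope, phase) -> value interface.
BASELINE_METHODS = {
    "mvl": mvl,
    "plv": plv,
    "mi": _mi_value,
    "glm": _glm_value,
}
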