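"""Linear parameter varying autoregressive (LPV-AR) coupling estimator.

The high-band envelope ``y`` is modelled as an AR(p) process whose lag
coefficients are modulated by a scheduling signal ``s = [cos P_L, sin P_L]``
built from the low-band instantaneous phase:

    y(n) = sum_k a_k(s_n) y(n-k) + eps(n),
    a_k(s_n) = theta_k0 + sum_{i+j=q} theta_kij s1_n^i s2_n^j

Only the q-th order monomials are retained alongside the constant, so each
lag contributes ``q + 2`` coefficients (``1`` for q = 0, i.e. a plain AR
model).  The model is linear in the parameters and fitted by ridge
regression.  Coupling strength is the absolute log-ratio of residual
energies between the intact model and the same coefficients applied to a
regressor matrix rebuilt from a time-permuted scheduling signal: if the
phase truly modulates the envelope, scrambling the phase degrades the
prediction and the ratio moves away from one.

Structure selection is two-step: (1) a grid search over (p, q) at a fixed
regularization picks the orders by in-sample MSE; (2) with the orders
fixed, the ridge parameter is chosen on a log-spaced grid by the U-curve
criterion ``U(lam) = 1/||w|| + 1/||e||``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .preprocess import PhaseSeries

__all__ = [
    "SchedulingSignal",
    "LPVARStructure",
    "RegressorMatrix",
    "LPVARModel",
    "ResidualPair",
    "OrderSelectionResult",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_P_GRID",
    "DEFAULT_Q_GRID",
    "build_scheduling",
    "basis_row",
    "basis_matrix",
    "build_regressor_matrix",
    "fit_rls",
    "predict_residuals",
    "permuted_regressors",
    "cfc_index",
    "select_order_step1",
    "select_lambda_ucurve",
    "lpvar_cfc",
]

#: Ridge parameter grid for the U-curve search.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 1e2, 1e3)
#: Default lag-order grid for step-1 structure selection.
DEFAULT_P_GRID: tuple[int, ...] = tuple(range(1, 16))
#: Default polynomial-order grid for step-1 structure selection.
DEFAULT_Q_GRID: tuple[int, ...] = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class SchedulingSignal:
    """Cosine and sine of the low-band instantaneous phase, per sample."""

    s1: np.ndarray
    s2: np.ndarray

    def __post_init__(self) -> None:
        s1 = np.asarray(self.s1, dtype=float)
        s2 = np.asarray(self.s2, dtype=float)
        if s1.shape != s2.shape or s1.ndim != 1:
            raise ValueError("s1 and s2 must be equal-length 1-D arrays")
        object.__setattr__(self, "s1", s1)
        object.__setattr__(self, "s2", s2)

    def __len__(self) -> int:
        return self.s1.size

    def take(self, order: np.ndarray) -> "SchedulingSignal":
        """Reindex both components jointly (pairs kept intact)."""
        return SchedulingSignal(self.s1[order], self.s2[order])


@dataclass(frozen=True)
class LPVARStructure:
    """Model structure: lag order ``p``, polynomial order ``q``, ridge ``lam``."""

    p: int
    q: int
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

    @property
    def n_basis(self) -> int:
        """Coefficients per lag: 1 for q = 0, else q + 2."""
        return 1 if self.q == 0 else self.q + 2

    @property
    def n_coefficients(self) -> int:
        return self.p * self.n_basis


@dataclass(frozen=True)
class RegressorMatrix:
    """Extended regressor rows and the aligned target vector.

    Rows exist for samples ``n = p .. N-1`` (0-based); no zero-padding of
    pre-sample history is fabricated, so ``n_effective = N - p``.  Column
    ordering is lag-major: for each lag ``k = 1..p``, the lagged sample
    ``y(n-k)`` multiplied by each basis value at sample ``n``.
    """

    X: np.ndarray
    target: np.ndarray
    structure: LPVARStructure

    @property
    def n_effective(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class LPVARModel:
    w: np.ndarray
    structure: LPVARStructure


@dataclass(frozen=True)
class ResidualPair:
    """Residuals of the intact model and under permuted scheduling."""

    e: np.ndarray
    e0: np.ndarray
    yhat: np.ndarray
    yhat0: np.ndarray


@dataclass(frozen=True)
class OrderSelectionResult:
    p_star: int
    q_star: int
    lam_star: float
    mse_grid: dict = field(repr=False)
    ucurve: dict = field(repr=False)


def build_scheduling(P: PhaseSeries | np.ndarray) -> SchedulingSignal:
    """Scheduling signal ``s = [cos(P), sin(P)]`` from an instantaneous phase."""
    values = P.values if isinstance(P, PhaseSeries) else np.asarray(P, dtype=float)
    return SchedulingSignal(np.cos(values), np.sin(values))


def basis_row(s1n: float, s2n: float, q: int) -> np.ndarray:
    """Polynomial basis at one sample: ``[1] + [s1^i s2^(q-i) for i = 0..q]``.

    For q = 0 the basis collapses to ``[1]`` (constant-coefficient AR).
    Note that for even q the monomials are linearly dependent with the
    constant (e.g. ``s1^2 + s2^2 = 1``), which is why the fit is
    regularized.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    if q == 0:
        return np.array([1.0])
    row = np.empty(q + 2)
    row[0] = 1.0
    for i in range(q + 1):
        row[1 + i] = s1n**i * s2n ** (q - i)
    return row


def basis_matrix(s: SchedulingSignal, q: int) -> np.ndarray:
    """Vectorized :func:`basis_row` over all samples, shape ``(N, n_basis)``."""
    n = len(s)
    if q == 0:
        return np.ones((n, 1))
    B = np.empty((n, q + 2))
    B[:, 0] = 1.0
    for i in range(q + 1):
        B[:, 1 + i] = s.s1**i * s.s2 ** (q - i)
    return B


def build_regressor_matrix(
    y: np.ndarray, s: SchedulingSignal, structure: LPVARStructure
) -> RegressorMatrix:
    """Assemble the extended regressor matrix and aligned target.

    Each row ``n`` concatenates, for lag ``k = 1..p``, the product of
    ``y(n-k)`` with every basis value evaluated at sample ``n``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    p = structure.p
    if n <= p:
        raise ValueError(f"signal of {n} samples is too short for lag order p={p}")
    if len(s) != n:
        raise ValueError("scheduling signal length must match the target length")
    B = basis_matrix(s, structure.q)[p:]
    blocks = [y[p - k : n - k, None] * B for k in range(1, p + 1)]
    return RegressorMatrix(np.hstack(blocks), y[p:], structure)


def fit_rls(Phi: RegressorMatrix, lam: float | None = None) -> LPVARModel:
    """Ridge (regularized least squares) coefficient estimate.

    Solves ``(X'X + lam I) w = X'y``.  With ``lam = 0`` this is the plain
    LS solution and raises if the regressor matrix is rank deficient.
    """
    if lam is None:
        lam = Phi.structure.lam
    if lam < 0:
        raise ValueError("lam must be >= 0")
    X, y = Phi.X, Phi.target
    G = X.T @ X
    if lam > 0:
        G = G + lam * np.eye(G.shape[0])
    try:
        w = linalg.solve(G, X.T @ y, assume_a="pos")
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "normal equations are singular; use lam > 0 for a rank-deficient basis"
        ) from err
    structure = LPVARStructure(Phi.structure.p, Phi.structure.q, lam)
    return LPVARModel(w, structure)


def predict_residuals(model: LPVARModel, Phi: RegressorMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Fitted values and residuals ``e = y - X w`` on a regressor matrix."""
    if Phi.X.shape[1] != model.w.size:
        raise ValueError("model and regressor matrix dimensions disagree")
    yhat = Phi.X @ model.w
    return yhat, Phi.target - yhat


def permuted_regressors(
    y: np.ndarray,
    s: SchedulingSignal,
    structure: LPVARStructure,
    rng: np.random.Generator | None = None,
    permutation: np.ndarray | None = None,
) -> RegressorMatrix:
    """Regressor matrix rebuilt from a time-permuted scheduling signal.

    One random permutation of the time order of ``s`` is drawn and applied
    jointly to both components (cos/sin pairs stay intact, preserving the
    unit-circle identity), then the matrix is rebuilt.  An explicit
    ``permutation`` overrides the random draw (identity reproduces the
    intact matrix).
    """
    if permutation is None:
        if rng is None:
            rng = np.random.default_rng()
        permutation = rng.permutation(len(s))
    return build_regressor_matrix(np.asarray(y, dtype=float), s.take(permutation), structure)


def cfc_index(e: np.ndarray, e0: np.ndarray) -> float:
    """Coupling index ``|log(e'e / e0'e0)|`` from a residual pair."""
    num = float(np.dot(e, e))
    den = float(np.dot(e0, e0))
    if den <= 0:
        raise ValueError("permuted-model residual energy must be positive")
    return abs(float(np.log(num / den)))


def select_order_step1(
    y: np.ndarray,
    s: SchedulingSignal,
    p_grid: tuple[int, ...] = DEFAULT_P_GRID,
    q_grid: tuple[int, ...] = DEFAULT_Q_GRID,
    lam_init: float = 10.0,
) -> tuple[int, int, dict]:
    """Step 1 of structure selection: (p, q) by in-sample MSE.

    Fits every (p, q) pair at a fixed (relatively large) ridge parameter
    and computes the in-sample mean squared residual over the retained
    rows.  Ties break toward smaller q, then smaller p.
    """
    if not p_grid or not q_grid:
        raise ValueError("order grids must be nonempty")
    mse_grid: dict[tuple[int, int], float] = {}
    best: tuple[int, int] | None = None
    best_mse = np.inf
    for q in sorted(q_grid):
        for p in sorted(p_grid):
            Phi = build_regressor_matrix(y, s, LPVARStructure(p, q, lam_init))
            model = fit_rls(Phi)
            _, e = predict_residuals(model, Phi)
            mse = float(np.mean(e**2))
            mse_grid[(p, q)] = mse
            if mse < best_mse:
                best_mse = mse
                best = (p, q)
    assert best is not None
    return best[0], best[1], mse_grid


def select_lambda_ucurve(
    Phi: RegressorMatrix,
    lam_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
) -> tuple[float, dict]:
    """Step 2: ridge parameter by the U-curve criterion.

    ``U(lam) = 1/||w_RLS(lam)|| + 1/||e(lam)||`` over the grid; the grid
    argmin balances solution size against data fit.  Ties break toward the
    smaller lam.
    """
    if any(l <= 0 for l in lam_grid):
        raise ValueError("U-curve grid requires strictly positive lam values")
    X, y = Phi.X, Phi.target
    G = X.T @ X
    c = X.T @ y
    eye = np.eye(G.shape[0])
    ucurve: dict[float, float] = {}
    best_lam, best_u = None, np.inf
    for lam in sorted(lam_grid):
        w = linalg.solve(G + lam * eye, c, assume_a="pos")
        wn = np.linalg.norm(w)
        en = np.linalg.norm(y - X @ w)
        if wn == 0 or en == 0:
            raise ValueError("degenerate input: zero solution or residual norm on the grid")
        u = 1.0 / wn + 1.0 / en
        ucurve[lam] = u
        if u < best_u:
            best_u = u
            best_lam = lam
    assert best_lam is not None
    return best_lam, ucurve


def select_structure(
    y: np.ndarray,
    s: SchedulingSignal,
    p_grid: tuple[int, ...] = DEFAULT_P_GRID,
    q_grid: tuple[int, ...] = DEFAULT_Q_GRID,
    lam_init: float = 10.0,
    lam_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
) -> OrderSelectionResult:
    """Full two-step structure selection."""
    p_star, q_star, mse_grid = select_order_step1(y, s, p_grid, q_grid, lam_init)
    Phi = build_regressor_matrix(y, s, LPVARStructure(p_star, q_star))
    lam_star, ucurve = select_lambda_ucurve(Phi, lam_grid)
    return OrderSelectionResult(p_star, q_star, lam_star, mse_grid, ucurve)


def lpvar_cfc(
    y: np.ndarray,
    s: SchedulingSignal,
    structure: LPVARStructure | None = None,
    p_grid: tuple[int, ...] = DEFAULT_P_GRID,
    q_grid: tuple[int, ...] = DEFAULT_Q_GRID,
    lam_init: float = 10.0,
    lam_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    n_permutations: int = 1,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, LPVARModel, OrderSelectionResult | None]:
    """LPV-AR coupling index on a prepared (envelope, scheduling) pair.

    Runs structure selection (unless a fixed ``structure`` is supplied),
    fits the ridge solution, and compares residual energies against
    ``n_permutations`` permuted rebuilds of the regressor matrix.  With
    more than one permutation the permuted residual energy is averaged
    before taking the log-ratio, reducing index variance.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    selection: OrderSelectionResult | None = None
    if structure is None:
        selection = select_structure(y, s, p_grid, q_grid, lam_init, lam_grid)
        structure = LPVARStructure(selection.p_star, selection.q_star, selection.lam_star)
    Phi = build_regressor_matrix(y, s, structure)
    model = fit_rls(Phi)
    _, e = predict_residuals(model, Phi)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    e0_energy = 0.0
    for _ in range(n_permutations):
        Phi0 = permuted_regressors(y, s, structure, rng=rng)
        _, e0 = predict_residuals(model, Phi0)
        e0_energy += float(np.dot(e0, e0))
    e0_energy /= n_permutations
    if e0_energy <= 0:
        raise ValueError("permuted-model residual energy must be positive")
    value = abs(float(np.log(float(np.dot(e, e)) / e0_energy)))
    return value, model, selection
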