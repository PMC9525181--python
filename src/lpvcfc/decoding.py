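"""Trial-wise CFC features and movement-attempt style decoding.

Features are coupling indices over (phase band, amplitude band) pairs of
the six canonical EEG bands, one per region of interest (ROI).  The
decoder is a multiclass shrinkage LDA with permutation-importance
backward elimination, validated by a nested scheme: an internal
(stratified five-fold) CV drives feature selection, an external 10%
hold-out repeated with resampling measures generalization, and an
optional label-permutation control on the identical splits estimates the
chance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .cfc import CFCOptions, estimate_cfc
from .core import NAMED_BANDS, BandSpec, TimeSeries
from .preprocess import bandpass_twoway, dominant_subband

__all__ = [
    "ROISpec",
    "FeatureMatrix",
    "EliminationTrace",
    "NestedCVReport",
    "BAND_PAIRS",
    "SCI_MONTAGE_ROIS",
    "extract_trial_features",
    "extract_feature_matrix",
    "fit_shrinkage_lda",
    "permutation_importance",
    "backward_elimination",
    "nested_cv",
]

#: The 15 (phase band, amplitude band) pairs of the six canonical bands,
#: ordered by ascending phase band: D pairs first, then T, A, B, G.
BAND_PAIRS: tuple[tuple[str, str], ...] = (
    ("delta", "theta"),
    ("delta", "alpha"),
    ("delta", "beta"),
    ("delta", "gamma"),
    ("delta", "high_gamma"),
    ("theta", "alpha"),
    ("theta", "beta"),
    ("theta", "gamma"),
    ("theta", "high_gamma"),
    ("alpha", "beta"),
    ("alpha", "gamma"),
    ("alpha", "high_gamma"),
    ("beta", "gamma"),
    ("beta", "high_gamma"),
    ("gamma", "high_gamma"),
)


@dataclass(frozen=True)
class ROISpec:
    """A named region of interest: the average over a set of channels."""

    name: str
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.channel_names:
            raise ValueError("ROI needs at least one channel")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channels within an ROI")
        object.__setattr__(self, "channel_names", tuple(self.channel_names))


#: Nine-ROI grouping of a 61-channel motor montage (frontal, central,
#: parietal; midline/left/right).
SCI_MONTAGE_ROIS: tuple[ROISpec, ...] = (
    ROISpec("FZ", ("FCz", "Fz")),
    ROISpec("FL", ("F3", "F1", "FFC5h", "FFC3h", "FFC1h", "FC5", "FC3", "FC1",
                   "FCC5h", "FCC3h", "FCC1h")),
    ROISpec("FR", ("F2", "F4", "FFC2h", "FFC4h", "FFC6h", "FC2", "FC4", "FC6",
                   "FCC2h", "FCC4h", "FCC6h")),
    ROISpec("CZ", ("Cz", "CPz")),
    ROISpec("CL", ("C5", "C3", "C1", "CCP5h", "CCP3h", "CCP1h", "CP5", "CP3",
                   "CP1", "CPP5h", "CPP3h", "CPP1h")),
    ROISpec("CR", ("C2", "C4", "C6", "CCP2h", "CCP4h", "CCP6h", "CP2", "CP4",
                   "CP6", "CPP2h", "CPP4h", "CPP6h")),
    ROISpec("PZ", ("Pz", "POz")),
    ROISpec("PL", ("P5", "P3", "P1", "PPO1h")),
    ROISpec("PR", ("P2", "P4", "P6", "PPO2h")),
)


@dataclass(frozen=True)
class FeatureMatrix:
    """Trials x features table with class labels."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        if values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match the feature axis")
        if labels.shape != (values.shape[0],):
            raise ValueError("one label per trial required")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _roi_average(trial: TimeSeries, roi: ROISpec) -> TimeSeries:
    if trial.values.ndim == 1:
        return trial
    if trial.channel_names is None:
        raise ValueError("multi-channel trials need channel names to resolve ROIs")
    missing = [c for c in roi.channel_names if c not in trial.channel_names]
    if missing:
        raise ValueError(f"trial is missing ROI channels: {missing}")
    idx = [trial.channel_names.index(c) for c in roi.channel_names]
    return TimeSeries(trial.values[idx].mean(axis=0), trial.fs)


def extract_trial_features(
    trial: TimeSeries,
    band_pairs: tuple[tuple[str, str], ...] = BAND_PAIRS,
    rois: tuple[ROISpec, ...] | None = None,
    method: str = "lpvar",
    options: CFCOptions | None = None,
    bands: dict[str, BandSpec] | None = None,
    subband_step: float = 0.5,
    subband_width: float = 1.0,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """One coupling feature per (band pair, ROI) for a single trial.

    Channels of each ROI are averaged (filtering is linear, so averaging
    first is identical to filtering each channel and averaging after).
    The phase driver for each pair is not the whole low band but its
    dominant sub-band — the 1 Hz window with the highest power — which
    anchors the phase estimate to the spectral peak of the slow rhythm.

    Features are ordered pair-major, ROI-minor, named ``"<L>-<H>@<ROI>"``
    with the band's short code (e.g. ``"T-A@FZ"``).
    """
    if bands is None:
        bands = NAMED_BANDS
    if options is None:
        options = CFCOptions(cap_order=True)
    if rois is None:
        rois = (ROISpec("all", trial.channel_names or ("ch0",)),) if trial.values.ndim == 2 else (
            ROISpec("signal", ("signal",)),
        )
    roi_signals = {}
    for roi in rois:
        roi_signals[roi.name] = trial if trial.values.ndim == 1 else _roi_average(trial, roi)
    values: list[float] = []
    names: list[str] = []
    for low_name, high_name in band_pairs:
        low, high = bands[low_name], bands[high_name]
        code = f"{low.label or low_name}-{high.label or high_name}"
        for roi in rois:
            sig = roi_signals[roi.name]
            driver = dominant_subband(
                sig, low, step=subband_step, width=subband_width, cap_order=options.cap_order
            )
            values.append(estimate_cfc(sig, driver, high, method=method, options=options))
            names.append(f"{code}@{roi.name}")
    return np.asarray(values), tuple(names)


def extract_feature_matrix(
    trials,
    band_pairs: tuple[tuple[str, str], ...] = BAND_PAIRS,
    rois: tuple[ROISpec, ...] | None = None,
    method: str = "lpvar",
    options: CFCOptions | None = None,
) -> FeatureMatrix:
    """Feature matrix over a :class:`~lpvcfc.simulate.LabeledTrials` batch."""
    rows = []
    names: tuple[str, ...] = ()
    for i in range(trials.n_trials):
        vec, names = extract_trial_features(
            trials.trial(i), band_pairs=band_pairs, rois=rois, method=method, options=options
        )
        rows.append(vec)
    return FeatureMatrix(np.vstack(rows), names, trials.labels)


def fit_shrinkage_lda(
    X: np.ndarray, y: np.ndarray, shrinkage: float | str = "auto"
) -> LinearDiscriminantAnalysis:
    """Multiclass LDA with the pooled covariance shrunk toward identity.

    The shrinkage intensity is chosen analytically (Ledoit-Wolf) by
    default; pass a float in [0, 1] to force it (1 reduces the decision
    rule to nearest class mean under a scaled identity covariance).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least two training trials")
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    clf.fit(X, y)
    return clf


def permutation_importance(
    clf,
    X: np.ndarray,
    y: np.ndarray,
    feature_index: int,
    n_shuffles: int = 10,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean accuracy drop when one feature column is shuffled on test data.

    An uninformative feature leaves the accuracy unchanged (importance
    near zero, possibly slightly negative); an informative one degrades it.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    baseline = float(np.mean(clf.predict(X) == y))
    drops = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = X.copy()
        shuffled[:, feature_index] = rng.permutation(shuffled[:, feature_index])
        drops[k] = baseline - float(np.mean(clf.predict(shuffled) == y))
    return float(drops.mean())


@dataclass(frozen=True)
class EliminationStep:
    removed: int
    surviving: tuple[int, ...]
    accuracy: float


@dataclass(frozen=True)
class EliminationTrace:
    """Backward-elimination record: one removal per step until empty.

    ``optimal_n`` is the surviving-set size at the internal-CV accuracy
    maximum (ties toward fewer features).
    """

    steps: tuple[EliminationStep, ...]
    optimal_n: int

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([s.accuracy for s in self.steps])

    def surviving_at(self, n_features: int) -> tuple[int, ...]:
        for step in self.steps:
            if len(step.surviving) == n_features:
                return step.surviving
        raise KeyError(f"no step with {n_features} surviving features")

    @property
    def optimal_features(self) -> tuple[int, ...]:
        return self.surviving_at(self.optimal_n)


def backward_elimination(
    X: np.ndarray,
    y: np.ndarray,
    inner_folds: int = 5,
    n_shuffles: int = 10,
    seed: int | None = None,
    shrinkage: float | str = "auto",
) -> EliminationTrace:
    """Permutation-importance backward elimination with internal CV.

    At each step, classifiers are trained on the stratified folds; each
    surviving feature's importance is the fold-averaged accuracy drop
    under test-set shuffling; the least important feature is removed and
    the step's mean CV accuracy recorded.  Repeats until no features are
    left.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    surviving = list(range(X.shape[1]))
    steps: list[EliminationStep] = []
    while surviving:
        skf = StratifiedKFold(
            n_splits=inner_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        fold_acc = []
        fold_imp = np.zeros((inner_folds, len(surviving)))
        for f, (tr, te) in enumerate(skf.split(X, y)):
            clf = fit_shrinkage_lda(X[np.ix_(tr, surviving)], y[tr], shrinkage=shrinkage)
            X_te = X[np.ix_(te, surviving)]
            fold_acc.append(float(np.mean(clf.predict(X_te) == y[te])))
            for k in range(len(surviving)):
                fold_imp[f, k] = permutation_importance(
                    clf, X_te, y[te], k, n_shuffles=n_shuffles, rng=rng
                )
        importance = fold_imp.mean(axis=0)
        worst = int(np.argmin(importance))
        steps.append(
            EliminationStep(surviving[worst], tuple(surviving), float(np.mean(fold_acc)))
        )
        surviving.pop(worst)
    accs = np.array([s.accuracy for s in steps])
    sizes = np.array([len(s.surviving) for s in steps])
    best = accs.max()
    optimal_n = int(sizes[accs >= best - 1e-12].min())
    return EliminationTrace(tuple(steps), optimal_n)


@dataclass(frozen=True)
class NestedCVReport:
    """Accuracies from the repeated internal/external CV scheme.

    ``external_by_count[r, k]`` is the hold-out accuracy of repeat ``r``
    retrained on the surviving set of size ``feature_counts[k]``;
    ``external_at_optimal[r]`` uses each repeat's internally selected
    feature count.
    """

    feature_counts: np.ndarray
    internal_by_count: np.ndarray
    external_by_count: np.ndarray
    optimal_n: np.ndarray
    external_at_optimal: np.ndarray
    permuted: bool = False
    holdout_indices: tuple[tuple[int, ...], ...] = field(default=(), repr=False)

    @property
    def mean_external_at_optimal(self) -> float:
        return float(self.external_at_optimal.mean())

    def summary(self) -> dict:
        return {
            "permuted": self.permuted,
            "n_repeats": int(self.external_at_optimal.size),
            "mean_external_at_optimal": self.mean_external_at_optimal,
            "sd_external_at_optimal": float(self.external_at_optimal.std(ddof=1))
            if self.external_at_optimal.size > 1
            else 0.0,
            "mean_internal_by_count": self.internal_by_count.mean(axis=0).tolist(),
            "mean_external_by_count": self.external_by_count.mean(axis=0).tolist(),
            "feature_counts": self.feature_counts.tolist(),
            "median_optimal_n": float(np.median(self.optimal_n)),
        }


def nested_cv(
    features: FeatureMatrix,
    n_repeats: int = 50,
    holdout_fraction: float = 0.10,
    inner_folds: int = 5,
    n_shuffles: int = 10,
    permute_labels: bool = False,
    seed: int | None = None,
    shrinkage: float | str = "auto",
) -> NestedCVReport:
    """Repeated nested cross-validation of the full selection pipeline.

    Per repeat: hold out a stratified ``holdout_fraction`` of trials, run
    backward elimination with internal CV on the remainder, then for every
    surviving-set size retrain on all internal data and score the
    hold-out.  With ``permute_labels=True`` the labels are shuffled once
    per repeat while the splits stay tied to the true labels, giving a
    chance-level control on identical partitions.
    """
    X, y = features.values, features.labels
    master = np.random.SeedSequence(seed if seed is not None else 0)
    repeat_seqs = master.spawn(n_repeats)
    n_feat = X.shape[1]
    counts = np.arange(n_feat, 0, -1)
    internal = np.empty((n_repeats, n_feat))
    external = np.empty((n_repeats, n_feat))
    optimal_n = np.empty(n_repeats, dtype=int)
    ext_opt = np.empty(n_repeats)
    holdouts = []
    for r in range(n_repeats):
        rng = np.random.default_rng(repeat_seqs[r])
        split_seed = int(rng.integers(2**31 - 1))
        sss = StratifiedShuffleSplit(
            n_splits=1, test_size=holdout_fraction, random_state=split_seed
        )
        train_idx, test_idx = next(sss.split(X, y))
        labels = y
        if permute_labels:
            labels = rng.permutation(y)
        trace = backward_elimination(
            X[train_idx],
            labels[train_idx],
            inner_folds=inner_folds,
            n_shuffles=n_shuffles,
            seed=int(rng.integers(2**31 - 1)),
            shrinkage=shrinkage,
        )
        holdouts.append(tuple(int(i) for i in test_idx))
        for k, step in enumerate(trace.steps):
            cols = list(step.surviving)
            clf = fit_shrinkage_lda(X[np.ix_(train_idx, cols)], labels[train_idx], shrinkage)
            acc = float(np.mean(clf.predict(X[np.ix_(test_idx, cols)]) == labels[test_idx]))
            internal[r, k] = step.accuracy
            external[r, k] = acc
        optimal_n[r] = trace.optimal_n
        ext_opt[r] = external[r, n_feat - trace.optimal_n]
    return NestedCVReport(
        counts, internal, external, optimal_n, ext_opt, permute_labels, tuple(holdouts)
    )
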