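"""Motor-imagery classification pipeline.

Band-pass to the sensorimotor 8-30 Hz range, common-spatial-pattern (CSP)
decomposition into discriminative sources, per-source scalar features (total
power or Higuchi fractal dimension), linear discriminant classification, and
balanced accuracy as the figure of merit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import (
    ClassMissing,
    DegenerateInput,
    EmptyCondition,
    NyquistViolation,
    ShapeMismatch,
    SingularCovariance,
)

__all__ = [
    "EpochSet",
    "CSPModel",
    "FeatureMatrix",
    "bandpass",
    "n_csp",
    "fit_csp",
    "apply_csp",
    "total_power",
    "higuchi_fd",
    "extract_features",
    "train_classifier",
    "predict",
    "balanced_accuracy",
]


@dataclass
class EpochSet:
    """Labeled multichannel (or source-level) epochs.

    ``data`` has shape (epochs, channels, samples); ``labels`` holds one
    condition id per epoch.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    subject_id: str = ""
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ShapeMismatch("data must be (epochs, channels, samples)")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ShapeMismatch("one label per epoch required")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def conditions(self) -> np.ndarray:
        return np.unique(self.labels)

    def select(self, idx) -> "EpochSet":
        return replace(self, data=self.data[idx], labels=self.labels[idx])

    def per_condition(self) -> dict:
        return {c: self.data[self.labels == c] for c in self.conditions}


@dataclass
class CSPModel:
    """Spatial filters (sources = filters @ channels) and their patterns."""

    filters: np.ndarray    # (n_csp, n_channels)
    patterns: np.ndarray   # (n_channels, n_csp)
    n_csp: int
    class_order: list
    eigenvalues: np.ndarray | None = None


@dataclass
class FeatureMatrix:
    values: np.ndarray      # (epochs, n_features)
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2 or self.values.shape[0] != self.labels.shape[0]:
            raise ShapeMismatch("values must be (epochs, features) with matching labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite")

    def concat(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if self.feature_names != other.feature_names:
            raise ShapeMismatch("feature columns differ")
        return FeatureMatrix(
            np.vstack([self.values, other.values]),
            np.concatenate([self.labels, other.labels]),
            list(self.feature_names),
        )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def bandpass(e: EpochSet, f_lo: float = 8.0, f_hi: float = 30.0,
             order: int = 4) -> EpochSet:
    """Zero-phase IIR band-pass per channel per epoch; removes DC."""
    if f_hi >= e.fs / 2.0:
        raise NyquistViolation(f"f_hi={f_hi} >= Nyquist {e.fs / 2.0}")
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=e.fs, output="sos")
    data = sps.sosfiltfilt(sos, e.data - e.data.mean(axis=-1, keepdims=True),
                           axis=-1)
    return replace(e, data=data)


# ---------------------------------------------------------------------------
# common spatial patterns
# ---------------------------------------------------------------------------

def n_csp(n_conditions: int) -> int:
    """Number of retained CSP sources: 2 * ceil(1 + n_conditions / 2)."""
    if n_conditions < 2:
        raise ValueError("need at least two conditions")
    return 2 * int(np.ceil(1 + n_conditions / 2.0))


def _class_covariance(epochs: np.ndarray) -> np.ndarray:
    """Trace-normalized per-epoch covariances averaged over epochs."""
    covs = []
    for ep in epochs:
        c = ep @ ep.T / ep.shape[1]
        tr = np.trace(c)
        if tr <= 0:
            continue
        covs.append(c / tr)
    if not covs:
        raise SingularCovariance("all epochs have zero power")
    return np.mean(covs, axis=0)


def fit_csp(e: EpochSet) -> CSPModel:
    """Fit two-class CSP filters on (band-passed) training epochs.

    Filters are generalized eigenvectors of the class covariance pair; the
    retained set takes the components most discriminative for either class
    (largest and smallest generalized eigenvalues in equal number).  Patterns
    are the pseudo-inverse of the filter matrix.
    """
    conds = list(e.conditions)
    if len(conds) != 2:
        raise ClassMissing(f"two-class CSP requires 2 conditions, got {len(conds)}")
    by = e.per_condition()
    if min(arr.shape[0] for arr in by.values()) < 2:
        raise ClassMissing("need at least 2 epochs per condition")
    c_a = _class_covariance(by[conds[0]])
    c_b = _class_covariance(by[conds[1]])
    comp = c_a + c_b
    comp = comp + 1e-10 * np.trace(comp) / comp.shape[0] * np.eye(comp.shape[0])
    try:
        evals, evecs = sla.eigh(c_a, comp)
    except sla.LinAlgError as exc:  # pragma: no cover - pathological inputs
        raise SingularCovariance(str(exc)) from exc
    m = n_csp(2)
    half = m // 2
    # eigh returns ascending eigenvalues: last `half` favour class A,
    # first `half` favour class B.
    sel = np.r_[np.argsort(evals)[::-1][:half], np.argsort(evals)[:half]]
    filters = evecs[:, sel].T
    patterns = np.linalg.pinv(filters)
    if np.all(np.abs(evals - 0.5) < 1e-3):
        warnings.warn("CSP eigenvalues all ~0.5: classes indistinguishable",
                      DegenerateInput)
    return CSPModel(filters=filters, patterns=patterns, n_csp=m,
                    class_order=conds, eigenvalues=evals[sel])


def apply_csp(m: CSPModel, e: EpochSet) -> EpochSet:
    """Project channel epochs onto CSP source space."""
    if e.n_channels != m.filters.shape[1]:
        raise ShapeMismatch(
            f"model expects {m.filters.shape[1]} channels, got {e.n_channels}")
    data = np.einsum("sc,ecn->esn", m.filters, e.data)
    names = [f"csp{i}" for i in range(m.n_csp)]
    return replace(e, data=data, channel_names=names)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def total_power(x: np.ndarray) -> float:
    """Mean squared amplitude of a signal.

    Under the unitary transform convention the identical value is the mean
    squared magnitude of the Fourier coefficients (Parseval), which is how the
    spectral route evaluates it.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return float(np.mean(x ** 2))


def total_power_spectral(x: np.ndarray) -> float:
    """Frequency-domain evaluation of :func:`total_power` (unitary FFT)."""
    xhat = np.fft.fft(np.asarray(x, dtype=float), norm="ortho")
    return float(np.mean(np.abs(xhat) ** 2))


def higuchi_fd(x: np.ndarray, n_max: int = 10) -> float:
    """Higuchi fractal dimension of a 1-D series.

    Builds stride-``n`` sub-series for every offset, averages their normalized
    curve lengths L(n), and returns minus the slope of log2 L(n) against
    log2 n over n = 1..n_max.  Smooth curves give 1, white noise about 2.
    A constant input is degenerate (all lengths zero) and returns 1.0 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    if N < 2 * n_max:
        raise ValueError(f"need at least {2 * n_max} samples, got {N}")
    lengths = np.empty(n_max)
    for n in range(1, n_max + 1):
        lm = []
        for m in range(1, n + 1):
            sub = x[m - 1::n]
            p = (N - m) // n
            if p < 1:
                continue
            dist = np.abs(np.diff(sub[: p + 1])).sum()
            lm.append(dist * (N - 1) / (p * n ** 2))
        lengths[n - 1] = np.mean(lm)
    if np.any(lengths <= 0):
        warnings.warn("constant signal: Higuchi length is zero, returning 1.0",
                      DegenerateInput)
        return 1.0
    ns = np.arange(1, n_max + 1)
    slope = np.polyfit(np.log2(ns), np.log2(lengths), 1)[0]
    return float(-slope)


def extract_features(sources: EpochSet, feature: str = "TP",
                     hfd_n_max: int = 10) -> FeatureMatrix:
    """One scalar per CSP source per epoch; columns ordered by source index."""
    feature = feature.upper()
    if feature not in ("TP", "HFD"):
        raise ValueError("feature must be 'TP' or 'HFD'")
    n_ep, n_src, _ = sources.data.shape
    vals = np.empty((n_ep, n_src))
    for i in range(n_ep):
        for j in range(n_src):
            x = sources.data[i, j]
            vals[i, j] = (total_power(x) if feature == "TP"
                          else higuchi_fd(x, hfd_n_max))
    names = [f"csp{j}_{feature}" for j in range(n_src)]
    return FeatureMatrix(vals, sources.labels.copy(), names)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def train_classifier(f: FeatureMatrix) -> LinearDiscriminantAnalysis:
    """Two-class LDA with pooled covariance and a small shrinkage ridge."""
    classes, counts = np.unique(f.labels, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ClassMissing("need >= 2 classes with >= 2 samples each")
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)
    try:
        clf.fit(f.values, f.labels)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise SingularCovariance(str(exc)) from exc
    return clf


def predict(state: LinearDiscriminantAnalysis, f: FeatureMatrix) -> np.ndarray:
    return state.predict(f.values)


def balanced_accuracy(y_true: Sequence, y_pred: Sequence) -> float:
    """Mean per-condition recall (the average of the true-positive rates)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ShapeMismatch("prediction/truth length mismatch")
    accs = []
    for c in np.unique(y_true):
        mask = y_true == c
        if not mask.any():
            raise EmptyCondition(str(c))
        accs.append(np.mean(y_pred[mask] == c))
    return float(np.mean(accs))
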