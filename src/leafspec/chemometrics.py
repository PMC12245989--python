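"""Multivariate analysis of the spectra matrix: PCA and PLS-DA.

PCA is computed by singular value decomposition of the centred (optionally
unit-variance scaled) matrix; component signs are fixed so the
largest-magnitude loading of each component is positive, making scores
reproducible run to run.

PLS-DA regresses the centred/scaled matrix on a 0/1 dummy coding of the CO2
treatment (aCO2 = 0, eCO2 = 1) with NIPALS partial least squares and
classifies by thresholding the continuous prediction at 0.5.  Component
count is tuned by stratified k-fold cross-validation on a stratified 70%
training split only; the untouched 30% test split is scored once, after the
tuned model is refit on the full training split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from .spectra import GRID, SpectrumSet, TREATMENTS

logger = logging.getLogger(__name__)


@dataclass
class SpectraMatrix:
    """Spectra as an (n, 2151) matrix with aligned row metadata."""

    X: np.ndarray
    meta: pd.DataFrame
    wavelengths: np.ndarray = field(default_factory=lambda: GRID.copy())

    @classmethod
    def from_spectrum_set(cls, spectrum_set: SpectrumSet) -> "SpectraMatrix":
        return cls(X=spectrum_set.to_matrix(), meta=spectrum_set.meta_frame())

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("metadata rows must match spectra rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("spectra matrix contains non-finite cells")

    @property
    def labels(self) -> np.ndarray:
        return self.meta["treatment"].to_numpy()


def _drop_zero_variance(X: np.ndarray, wavelengths: np.ndarray):
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropping %d zero-variance wavelength column(s) before scaling "
            "(first: %s nm)", n_dropped, wavelengths[~keep][0],
        )
    return keep


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Fitted principal components of the spectra matrix.

    ``explained_variance_ratio`` covers *all* components (sums to 1);
    ``loadings``/``scores`` keep the first ``n_components`` only.
    """

    loadings: np.ndarray            # (p, k), orthonormal columns
    scores: np.ndarray              # (n, k)
    explained_variance_ratio: np.ndarray  # full spectrum of fractions
    mean: np.ndarray
    scale: np.ndarray               # ones when standardize=False
    n_components: int
    standardized: bool
    wavelengths: np.ndarray
    column_mask: np.ndarray         # kept (non-zero-variance) columns

    def variance_table(self) -> pd.DataFrame:
        k = self.n_components
        r = self.explained_variance_ratio[:k]
        return pd.DataFrame(
            {
                "component": np.arange(1, k + 1),
                "variance_fraction": r,
                "variance_pct": 100 * r,
                "cumulative_pct": 100 * np.cumsum(r),
            }
        )

    def reconstruct(self) -> np.ndarray:
        """Inverse-transform the retained components back to reflectance."""
        Xp = self.scores @ self.loadings.T
        return Xp * self.scale + self.mean


def pca_fit(matrix: SpectraMatrix | np.ndarray, n_components: int = 10,
            standardize: bool = True) -> PCAModel:
    """PCA via SVD of the preprocessed matrix.

    Deterministic up to sign; signs are fixed by making each component's
    largest-magnitude loading positive.
    """
    if isinstance(matrix, SpectraMatrix):
        X, wavelengths = matrix.X, matrix.wavelengths
    else:
        X = np.asarray(matrix, dtype=float)
        wavelengths = np.arange(X.shape[1])
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least two spectra")
    keep = _drop_zero_variance(X, wavelengths) if standardize else np.ones(
        p, dtype=bool)
    Xk = X[:, keep]
    mean = Xk.mean(axis=0)
    scale = Xk.std(axis=0, ddof=1) if standardize else np.ones(keep.sum())
    if n_components > min(n, int(keep.sum())):
        raise ValueError(
            f"n_components={n_components} exceeds min(n, p) = {min(n, int(keep.sum()))}"
        )
    Z = (Xk - mean) / scale
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    ratio = S**2 / np.sum(S**2)
    # sign convention: largest-|loading| entry positive per component
    V = Vt.T
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    k = n_components
    return PCAModel(
        loadings=V[:, :k],
        scores=(U[:, :k] * S[:k]),
        explained_variance_ratio=ratio,
        mean=mean,
        scale=scale,
        n_components=k,
        standardized=standardize,
        wavelengths=wavelengths[keep],
        column_mask=keep,
    )


# ---------------------------------------------------------------------------
# classifier evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionStats:
    """Binary classification summary with eCO2 as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    accuracy_ci: tuple[float, float]   # exact Clopper-Pearson 95% interval
    sensitivity: float
    specificity: float
    no_information_rate: float
    nir_p_value: float                 # one-sided exact binomial, acc > NIR
    mcnemar_p_value: float             # exact binomial on discordant pairs

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "n": self.n,
            "accuracy": self.accuracy,
            "accuracy_ci_low": self.accuracy_ci[0],
            "accuracy_ci_high": self.accuracy_ci[1],
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "no_information_rate": self.no_information_rate,
            "nir_p_value": self.nir_p_value,
            "mcnemar_p_value": self.mcnemar_p_value,
        }


def evaluate(predictions, truth, positive: str = "eCO2") -> ConfusionStats:
    """Confusion-matrix statistics for predicted vs true treatment labels."""
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.size == 0:
        raise ValueError("cannot evaluate an empty prediction vector")
    if pred.shape != true.shape:
        raise ValueError("predictions and truth must have equal length")
    pos_p, pos_t = pred == positive, true == positive
    tp = int(np.sum(pos_p & pos_t))
    tn = int(np.sum(~pos_p & ~pos_t))
    fp = int(np.sum(pos_p & ~pos_t))
    fn = int(np.sum(~pos_p & pos_t))
    n = tp + tn + fp + fn
    correct = tp + tn
    accuracy = correct / n
    ci = stats.binomtest(correct, n).proportion_ci(
        confidence_level=0.95, method="exact")
    sensitivity = tp / (tp + fn) if tp + fn else np.nan
    specificity = tn / (tn + fp) if tn + fp else np.nan
    nir = max(np.mean(pos_t), 1 - np.mean(pos_t))
    nir_p = stats.binomtest(correct, n, p=nir, alternative="greater").pvalue
    discordant = fp + fn
    mcnemar_p = (
        stats.binomtest(fp, discordant, p=0.5).pvalue if discordant else 1.0
    )
    return ConfusionStats(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, accuracy_ci=(ci.low, ci.high),
        sensitivity=sensitivity, specificity=specificity,
        no_information_rate=float(nir), nir_p_value=float(nir_p),
        mcnemar_p_value=float(mcnemar_p),
    )


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

MAX_PLS_COMPONENTS = 60


class PLSDA:
    """PLS discriminant model of CO2 treatment from spectra.

    Statsmodels-style usage::

        model = PLSDA(matrix.X, matrix.labels)
        results = model.fit(n_components=10)
        results.predict(X_new)
    """

    def __init__(self, X: np.ndarray, labels, classes: tuple[str, str] = TREATMENTS,
                 wavelengths: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        if X.shape[0] != labels.shape[0]:
            raise ValueError("X and labels must have equal length")
        present = set(labels.tolist())
        if not set(classes) <= present:
            raise ValueError(
                f"both classes {classes} must be present, got {sorted(present)}"
            )
        self.X = X
        self.labels = labels
        self.classes = classes
        self.y = (labels == classes[1]).astype(float)  # aCO2=0, eCO2=1
        self.wavelengths = (
            wavelengths if wavelengths is not None else np.arange(X.shape[1])
        )

    def fit(self, n_components: int) -> "PLSDAResults":
        if not (1 <= n_components <= MAX_PLS_COMPONENTS):
            raise ValueError(
                f"n_components must be in [1, {MAX_PLS_COMPONENTS}]"
            )
        keep = _drop_zero_variance(self.X, self.wavelengths)
        Xk = self.X[:, keep]
        mean = Xk.mean(axis=0)
        scale = Xk.std(axis=0, ddof=1)
        Z = (Xk - mean) / scale
        n_components = min(n_components, Z.shape[0] - 1, Z.shape[1])
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(Z, self.y)
        return PLSDAResults(
            model=self, _pls=pls, column_mask=keep, mean=mean, scale=scale,
            n_components=n_components,
        )


@dataclass
class PLSDAResults:
    """A fitted PLS-DA model; prediction thresholds the PLS regression
    output at 0.5 (standard dummy-coded PLS-DA)."""

    model: PLSDA
    _pls: PLSRegression
    column_mask: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    n_components: int
    threshold: float = 0.5

    # -- low-level access ------------------------------------------------
    @property
    def x_weights(self) -> np.ndarray:
        """(p_kept, k) NIPALS X-weight vectors."""
        return self._pls.x_weights_

    @property
    def x_scores(self) -> np.ndarray:
        return self._pls.x_scores_

    @property
    def y_loadings(self) -> np.ndarray:
        return self._pls.y_loadings_

    def _preprocess(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X[:, self.column_mask] - self.mean) / self.scale

    def decision_values(self, X: np.ndarray,
                        n_components: int | None = None) -> np.ndarray:
        """Continuous prediction of the 0/1 class code.

        ``n_components`` may truncate the fitted model: NIPALS components
        are nested, so the k-component regression coefficients are
        recoverable from the leading k weight/loading vectors.
        """
        Z = self._preprocess(X)
        if n_components is None or n_components == self.n_components:
            return (self._pls.predict(Z)).ravel()
        k = n_components
        W = self._pls.x_weights_[:, :k]
        P = self._pls.x_loadings_[:, :k]
        Q = self._pls.y_loadings_[:, :k]
        coef = W @ np.linalg.solve(P.T @ W, Q.T)
        # the training matrix was centred in fit(), so the truncated-model
        # intercept is just the training-class-code mean
        return (Z @ coef).ravel() + float(self.model.y.mean())

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        yhat = self.decision_values(X, n_components=n_components)
        classes = self.model.classes
        return np.where(yhat >= self.threshold, classes[1], classes[0])

    def training_accuracy(self) -> float:
        return float(np.mean(self.predict(self.model.X) == self.model.labels))

    def y_variance_explained(self) -> np.ndarray:
        """Fraction of (centred) class-code variance captured per component."""
        y_c = self.model.y - self.model.y.mean()
        T = self._pls.x_scores_
        Q = self._pls.y_loadings_.ravel()
        total = float(y_c @ y_c)
        return np.array(
            [(Q[k] ** 2) * float(T[:, k] @ T[:, k]) / total
             for k in range(self.n_components)]
        )

    def wavelength_importance(self) -> pd.DataFrame:
        """Cumulative wavelength importance over retained components.

        importance(lambda) = sum_k |w_{lambda k}| * v_k, with w the NIPALS
        X-weights and v_k the fraction of class-code variance explained by
        component k; normalised to max = 1.  Wavelengths dropped as
        zero-variance reappear with importance 0.  Raw per-component
        weights are available via ``x_weights`` for alternative
        definitions.
        """
        v = self.y_variance_explained()
        raw = np.abs(self._pls.x_weights_) @ v
        full = np.zeros(self.column_mask.size)
        full[self.column_mask] = raw
        if full.max() > 0:
            full = full / full.max()
        return pd.DataFrame(
            {"wavelength_nm": self.model.wavelengths, "importance": full}
        )


@dataclass
class PLSDATuning:
    """Result of the 70/30 split + stratified-CV component scan."""

    best_n_components: int
    cv_curve: pd.DataFrame           # columns: n_components, cv_accuracy
    results: PLSDAResults            # tuned model refit on the full train split
    test_stats: ConfusionStats       # held-out 30% evaluated once
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int


def tune_plsda(X: np.ndarray, labels, max_components: int = MAX_PLS_COMPONENTS,
               folds: int = 10, train_fraction: float = 0.7,
               seed: int = 0, classes: tuple[str, str] = TREATMENTS,
               wavelengths: np.ndarray | None = None) -> PLSDATuning:
    """Tune the PLS-DA component count and evaluate on a held-out split.

    The data are split stratified by class (``train_fraction`` for
    training); the component scan uses stratified ``folds``-fold CV on the
    training portion only.  The component count with the highest mean CV
    accuracy is selected (ties go to the fewer-component model), refit on
    the whole training split, and scored once on the untouched test split.
    All randomness (split and folds) derives from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    ss = np.random.SeedSequence([int(seed), 7])
    split_seed, fold_seed = (int(s % (2**31)) for s in ss.generate_state(2))
    idx = np.arange(X.shape[0])
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=split_seed
    )
    X_train, y_train = X[train_idx], labels[train_idx]

    _, class_counts = np.unique(y_train, return_counts=True)
    if class_counts.min() < folds:
        raise ValueError(
            f"cannot form {folds} stratified folds: smallest class has "
            f"{class_counts.min()} training samples"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
    max_k = min(max_components, MAX_PLS_COMPONENTS)
    fold_acc = []
    for fit_rows, val_rows in skf.split(X_train, y_train):
        k_cap = min(max_k, len(fit_rows) - 1, X.shape[1])
        fold_model = PLSDA(X_train[fit_rows], y_train[fit_rows], classes=classes,
                           wavelengths=wavelengths).fit(k_cap)
        accs = np.full(max_k, np.nan)
        truth = y_train[val_rows]
        for k in range(1, k_cap + 1):
            pred = fold_model.predict(X_train[val_rows], n_components=k)
            accs[k - 1] = np.mean(pred == truth)
        fold_acc.append(accs)
    curve = np.nanmean(np.vstack(fold_acc), axis=0)
    best = int(np.nanargmax(curve)) + 1  # argmax; ties -> fewest components

    final = PLSDA(X_train, y_train, classes=classes,
                  wavelengths=wavelengths).fit(best)
    # the held-out split is touched only here, after the model is frozen
    test_pred = final.predict(X[test_idx])
    test_stats = evaluate(test_pred, labels[test_idx], positive=classes[1])
    return PLSDATuning(
        best_n_components=best,
        cv_curve=pd.DataFrame(
            {"n_components": np.arange(1, max_k + 1), "cv_accuracy": curve}
        ),
        results=final,
        test_stats=test_stats,
        train_indices=train_idx,
        test_indices=test_idx,
        seed=int(seed),
    )
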