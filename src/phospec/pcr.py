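"""Principal-component regression of growth-medium nutrients on leaf spectra.

The model regresses a (by default log10-transformed) medium concentration on
the leading principal-component scores of the centered training spectra.
Training follows the calibration protocol: the plant-level training matrix is
augmented by bootstrap resampling (6000 draws with replacement by default),
the component count is chosen by 10-fold cross-validation (first minimum of
the pooled mean squared error of prediction, MSEP), and the final model is
refit at that count.

Loadings come from a singular value decomposition of the centered matrix, so
score columns are mutually orthogonal; the per-fold CV exploits this by
fitting all candidate component counts from a single decomposition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GridMismatchError, SpectrumSet

__all__ = [
    "PCRModel",
    "CVResult",
    "BootstrapConfig",
    "RankError",
    "fit_pcr",
    "select_components",
    "bootstrap_train",
    "predict_available",
    "learning_curve",
    "resample_to_grid",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

TRANSFORMS = {
    "identity": (lambda y: y, lambda y: y),
    "log10": (np.log10, lambda y: np.power(10.0, y)),
}


class RankError(np.linalg.LinAlgError):
    """Requested more components than the centered matrix supports."""


def _svd(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD; falls back to the slower gesvd driver when gesdd stalls
    (bootstrap matrices with many duplicated rows occasionally trip it)."""
    try:
        return np.linalg.svd(A, full_matrices=False)
    except np.linalg.LinAlgError:
        from scipy.linalg import svd as scipy_svd

        return scipy_svd(A, full_matrices=False, lapack_driver="gesvd")


@dataclass
class PCRModel:
    mean_spectrum: np.ndarray
    loadings: np.ndarray                  # (n_points, n_components), orthonormal cols
    coefficients: np.ndarray              # (n_components,)
    intercept: float
    n_components: int
    target_transform: str = "identity"
    training_grid: np.ndarray | None = None

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predict on raw spectra rows (original target units)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = (X - self.mean_spectrum) @ self.loadings
        y_t = scores @ self.coefficients + self.intercept
        return TRANSFORMS[self.target_transform][1](y_t)


@dataclass
class CVResult:
    msep_by_components: np.ndarray        # index k-1 -> MSEP with k components
    selected_components: int
    fold_count: int
    seed: int

    @property
    def msep(self) -> float:
        """Pooled MSEP at the selected component count (transformed scale)."""
        return float(self.msep_by_components[self.selected_components - 1])


@dataclass(frozen=True)
class BootstrapConfig:
    n_resamples: int = 6000
    unit: str = "plant"                   # or "spectrum"
    seed: int = 0
    with_replacement: bool = True

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.unit not in ("plant", "spectrum"):
            raise ValueError("bootstrap unit must be 'plant' or 'spectrum'")


def _transform(y: np.ndarray, target_transform: str) -> np.ndarray:
    try:
        fwd = TRANSFORMS[target_transform][0]
    except KeyError:
        raise ValueError(
            f"unknown target_transform {target_transform!r}; choose from {list(TRANSFORMS)}"
        ) from None
    return fwd(np.asarray(y, dtype=float))


def fit_pcr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    target_transform: str = "identity",
    training_grid: np.ndarray | None = None,
) -> PCRModel:
    """Fit a PCR model: center X, project on leading right singular vectors,
    least-squares fit of the transformed target on the scores plus intercept."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_t = _transform(y, target_transform)
    n, p = X.shape
    if y_t.shape != (n,):
        raise ValueError(f"y length {y_t.shape} does not match {n} rows of X")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} must be in [1, min(n-1={n - 1}, p={p})]"
        )
    if np.isnan(X).any():
        raise ValueError("X must be column-complete (no missing values)")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = _svd(Xc)
    tol = s[0] * max(n, p) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if n_components > rank:
        raise RankError(
            f"requested {n_components} components but centered X has rank {rank}"
        )
    loadings = Vt[:n_components].T
    scores = U[:, :n_components] * s[:n_components]
    intercept = float(y_t.mean())
    # scores are orthogonal with zero column means, so the least-squares
    # coefficients decouple per component
    coef = (scores.T @ (y_t - intercept)) / (s[:n_components] ** 2)
    return PCRModel(
        mean_spectrum=mean,
        loadings=loadings,
        coefficients=coef,
        intercept=intercept,
        n_components=n_components,
        target_transform=target_transform,
        training_grid=None if training_grid is None else np.asarray(training_grid),
    )


def _fold_assignment(
    n: int, folds: int, seed: int, groups: Sequence | None
) -> np.ndarray:
    """Seeded shuffle into folds; rows sharing a group label stay together."""
    rng = np.random.default_rng(seed)
    fold_of_row = np.empty(n, dtype=int)
    if groups is None:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, folds)):
            fold_of_row[chunk] = f
    else:
        groups = np.asarray(groups)
        if groups.shape != (n,):
            raise ValueError("groups must have one label per row")
        labels = pd.unique(groups)
        perm = rng.permutation(len(labels))
        fold_of_label = {
            labels[i]: f
            for f, chunk in enumerate(np.array_split(perm, folds))
            for i in chunk
        }
        fold_of_row = np.array([fold_of_label[g] for g in groups])
    return fold_of_row


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    max_components: int = 41,
    seed: int = 0,
    groups: Sequence | None = None,
    target_transform: str = "identity",
) -> CVResult:
    """Choose the PCR component count by k-fold cross-validation.

    For every candidate count ``k`` in 1..max_components the MSEP is the mean
    squared prediction error pooled over all held-out folds; the selected
    count is the first minimum of the curve.  ``groups`` (e.g. plant ids)
    keeps related rows inside one fold.  Candidate counts beyond the
    trainable rank of some fold are capped with a logged warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_t = _transform(y, target_transform)
    n = X.shape[0]
    if n < folds:
        raise ValueError(f"need at least folds={folds} rows, got {n}")
    if folds < 2:
        raise ValueError("fold_count must be >= 2")
    fold_of_row = _fold_assignment(n, folds, seed, groups)

    cap = max_components
    sq_err = np.zeros(max_components)
    counts = np.zeros(max_components)
    for f in range(folds):
        test = fold_of_row == f
        train = ~test
        if not test.any():
            continue
        Xtr, ytr = X[train], y_t[train]
        mean = Xtr.mean(axis=0)
        U, s, Vt = _svd(Xtr - mean)
        tol = s[0] * max(Xtr.shape) * np.finfo(float).eps if s.size else 0.0
        rank = int(np.sum(s > tol))
        k_fold = min(max_components, rank)
        if k_fold < cap:
            cap = k_fold
        b = float(ytr.mean())
        coef = (U[:, :k_fold].T @ (ytr - b)) / s[:k_fold]
        # cumulative predictions: scores_test[:, :k] @ coef[:k] for every k
        contrib = ((X[test] - mean) @ Vt[:k_fold].T) * coef
        cum = np.cumsum(contrib, axis=1) + b
        err = (cum - y_t[test][:, None]) ** 2
        sq_err[:k_fold] += err.sum(axis=0)
        counts[:k_fold] += err.shape[0]
        # component counts beyond this fold's rank reuse its best prediction
        if k_fold < max_components:
            sq_err[k_fold:] += err[:, -1].sum()
            counts[k_fold:] += err.shape[0]
    if cap < max_components:
        log.warning(
            "max_components=%d exceeds trainable rank in some fold; capped at %d",
            max_components,
            cap,
        )
    msep = sq_err / counts
    selected = int(np.argmin(msep[:cap])) + 1  # first minimum wins ties
    return CVResult(msep, selected, folds, seed)


def learning_curve(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    max_components: int = 41,
    seed: int = 0,
    groups: Sequence | None = None,
    target_transform: str = "identity",
) -> pd.DataFrame:
    """MSEP vs component count, as a table (identical to the CV curve)."""
    cv = select_components(
        X, y, folds, max_components, seed, groups, target_transform
    )
    return pd.DataFrame(
        {
            "n_components": np.arange(1, max_components + 1),
            "msep": cv.msep_by_components,
            "selected": np.arange(1, max_components + 1) == cv.selected_components,
        }
    )


def _bootstrap_rows(
    sset: SpectrumSet, targets: pd.Series, bcfg: BootstrapConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the bootstrap training matrix by resampling units with replacement."""
    meta = sset.metadata
    if bcfg.unit == "plant" and "plant_id" in meta.columns:
        unit_of_sample = meta["plant_id"].astype(str)
    else:
        unit_of_sample = pd.Series(sset.sample_ids, index=meta.index)
    units = list(pd.unique(unit_of_sample))
    rows_of_unit = {
        u: np.flatnonzero((unit_of_sample == u).to_numpy()) for u in units
    }
    y_of_unit = {}
    for u in units:
        sids = [sset.sample_ids[i] for i in rows_of_unit[u]]
        key = u if u in targets.index else sids[0]
        if key not in targets.index:
            raise KeyError(f"no target for unit {u!r} (tried {u!r} and {sids[0]!r})")
        y_of_unit[u] = float(targets.loc[key])

    rng = np.random.default_rng(bcfg.seed)
    if bcfg.with_replacement:
        draws = rng.integers(0, len(units), size=bcfg.n_resamples)
    else:
        if bcfg.n_resamples != len(units):
            raise ValueError(
                "with_replacement=False requires n_resamples == number of units"
            )
        draws = np.arange(len(units))
    X_rows, y_rows, g_rows = [], [], []
    for d in draws:
        u = units[int(d)]
        for r in rows_of_unit[u]:
            X_rows.append(sset.absorbance[r])
            y_rows.append(y_of_unit[u])
            g_rows.append(u)
    return np.vstack(X_rows), np.asarray(y_rows), np.asarray(g_rows)


def bootstrap_train(
    sset: SpectrumSet,
    targets: pd.Series,
    bcfg: BootstrapConfig | None = None,
    folds: int = 10,
    max_components: int = 41,
    target_transform: str = "log10",
) -> tuple[PCRModel, CVResult]:
    """Bootstrap-augmented PCR training with CV component selection.

    Units (plants by default) are drawn with replacement to build the
    training matrix; 10-fold CV over the bootstrap rows picks the component
    count with the lowest pooled MSEP (on the transformed target scale), and
    the final model is refit on the full bootstrap matrix at that count.
    """
    bcfg = bcfg or BootstrapConfig()
    if bcfg.n_resamples < folds:
        raise ValueError(
            f"n_resamples={bcfg.n_resamples} must be >= folds={folds}"
        )
    X, y, _groups = _bootstrap_rows(sset, targets, bcfg)
    cv = select_components(
        X,
        y,
        folds=folds,
        max_components=max_components,
        seed=bcfg.seed,
        target_transform=target_transform,
    )
    model = fit_pcr(
        X,
        y,
        cv.selected_components,
        target_transform=target_transform,
        training_grid=sset.wavenumbers,
    )
    return model, cv


def predict_available(model: PCRModel, sset: SpectrumSet) -> pd.Series:
    """Predict the available concentration (original units, e.g. uM P) per sample.

    The set's grid must equal the model's training grid exactly; use
    :func:`resample_to_grid` first if it does not (no silent interpolation).
    """
    if model.training_grid is not None:
        if (
            sset.wavenumbers.shape != model.training_grid.shape
            or not np.allclose(sset.wavenumbers, model.training_grid, rtol=0, atol=1e-9)
        ):
            raise GridMismatchError(
                "spectra grid does not match the model training grid "
                f"({sset.wavenumbers.size} vs {model.training_grid.size} points)"
            )
    preds = model.predict_matrix(sset.absorbance)
    return pd.Series(
        preds, index=pd.Index(sset.sample_ids, name="sample_id"),
        name=f"predicted_available ({model.target_transform} model)",
    )


def resample_to_grid(sset: SpectrumSet, grid: np.ndarray) -> SpectrumSet:
    """Explicit linear interpolation of a set onto a new wavenumber grid."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = sset.wavenumbers[0], sset.wavenumbers[-1]
    if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
        raise ValueError(
            f"target grid [{grid[0]}, {grid[-1]}] extends beyond data [{lo}, {hi}]"
        )
    mat = np.vstack(
        [np.interp(grid, sset.wavenumbers, row) for row in sset.absorbance]
    )
    return SpectrumSet(grid, mat, sset.sample_ids, sset.metadata)


# ------------------------------------------------------------ serialization

def save_model(model: PCRModel, path: str) -> None:
    """Serialize a model to a JSON container (text, grid + loadings + coefficients)."""
    payload = {
        "format": "phospec-pcr-model",
        "version": 1,
        "n_components": model.n_components,
        "target_transform": model.target_transform,
        "intercept": model.intercept,
        "mean_spectrum": model.mean_spectrum.tolist(),
        "coefficients": model.coefficients.tolist(),
        "loadings": model.loadings.tolist(),
        "training_grid": None
        if model.training_grid is None
        else model.training_grid.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> PCRModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "phospec-pcr-model":
        raise ValueError(f"{path}: not a phospec PCR model file")
    return PCRModel(
        mean_spectrum=np.asarray(payload["mean_spectrum"]),
        loadings=np.asarray(payload["loadings"]),
        coefficients=np.asarray(payload["coefficients"]),
        intercept=float(payload["intercept"]),
        n_components=int(payload["n_components"]),
        target_transform=payload["target_transform"],
        training_grid=None
        if payload["training_grid"] is None
        else np.asarray(payload["training_grid"]),
    )
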