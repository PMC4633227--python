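"""C-SVM (RBF kernel) anticancer-activity classifier.

The classifier consumes binary functional-group feature vectors and
predicts activity labels in {1, 0}.  Hyperparameters (cost C, kernel width
gamma) are tuned by exhaustive grid search over exponentially growing
sequences with stratified 5-fold cross-validation; the final model is
refit on the whole training set and persisted with the fingerprint of the
SMARTS catalog it was trained against, so mismatched feature spaces are
refused at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .featurization import (FeatureMatrix, SmartsCatalog, SmilesParseError,
                            featurize_compound)

logger = logging.getLogger(__name__)

__all__ = [
    "SvmParams",
    "GridSpec",
    "TrainedModel",
    "DEFAULT_PARAMS",
    "coarse_grid",
    "fine_grid",
    "cross_validate",
    "grid_search",
    "train_final",
    "predict_activity",
    "save_model",
    "load_model",
    "PARSE_FAILURE_LABEL",
]

#: Sentinel emitted for unparseable SMILES in batch prediction.
PARSE_FAILURE_LABEL = -1

#: Default chunk size for streaming prediction over large libraries.
DEFAULT_CHUNK_SIZE = 100_000


@dataclass(frozen=True)
class SvmParams:
    """Soft-margin cost C and RBF width gamma; both strictly positive."""

    C: float
    gamma: float

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


#: Best parameters of the reference fine grid search: C = 2^1.5, gamma = 2^-1.5.
DEFAULT_PARAMS = SvmParams(C=2.0 ** 1.5, gamma=2.0 ** -1.5)


def _arange_inclusive(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(start + i * step for i in range(n))


@dataclass(frozen=True)
class GridSpec:
    """Log2 exponent sequences for C and gamma, plus the CV fold count."""

    c_exponents: tuple[float, ...]
    gamma_exponents: tuple[float, ...]
    folds: int = 5

    def __post_init__(self):
        if not self.c_exponents or not self.gamma_exponents:
            raise ValueError("exponent sequences must be non-empty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @property
    def n_cells(self) -> int:
        return len(self.c_exponents) * len(self.gamma_exponents)

    def cells(self) -> Iterable[SvmParams]:
        for ce in self.c_exponents:
            for ge in self.gamma_exponents:
                yield SvmParams(C=2.0 ** ce, gamma=2.0 ** ge)


def coarse_grid(folds: int = 5) -> GridSpec:
    """Coarse search: C = 2^-5..2^15, gamma = 2^-15..2^3, whole-integer steps."""
    return GridSpec(_arange_inclusive(-5, 15, 1), _arange_inclusive(-15, 3, 1), folds)


def fine_grid(folds: int = 5) -> GridSpec:
    """Fine search: C = 2^-1..2^6, gamma = 2^-5..2^0, quarter-exponent steps."""
    return GridSpec(_arange_inclusive(-1, 6, 0.25), _arange_inclusive(-5, 0, 0.25), folds)


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")


def cross_validate(matrix: FeatureMatrix, params: SvmParams, folds: int = 5,
                   seed: int = 0) -> float:
    """Stratified k-fold cross-validation accuracy of an RBF SVM.

    Every row is predicted exactly once by a model trained on the other
    folds; the return value is (#correct out-of-fold predictions) / M.
    Fold assignment is stratified by label and shuffled with ``seed``, so
    the estimate is invariant to row order.
    """
    M = matrix.n_compounds
    if folds > M:
        raise ValueError(f"folds ({folds}) exceeds number of compounds ({M})")
    _check_two_classes(matrix.labels)
    X = matrix.bits.astype(np.float64)
    y = matrix.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        svc = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
        svc.fit(X[train_idx], y[train_idx])
        correct += int((svc.predict(X[test_idx]) == y[test_idx]).sum())
    return correct / M


def grid_search(matrix: FeatureMatrix, grid: GridSpec,
                seed: int = 0) -> tuple[SvmParams, pd.DataFrame]:
    """Exhaustive (C, gamma) search by cross-validation accuracy.

    Every grid cell is evaluated; the winner is the argmax cell, ties broken
    toward smaller C then smaller gamma (preferring smoother models).  The
    full accuracy surface is returned for contour plotting.
    """
    best: SvmParams | None = None
    best_acc = -1.0
    rows = []
    for ce in grid.c_exponents:
        for ge in grid.gamma_exponents:
            params = SvmParams(C=2.0 ** ce, gamma=2.0 ** ge)
            acc = cross_validate(matrix, params, folds=grid.folds, seed=seed)
            rows.append({"log2_C": ce, "log2_gamma": ge, "accuracy": acc})
            # strict improvement only: earlier cells (smaller C, then smaller
            # gamma) win ties because exponents are iterated in ascending order
            if acc > best_acc:
                best_acc = acc
                best = params
    surface = pd.DataFrame(rows)
    logger.info("grid search best: C=%g gamma=%g accuracy=%.4f",
                best.C, best.gamma, best_acc)
    return best, surface


@dataclass
class TrainedModel:
    """A fitted SVC plus its parameters and the catalog fingerprint it expects."""

    svc: SVC
    params: SvmParams
    catalog_fingerprint: str
    n_features: int
    format_version: int = 1

    def check_width(self, n: int) -> None:
        if n != self.n_features:
            raise ValueError(
                f"feature length {n} does not match the model's catalog "
                f"({self.n_features} features)")


def train_final(matrix: FeatureMatrix, params: SvmParams | None = None,
                catalog: SmartsCatalog | None = None) -> TrainedModel:
    """Fit the final classifier on the whole training set.

    Without explicit parameters the reference optimum C = 2^1.5,
    gamma = 2^-1.5 is used.  The catalog fingerprint (when a catalog is
    given) is stored so prediction can refuse mismatched feature spaces.
    """
    params = params or DEFAULT_PARAMS
    _check_two_classes(matrix.labels)
    svc = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
    svc.fit(matrix.bits.astype(np.float64), matrix.labels)
    fp = catalog.fingerprint() if catalog is not None else ""
    return TrainedModel(svc=svc, params=params, catalog_fingerprint=fp,
                        n_features=matrix.n_features)


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} is not an ocscreen model artifact")
    return model


def _predict_bits(model: TrainedModel, bits: np.ndarray,
                  chunk_size: int) -> np.ndarray:
    out = np.empty(bits.shape[0], dtype=np.int64)
    for start in range(0, bits.shape[0], chunk_size):
        block = bits[start:start + chunk_size].astype(np.float64)
        out[start:start + chunk_size] = model.svc.predict(block)
    return out


def predict_activity(
    model: TrainedModel,
    compounds: FeatureMatrix | Sequence[tuple[str, str]],
    catalog: SmartsCatalog | None = None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> np.ndarray:
    """Predict activity labels for a feature matrix or (id, smiles) table.

    Evaluation streams in chunks; chunked and unchunked results are
    identical and output order equals input order.  When SMILES records are
    given, a catalog is required (and checked against the model's stored
    catalog fingerprint); unparseable SMILES receive the sentinel label
    ``PARSE_FAILURE_LABEL`` with a warning.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be positive")
    if isinstance(compounds, FeatureMatrix):
        model.check_width(compounds.n_features)
        return _predict_bits(model, compounds.bits, chunk_size)
    if catalog is None:
        raise ValueError("a SMARTS catalog is required to featurize SMILES input")
    if model.catalog_fingerprint and catalog.fingerprint() != model.catalog_fingerprint:
        raise ValueError("catalog does not match the one the model was trained with")
    model.check_width(len(catalog))
    labels = np.empty(len(compounds), dtype=np.int64)
    rows: list[np.ndarray] = []
    row_pos: list[int] = []
    for i, (cid, smi) in enumerate(compounds):
        try:
            rows.append(featurize_compound(smi, catalog, compound_id=cid))
            row_pos.append(i)
        except SmilesParseError:
            logger.warning("unparseable SMILES for %s; sentinel label emitted", cid)
            labels[i] = PARSE_FAILURE_LABEL
    if rows:
        preds = _predict_bits(model, np.array(rows, dtype=np.uint8), chunk_size)
        for pos, pred in zip(row_pos, preds):
            labels[pos] = pred
    return labels
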