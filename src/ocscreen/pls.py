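"""Partial-least-squares target weighting and the oral-cancer score (OC_Score).

The training data is a three-class drug-target presence matrix: each row is
a therapeutic compound, each column a target gene, each cell 0/1 for the
compound targeting the gene.  The response is the indication class:
1 = active against oral cancer, 0 = active against other cancers,
-1 = no anticancer activity.  A one-component PLS1 regression of class on
the presence matrix (response and predictors mean-centered, unscaled)
yields a loading-weight vector over targets — the weight of a target
measures its contribution toward oral-cancer activity.

A compound's OC_Score is the sum of the weights of its targets
(``OC_Score = sum_i w[i]`` over the compound's target set); compounds are
screened by an inclusive cutoff derived as the rounded mean score of the
oral-cancer training class.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingMatrix",
    "TargetWeights",
    "OCScoreRecord",
    "PlsFit",
    "build_training_matrix",
    "fit_target_weights",
    "oc_score",
    "score_distribution",
    "derive_cutoff",
    "screen_compounds",
    "read_training_matrix",
    "write_training_matrix",
    "read_target_weights",
    "write_target_weights",
    "ORAL_CANCER_ICD10",
]

#: ICD10 codes for malignant neoplasms of the lip, tongue and oral cavity.
ORAL_CANCER_ICD10 = frozenset({f"C{i:02d}" for i in range(0, 7)})

VALID_CLASSES = (1, 0, -1)


@dataclass
class TrainingMatrix:
    """Rows of (record_id, class in {1,0,-1}) over binary target-presence columns."""

    record_ids: list[str]
    classes: np.ndarray  # shape (M,), values in {1, 0, -1}
    presence: np.ndarray  # shape (M, T), values in {0, 1}
    target_ids: list[str]

    def __post_init__(self):
        self.classes = np.asarray(self.classes, dtype=np.int64)
        self.presence = np.asarray(self.presence, dtype=np.uint8)
        m, t = self.presence.shape
        if len(self.record_ids) != m or len(self.classes) != m:
            raise ValueError("record_ids/classes must match presence row count")
        if len(self.target_ids) != t:
            raise ValueError("target_ids must match presence column count")
        if self.classes.size and not np.isin(self.classes, VALID_CLASSES).all():
            raise ValueError("class labels must be in {1, 0, -1}")
        if self.presence.size and not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence cells must be binary")

    @property
    def n_records(self) -> int:
        return self.presence.shape[0]

    @property
    def n_targets(self) -> int:
        return self.presence.shape[1]


@dataclass
class TargetWeights:
    """Map target gene id -> PLS loading weight (finite reals)."""

    weights: dict[str, float]

    def __post_init__(self):
        bad = [k for k, v in self.weights.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite weights for targets: {bad}")

    def __getitem__(self, gene_id: str) -> float:
        return self.weights[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.weights

    def __len__(self) -> int:
        return len(self.weights)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, name="weights")


@dataclass
class OCScoreRecord:
    compound_id: str
    targets: tuple[str, ...]
    oc_score: float
    n_unmapped: int = 0  # targets with no fitted weight (contribute 0)
    group: str | None = None  # class/source label for distribution plots


@dataclass
class PlsFit:
    """Full result of the one-component PLS1 fit."""

    weights: TargetWeights
    scores: np.ndarray  # latent scores t = Xc w
    x_loadings: np.ndarray  # p = Xc't / t't
    y_loading: float  # q = yc't / t't
    rmsep_loo: float | None  # leave-one-out root-mean-squared error of prediction


# ---------------------------------------------------------------------------
# Training-matrix construction from curated drug/compound-target tables
# ---------------------------------------------------------------------------

_ICD10_RE = re.compile(r"([A-Z])(\d{2})")


def _classify_icd10(codes: Iterable[str], oral_codes: frozenset[str]) -> set[int]:
    """Map a compound's ICD10 code list to the set of training classes it spans.

    Any code whose category (letter + two digits) is an oral-cavity neoplasm
    code contributes class 1; any other C-prefixed (malignant neoplasm) code
    contributes class 0; codes outside chapter C contribute class -1.
    """
    classes: set[int] = set()
    for code in codes:
        m = _ICD10_RE.match(code.strip().upper())
        if not m:
            continue
        category = m.group(1) + m.group(2)
        if category in oral_codes:
            classes.add(1)
        elif m.group(1) == "C":
            classes.add(0)
        else:
            classes.add(-1)
    return classes


def _split_multi(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    return [tok.strip() for tok in re.split(r"[,;|]", str(cell)) if tok.strip()]


def build_training_matrix(
    drug_tables: Sequence[pd.DataFrame],
    oral_codes: frozenset[str] = ORAL_CANCER_ICD10,
    extra_instances: Sequence[tuple[str, Iterable[str]]] = (),
) -> TrainingMatrix:
    """Combine curated drug/compound tables into the three-class training matrix.

    Each table needs an identifier column (``DrugName`` or ``compound_id``),
    an ``ICD10`` column (delimiter-separated codes) and a ``Targets`` column
    (delimiter-separated gene ids).  A compound indicated for oral cancer and
    also for other cancers emits two rows (classes 1 and 0) so neither signal
    is lost; a compound with only non-cancer indications gets class -1.
    ``extra_instances`` are appended as additional class-1 rows (prior-
    knowledge target profiles).  Rows with no targets are excluded.
    """
    rows: list[tuple[str, int, frozenset[str]]] = []
    n_dropped = 0
    for table in drug_tables:
        id_col = "DrugName" if "DrugName" in table.columns else "compound_id"
        for _, rec in table.iterrows():
            targets = frozenset(_split_multi(rec.get("Targets")))
            name = str(rec[id_col])
            if not targets:
                n_dropped += 1
                logger.warning("excluding %s: no targets", name)
                continue
            classes = _classify_icd10(_split_multi(rec.get("ICD10")), oral_codes)
            if not classes:
                n_dropped += 1
                logger.warning("excluding %s: no parseable ICD10 code", name)
                continue
            if 1 in classes:
                rows.append((name, 1, targets))
            if 0 in classes:
                rows.append((name, 0, targets))
            # a compound with any cancer indication is not a class -1 instance
            if -1 in classes and not classes & {0, 1}:
                rows.append((name, -1, targets))
    for name, targets in extra_instances:
        tset = frozenset(str(t) for t in targets)
        if not tset:
            raise ValueError(f"extra instance {name!r} has no targets")
        rows.append((name, 1, tset))
    if n_dropped:
        logger.warning("build_training_matrix excluded %d records", n_dropped)
    target_ids = sorted(set().union(*(t for _, _, t in rows)) if rows else set())
    col = {t: j for j, t in enumerate(target_ids)}
    presence = np.zeros((len(rows), len(target_ids)), dtype=np.uint8)
    for i, (_, _, targets) in enumerate(rows):
        for t in targets:
            presence[i, col[t]] = 1
    return TrainingMatrix(
        record_ids=[r[0] for r in rows],
        classes=np.array([r[1] for r in rows], dtype=np.int64),
        presence=presence,
        target_ids=target_ids,
    )


# ---------------------------------------------------------------------------
# PLS1 fit
# ---------------------------------------------------------------------------

def _pls1_component(Xc: np.ndarray, yc: np.ndarray):
    """One PLS1 component on centered data: weights, scores, loadings."""
    w = Xc.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("predictors carry no covariance with the response")
    w = w / norm
    t = Xc @ w
    tt = float(t @ t)
    p = (Xc.T @ t) / tt
    q = float(yc @ t) / tt
    return w, t, p, q


def fit_target_weights(matrix: TrainingMatrix, loo: bool = True) -> PlsFit:
    """Fit the one-component PLS1 model and extract per-target loading weights.

    Convention: response and predictor columns are mean-centered, not
    variance-scaled; the returned weight vector is the first loading-weight
    vector, unit Euclidean norm, sign such that it points along the centered
    cross-covariance X'y.  Columns never observed (all zero) receive weight 0
    with a warning.  Leave-one-out RMSEP is computed for reporting; the
    weights always come from the full-data fit.
    """
    if matrix.n_targets < 1:
        raise ValueError("training matrix has no target columns")
    if len(np.unique(matrix.classes)) < 2:
        raise ValueError("response is constant: need at least two distinct classes")
    X = matrix.presence.astype(np.float64)
    y = matrix.classes.astype(np.float64)
    zero_cols = [matrix.target_ids[j] for j in range(matrix.n_targets)
                 if not matrix.presence[:, j].any()]
    if zero_cols:
        warnings.warn(
            f"{len(zero_cols)} all-zero target columns receive weight 0", stacklevel=2)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    w, t, p, q = _pls1_component(Xc, yc)

    rmsep = None
    if loo and matrix.n_records > 2:
        errs = []
        for i in range(matrix.n_records):
            keep = np.ones(matrix.n_records, dtype=bool)
            keep[i] = False
            Xi, yi = X[keep], y[keep]
            xm, ym = Xi.mean(axis=0), yi.mean()
            try:
                wi, ti, pi, qi = _pls1_component(Xi - xm, yi - ym)
            except ValueError:
                continue
            # 1-component prediction for the held-out row
            b = wi * qi  # regression vector since p'w scaling folds into q for ncomp=1
            pred = ym + (X[i] - xm) @ b
            errs.append((pred - y[i]) ** 2)
        if errs:
            rmsep = float(np.sqrt(np.mean(errs)))

    weights = TargetWeights({t_id: float(wj) for t_id, wj in zip(matrix.target_ids, w)})
    return PlsFit(weights=weights, scores=t, x_loadings=p, y_loading=q, rmsep_loo=rmsep)


# ---------------------------------------------------------------------------
# OC_Score, distribution, cutoff, screening
# ---------------------------------------------------------------------------

def oc_score(targets: Iterable[str], weights: TargetWeights | Mapping[str, float],
             compound_id: str = "", group: str | None = None) -> OCScoreRecord:
    """Sum the weights of a compound's targets; unweighted targets contribute 0."""
    wmap = weights.weights if isinstance(weights, TargetWeights) else weights
    tlist = tuple(dict.fromkeys(str(t) for t in targets))  # de-dup, keep order
    total = 0.0
    unmapped = 0
    for t in tlist:
        if t in wmap:
            total += wmap[t]
        else:
            unmapped += 1
    if unmapped:
        logger.debug("compound %s: %d targets without fitted weights", compound_id, unmapped)
    return OCScoreRecord(compound_id=compound_id, targets=tlist, oc_score=total,
                         n_unmapped=unmapped, group=group)


_SUMMARY_COLS = ["Min.", "1st Quartile", "Median", "Mean", "3rd Quartile", "Max."]


def score_distribution(records: Iterable[OCScoreRecord]) -> pd.DataFrame:
    """Six-number summary (min, Q1, median, mean, Q3, max) of scores per group.

    Quartiles use linear interpolation between order statistics (R type-7),
    the convention of R's ``summary()``.  Groups with no scores are omitted
    with a warning.
    """
    by_group: dict[str, list[float]] = {}
    for rec in records:
        by_group.setdefault(rec.group or "all", []).append(rec.oc_score)
    rows = {}
    for group, vals in by_group.items():
        if not vals:
            warnings.warn(f"group {group!r} has no scores; omitted", stacklevel=2)
            continue
        arr = np.asarray(vals, dtype=np.float64)
        rows[group] = [
            float(arr.min()),
            float(np.quantile(arr, 0.25)),
            float(np.median(arr)),
            float(arr.mean()),
            float(np.quantile(arr, 0.75)),
            float(arr.max()),
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=_SUMMARY_COLS)


def derive_cutoff(class1_scores: Sequence[float] | Sequence[OCScoreRecord],
                  decimals: int = 2) -> float:
    """Screening cutoff = mean score of the oral-cancer class, rounded.

    Rounding is half-away-from-zero at ``decimals`` places (so a mean of
    0.6699 gives the conventional 0.67 two-decimal cutoff).
    """
    vals = [s.oc_score if isinstance(s, OCScoreRecord) else float(s)
            for s in class1_scores]
    if not vals:
        raise ValueError("cannot derive a cutoff from an empty score list")
    mean = float(np.mean(vals))
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(mean) * factor + 0.5), mean) / factor


def screen_compounds(records: Sequence[OCScoreRecord], cutoff: float) -> list[OCScoreRecord]:
    """Keep records with oc_score >= cutoff (inclusive), preserving input order."""
    return [r for r in records if r.oc_score >= cutoff]


# ---------------------------------------------------------------------------
# I/O: S14-style training matrix TSV and two-column weights TSV
# ---------------------------------------------------------------------------

def write_training_matrix(matrix: TrainingMatrix, path: str | Path) -> None:
    """Write the Record_ID / class / per-target 0-1 column layout."""
    df = pd.DataFrame(matrix.presence, columns=matrix.target_ids)
    df.insert(0, "class", matrix.classes)
    df.insert(0, "Record_ID", matrix.record_ids)
    df.to_csv(path, sep="\t", index=False)


def read_training_matrix(path: str | Path) -> TrainingMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"Record_ID": str})
    if list(df.columns[:2]) != ["Record_ID", "class"]:
        raise ValueError(f"{path}: first two columns must be Record_ID and class")
    target_ids = [str(c) for c in df.columns[2:]]
    return TrainingMatrix(
        record_ids=df["Record_ID"].tolist(),
        classes=df["class"].to_numpy(dtype=np.int64),
        presence=df.iloc[:, 2:].to_numpy(dtype=np.uint8),
        target_ids=target_ids,
    )


def write_target_weights(weights: TargetWeights, path: str | Path) -> None:
    pd.DataFrame({"features": list(weights.weights),
                  "weights": list(weights.weights.values())}).to_csv(
        path, sep="\t", index=False)


def read_target_weights(path: str | Path) -> TargetWeights:
    df = pd.read_csv(path, sep="\t", dtype={"features": str})
    return TargetWeights(dict(zip(df["features"], df["weights"].astype(float))))
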