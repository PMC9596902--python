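"""Screening of arthroscopic spectra with poor probe–cartilage contact.

Saline between the probe tip and the cartilage surface inflates the
water absorption band near 1.4 μm and corrupts the measurement.  There
is no direct label for "poor contact", so labels are manufactured from
the calibration model itself: an ex vivo training spectrum whose
prediction error exceeds a threshold (2× or 3× the model's RMSECV, or
the upper half of absolute errors) is labelled an outlier.  A classifier
(1-NN, distance-weighted 10-NN, or RBF SVM) is then trained on the first
12 PCA scores of the ex vivo spectra and applied to the held-out
cadaver's arthroscopic spectra.

Candidate combinations of algorithm × label rule × preprocessing are
screened: any candidate flagging fewer than 10% or more than 90% of
ex vivo spectra is discarded as unrealistic; survivors are ranked by the
agreement of in vitro and ex vivo performance over the same retained
locations (smaller |ρ_in_vitro − ρ_ex_vivo| gap is better), with ties
broken by classifier F1 then accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .evaluation import classification_metrics
from .pca_lme import PcaModel, project
from .preprocess import PreprocessConfig
from .spectral_data import LOCATION_COLUMNS, CartigradeError

logger = logging.getLogger(__name__)

ALGORITHMS = ("fine_knn", "weighted_knn", "svm")
N_CLASSIFIER_SCORES = 12
OUTLIER_S_BOUNDS = (10.0, 90.0)  # admissible % of ex vivo spectra flagged


class LabelRuleError(CartigradeError):
    """The label rule produced unusable (single-class) labels."""


class SelectionError(CartigradeError):
    """No candidate combination survived the screening constraints."""


@dataclass(frozen=True)
class LabelRule:
    """How outlier labels are manufactured from prediction errors."""

    kind: str  # 'rmsecv_multiple' | 'half_split'
    factor: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "rmsecv_multiple":
            if self.factor not in (2, 3):
                raise ValueError("rmsecv_multiple factor must be 2 or 3")
        elif self.kind == "half_split":
            if self.factor is not None:
                raise ValueError("half_split takes no factor")
        else:
            raise ValueError(f"unknown label rule {self.kind!r}")

    def describe(self) -> str:
        return f"{self.factor}xRMSECV" if self.kind == "rmsecv_multiple" else "half_split"


DEFAULT_RULES = (LabelRule("rmsecv_multiple", 2), LabelRule("rmsecv_multiple", 3),
                 LabelRule("half_split"))


def generate_labels(predictions, references, rmsecv: float, rule: LabelRule) -> np.ndarray:
    """Binary outlier labels per spectrum from absolute prediction errors.

    ``rmsecv_multiple``: label 1 iff |pred − ref| > factor × RMSECV.
    ``half_split``: the ⌈n/2⌉ spectra with the largest absolute errors
    are labelled 1; ties at the boundary are resolved by stable original
    (location, replicate) order.
    """
    predictions = np.asarray(predictions, dtype=float)
    references = np.asarray(references, dtype=float)
    if predictions.shape != references.shape:
        raise ValueError("predictions and references must align")
    errors = np.abs(predictions - references)
    if rule.kind == "rmsecv_multiple":
        if not rmsecv > 0:
            raise ValueError("rmsecv must be > 0")
        return (errors > rule.factor * rmsecv).astype(int)
    n = len(errors)
    n_out = int(np.ceil(n / 2))
    order = np.argsort(-errors, kind="stable")  # descending, stable among ties
    labels = np.zeros(n, dtype=int)
    labels[order[:n_out]] = 1
    if n_out and errors[order[n_out - 1]] == errors[order[-1]]:
        logger.info("half_split ties at the median error resolved by stable index order")
    return labels


# ---------------------------------------------------------------------------
# classifier training and application
# ---------------------------------------------------------------------------


def _inverse_squared_distance(distances: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        w = 1.0 / (distances ** 2)
    # exact matches get all the weight
    inf_rows = np.isinf(w).any(axis=1)
    w[inf_rows] = np.isinf(w[inf_rows]).astype(float)
    return w


def _median_heuristic_gamma(scores: np.ndarray, rng: np.random.Generator) -> float:
    """RBF kernel scale: gamma = 1 / (2 · median pairwise distance²)."""
    n = len(scores)
    sample = scores if n <= 500 else scores[rng.choice(n, 500, replace=False)]
    d2 = np.sum((sample[:, None, :] - sample[None, :, :]) ** 2, axis=-1)
    med = np.median(np.sqrt(d2[np.triu_indices_from(d2, k=1)]))
    if med <= 0:
        return 1.0
    return float(1.0 / (2.0 * med ** 2))


def _make_estimator(algorithm: str, scores: np.ndarray, rng: np.random.Generator):
    if algorithm == "fine_knn":
        return KNeighborsClassifier(n_neighbors=1, metric="euclidean")
    if algorithm == "weighted_knn":
        n_neighbors = min(10, len(scores) - 1)
        return KNeighborsClassifier(n_neighbors=n_neighbors, metric="euclidean",
                                    weights=_inverse_squared_distance)
    if algorithm == "svm":
        return SVC(kernel="rbf", C=1.0, gamma=_median_heuristic_gamma(scores, rng))
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class ContactClassifier:
    """A trained poor-contact screen and its provenance."""

    algorithm: str
    preprocess: PreprocessConfig
    rule: LabelRule
    pca: PcaModel
    estimator: object
    train_accuracy: float
    train_f1: float
    n_scores: int = N_CLASSIFIER_SCORES

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(scores[:, : self.n_scores]), dtype=int)


def train_classifier(scores: np.ndarray, labels: np.ndarray, algorithm: str,
                     preprocess: PreprocessConfig, rule: LabelRule, pca: PcaModel,
                     n_folds: int = 10, seed: int = 0) -> ContactClassifier:
    """Train one classifier on 12 PCA scores with k-fold CV metrics.

    Cross-validated accuracy/F1 are computed with stratified folds; the
    returned estimator is refit on all rows.
    """
    scores = np.asarray(scores, dtype=float)[:, :N_CLASSIFIER_SCORES]
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise LabelRuleError(
            f"labels are single-class ({classes.tolist()}); choose a different "
            "rule or threshold so both classes are present"
        )
    rng = np.random.default_rng(seed)
    estimator = _make_estimator(algorithm, scores, rng)
    n_folds_eff = min(n_folds, int(np.bincount(labels).min()))
    if n_folds_eff < 2:
        raise LabelRuleError("minority class too small for cross-validation")
    cv = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed % (2 ** 31))
    pred = cross_val_predict(estimator, scores, labels, cv=cv)
    accuracy, f1 = classification_metrics(labels, pred)
    estimator.fit(scores, labels)
    return ContactClassifier(algorithm=algorithm, preprocess=preprocess, rule=rule,
                             pca=pca, estimator=estimator, train_accuracy=accuracy,
                             train_f1=f1)


@dataclass
class ExclusionSummary:
    """Flagging outcome on one set of arthroscopic spectra.

    ``outlier_s``: % of spectra flagged.  ``outlier_n``: % of
    measurement locations excluded outright — a location is excluded
    only when *all* of its replicate spectra are flagged.
    """

    outlier_s: float
    outlier_n: float
    retained_locations: list[tuple] = field(default_factory=list)
    excluded_locations: list[tuple] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"outlier_s_pct": self.outlier_s, "outlier_n_pct": self.outlier_n,
                "n_retained_locations": len(self.retained_locations),
                "n_excluded_locations": len(self.excluded_locations)}


def summarize_exclusion(meta: pd.DataFrame, labels: np.ndarray) -> ExclusionSummary:
    """OutlierS / OutlierN percentages from per-spectrum flags."""
    labels = np.asarray(labels, dtype=int)
    if len(meta) != len(labels):
        raise ValueError("meta and labels must align")
    outlier_s = 100.0 * labels.mean() if len(labels) else 0.0
    flagged = pd.Series(labels, index=meta.index)
    retained, excluded = [], []
    for key, idx in meta.groupby(LOCATION_COLUMNS, sort=True).indices.items():
        if flagged.iloc[idx].all():
            excluded.append(tuple(key))
        else:
            retained.append(tuple(key))
    n_loc = len(retained) + len(excluded)
    outlier_n = 100.0 * len(excluded) / n_loc if n_loc else 0.0
    return ExclusionSummary(outlier_s=float(outlier_s), outlier_n=float(outlier_n),
                            retained_locations=retained, excluded_locations=excluded)


def classify_spectra(classifier: ContactClassifier, scores: np.ndarray,
                     meta: pd.DataFrame) -> tuple[np.ndarray, ExclusionSummary]:
    """Flag spectra of an unseen cadaver and summarize the exclusions.

    ``scores`` must come from the classifier's own preprocessing config
    and PCA basis.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] < classifier.n_scores:
        raise ValueError(
            f"need {classifier.n_scores} score columns, got {scores.shape[1]}; "
            "grid/PCA mismatch with the classifier"
        )
    labels = classifier.predict(scores)
    return labels, summarize_exclusion(meta, labels)


# ---------------------------------------------------------------------------
# combination selection
# ---------------------------------------------------------------------------


@dataclass
class CandidateResult:
    """Evaluation record for one algorithm × rule × preprocessing combo."""

    algorithm: str
    rule: LabelRule
    preprocess: PreprocessConfig
    outlier_s: float            # median % of ex vivo spectra flagged
    srl_gap: float              # median |ρ_in_vitro,SRL − ρ_ex_vivo,SRL|
    accuracy: float             # median CV training accuracy
    f1: float                   # median CV training F1
    payload: object = None      # pipeline-level detail (per-iteration records)

    def describe(self) -> str:
        return f"{self.algorithm}/{self.rule.describe()}/{self.preprocess.describe()}"


def select_combo(candidates: list[CandidateResult]) -> tuple[CandidateResult, pd.DataFrame]:
    """Screen and rank candidate combinations; return winner + ranking table.

    Candidates flagging < 10% or > 90% of ex vivo spectra are removed;
    the rest are ranked by ascending SRL ρ-gap, ties broken by
    descending F1 then descending accuracy.
    """
    if not candidates:
        raise SelectionError("no candidate combinations supplied")
    lo, hi = OUTLIER_S_BOUNDS
    rows = []
    survivors = []
    for c in candidates:
        admissible = lo <= c.outlier_s <= hi
        rows.append({"combo": c.describe(), "outlier_s": c.outlier_s,
                     "srl_gap": c.srl_gap, "f1": c.f1, "accuracy": c.accuracy,
                     "admissible": admissible})
        if admissible:
            survivors.append(c)
    table = pd.DataFrame(rows).sort_values(
        ["admissible", "srl_gap", "f1", "accuracy"],
        ascending=[False, True, False, False]).reset_index(drop=True)
    if not survivors:
        raise SelectionError(
            "every candidate flagged <10% or >90% of ex vivo spectra; "
            "expand the algorithm/rule/preprocessing grid"
        )
    winner = min(survivors, key=lambda c: (c.srl_gap, -c.f1, -c.accuracy))
    return winner, table
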