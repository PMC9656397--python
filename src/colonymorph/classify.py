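"""Phenotype classification from morphological descriptors.

The analysis protocol:

1. train a cross-validated classifier on all descriptors (the "full model");
2. enumerate every descriptor subset of size 2..p, train each, and score a
   per-descriptor *importance*: the mean cross-validation accuracy over all
   evaluated subsets that contain the descriptor;
3. train models on the k best descriptors (k = 2..p) to obtain the
   accuracy-versus-k curve, and pick the *minimal model*: the smallest k
   whose mean accuracy is within one standard error of the best k;
4. evaluate the minimal model on the whole sample via pooled out-of-fold
   predictions and report the confusion matrix with per-class rates.

The classifier is a declared, seeded stand-in for an automated model
search: a single-hidden-layer feed-forward network over a small fixed
hyperparameter grid, with a logistic-regression alternative for fast runs.
Inputs are standardized inside each training fold; no other preprocessing
is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .morphometry import CELL_PARAMETERS, COLONY_PARAMETERS

logger = logging.getLogger(__name__)

PHENOTYPE_LABELS = ("bad", "good")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    """Declared classifier family, hyperparameter grid and CV protocol.

    ``model_family`` is ``"mlp"`` (single hidden layer, grid over hidden
    units x L2 strength) or ``"logistic"`` (grid over C).  The grid is
    finite and enumerated in declared order; ties in CV accuracy go to the
    earlier grid point.  The CV protocol is repeated stratified k-fold;
    the SEM of accuracy is computed across the repeat-level means.
    """

    model_family: str = "mlp"
    hidden_units: tuple[int, ...] = (4, 8, 16)
    alphas: tuple[float, ...] = (1e-4, 1e-2)
    logistic_c: tuple[float, ...] = (1.0,)
    max_iter: int = 400
    cv_folds: int = 5
    cv_repeats: int = 10
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.model_family not in ("mlp", "logistic"):
            raise ValueError("model_family must be 'mlp' or 'logistic'")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")

    def grid(self) -> list[dict]:
        if self.model_family == "mlp":
            return [{"hidden": h, "alpha": a}
                    for h in self.hidden_units for a in self.alphas]
        return [{"C": c} for c in self.logistic_c]

    def make_estimator(self, params: dict):
        if self.model_family == "mlp":
            return MLPClassifier(
                hidden_layer_sizes=(params["hidden"],),
                alpha=params["alpha"],
                solver="lbfgs",
                max_iter=self.max_iter,
                random_state=self.seed,
            )
        return LogisticRegression(C=params["C"], max_iter=self.max_iter,
                                  random_state=self.seed)


#: fast preset used by pipeline runs and simulation studies
FAST_LOGISTIC = ClassifierConfig(model_family="logistic", cv_repeats=2)


# --------------------------------------------------------------------------
# results containers
# --------------------------------------------------------------------------

@dataclass
class SubsetResult:
    """Cross-validation outcome for one descriptor subset."""

    subset: tuple[str, ...]
    mean_accuracy: float
    sem_accuracy: float
    per_fold_accuracies: np.ndarray  # shape (repeats, folds)
    best_params: dict = field(default_factory=dict)

    @property
    def per_repeat_accuracies(self) -> np.ndarray:
        return self.per_fold_accuracies.mean(axis=1)


@dataclass
class ImportanceTable:
    """Per-descriptor importance: mean accuracy over subsets containing it."""

    table: pd.DataFrame  # columns: parameter, importance, n_models
    subset_results: list[SubsetResult] = field(default_factory=list)

    @property
    def parameters(self) -> list[str]:
        return list(self.table["parameter"])


@dataclass
class ConfusionMatrix:
    """2x2 observed x predicted counts for the bad/good phenotypes."""

    counts: np.ndarray  # rows observed (bad, good), cols predicted (bad, good)
    labels: tuple[str, str] = PHENOTYPE_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 2x2 with counts >= 0")

    @classmethod
    def from_labels(cls, observed, predicted,
                    labels: tuple[str, str] = PHENOTYPE_LABELS):
        observed = np.asarray(observed)
        predicted = np.asarray(predicted)
        if observed.shape != predicted.shape:
            raise ValueError("observed and predicted labels must align")
        unknown = (set(observed) | set(predicted)) - set(labels)
        if unknown:
            raise ValueError(f"unexpected labels: {sorted(unknown)}")
        counts = np.zeros((2, 2), dtype=int)
        for i, obs in enumerate(labels):
            for j, pred in enumerate(labels):
                counts[i, j] = int(((observed == obs) & (predicted == pred)).sum())
        return cls(counts, labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def class_rate(self, label: str) -> float:
        """Correctly classified members of an observed class divided by the
        class's observed total (the per-class rate quoted alongside the
        confusion matrix)."""
        i = self.labels.index(label)
        return float(self.counts[i, i]) / float(self.counts[i].sum())

    def to_frame(self) -> pd.DataFrame:
        idx = [f"observed_{l}" for l in self.labels]
        cols = [f"predicted_{l}" for l in self.labels]
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def round_percent(fraction: float) -> int:
    """Round a fraction to an integer percentage, halves up."""
    return int(Decimal(fraction * 100).quantize(0, rounding=ROUND_HALF_UP))


@dataclass
class EvaluationResult:
    """Confusion matrix plus the derived headline metrics."""

    confusion: ConfusionMatrix
    per_line_misclassified: pd.DataFrame | None = None

    @property
    def accuracy_pct(self) -> int:
        return round_percent(self.confusion.accuracy)

    def class_pct(self, label: str) -> int:
        return round_percent(self.confusion.class_rate(label))

    def summary(self) -> str:
        lines = [self.confusion.to_frame().to_string(), ""]
        lines.append(f"overall accuracy: {self.accuracy_pct}%")
        for label in self.confusion.labels:
            lines.append(f"{label} class: {self.class_pct(label)}%")
        if self.per_line_misclassified is not None:
            lines += ["", "misclassified per line:",
                      self.per_line_misclassified.to_string(index=False)]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# core operations
# --------------------------------------------------------------------------

def _design(records: pd.DataFrame, subset: Sequence[str]):
    missing = [p for p in subset if p not in records.columns]
    if missing:
        raise KeyError(f"unknown parameter(s): {missing}")
    X = records[list(subset)].to_numpy(dtype=float)
    y = records["phenotype"].to_numpy()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two phenotype classes to train")
    return X, y


def _fold_accuracy(est, X, y, train, test, standardize: bool) -> float:
    Xtr, Xte = X[train], X[test]
    if standardize:
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(Xtr, y[train])
    return float((est.predict(Xte) == y[test]).mean())


def train_cv(records: pd.DataFrame, subset: Sequence[str],
             config: ClassifierConfig) -> SubsetResult:
    """Repeated stratified k-fold CV accuracy of one descriptor subset.

    Every grid point is evaluated on the same folds; the reported result is
    the grid point with the best mean accuracy (earlier grid point on ties).
    Fully reproducible from the config seed.
    """
    X, y = _design(records, subset)
    cv = RepeatedStratifiedKFold(n_splits=config.cv_folds,
                                 n_repeats=config.cv_repeats,
                                 random_state=config.seed)
    splits = list(cv.split(X, y))
    best = None
    for params in config.grid():
        accs = np.array([
            _fold_accuracy(config.make_estimator(params), X, y, tr, te,
                           config.standardize)
            for tr, te in splits
        ]).reshape(config.cv_repeats, config.cv_folds)
        if best is None or accs.mean() > best[0].mean():
            best = (accs, params)
    accs, params = best
    per_repeat = accs.mean(axis=1)
    if config.cv_repeats > 1:
        sem = per_repeat.std(ddof=1) / np.sqrt(config.cv_repeats)
    else:
        sem = accs.ravel().std(ddof=1) / np.sqrt(accs.size)
    return SubsetResult(tuple(subset), float(accs.mean()), float(sem),
                        accs, params)


def enumerate_subsets(parameters: Sequence[str], min_size: int = 2,
                      max_size: int | None = None) -> list[tuple[str, ...]]:
    """All descriptor subsets with sizes in [min_size, max_size],
    in deterministic order (by size, then input order)."""
    parameters = list(parameters)
    if not parameters:
        raise ValueError("parameter list is empty")
    if max_size is None:
        max_size = len(parameters)
    if not 2 <= min_size <= max_size:
        raise ValueError(
            f"need 2 <= min_size <= max_size, got ({min_size}, {max_size})")
    out: list[tuple[str, ...]] = []
    for size in range(min_size, max_size + 1):
        out.extend(combinations(parameters, size))
    return out


def importance_table(records: pd.DataFrame, parameters: Sequence[str],
                     config: ClassifierConfig) -> ImportanceTable:
    """Exhaustive-subset importance of every descriptor.

    Trains one CV model per subset of size 2..p and scores each descriptor
    by the unweighted mean of the mean accuracies of all subsets containing
    it.  Sorted by descending importance; ties break alphabetically.
    """
    subsets = enumerate_subsets(parameters)
    results = []
    for subset in subsets:
        try:
            results.append(train_cv(records, subset, config))
        except Exception as err:
            raise RuntimeError(f"training failed for subset {subset}") from err
    rows = []
    for param in parameters:
        accs = [r.mean_accuracy for r in results if param in r.subset]
        rows.append({"parameter": param,
                     "importance": float(np.mean(accs)),
                     "n_models": len(accs)})
    table = (pd.DataFrame(rows)
             .sort_values(["importance", "parameter"],
                          ascending=[False, True], kind="stable")
             .reset_index(drop=True))
    return ImportanceTable(table, results)


def topk_curve(records: pd.DataFrame, importance: ImportanceTable,
               config: ClassifierConfig, min_k: int = 2) -> list[SubsetResult]:
    """Accuracy of the model built on the k best descriptors, k = min_k..p."""
    ranked = importance.parameters
    return [train_cv(records, tuple(ranked[:k]), config)
            for k in range(min_k, len(ranked) + 1)]


def select_minimal_model(curve: Sequence[SubsetResult]
                         ) -> tuple[int, tuple[str, ...]]:
    """Smallest k whose mean accuracy is within one SEM of the best k.

    The threshold is (best mean accuracy) - (SEM at the maximizer); the
    minimal model is the first curve entry at or above it.
    """
    if not curve:
        raise ValueError("empty accuracy curve")
    means = np.array([r.mean_accuracy for r in curve])
    best_idx = int(np.argmax(means))
    threshold = means[best_idx] - curve[best_idx].sem_accuracy
    for r in curve:
        if r.mean_accuracy >= threshold:
            return len(r.subset), r.subset
    return len(curve[best_idx].subset), curve[best_idx].subset


def drop_correlated(records: pd.DataFrame, parameters: Sequence[str],
                    threshold: float = 0.95) -> list[str]:
    """Greedy pre-filter of near-collinear descriptors.

    Walks the descriptors in the given order and drops any whose absolute
    Pearson correlation with an already-retained descriptor exceeds the
    threshold.  Mirrors the preliminary exclusion of the two caliper
    diameters from the cellular models, which track the fitted-ellipse axes
    almost exactly.
    """
    corr = records[list(parameters)].corr().abs()
    retained: list[str] = []
    for p in parameters:
        if any(corr.loc[p, q] > threshold for q in retained):
            logger.info("dropping %s (|r| > %.2f with a retained descriptor)",
                        p, threshold)
            continue
        retained.append(p)
    return retained


def pooled_cv_predictions(records: pd.DataFrame, subset: Sequence[str],
                          config: ClassifierConfig,
                          mode: str = "pooled_cv") -> np.ndarray:
    """Whole-sample predictions for confusion-matrix evaluation.

    ``"pooled_cv"`` (default) pools out-of-fold predictions over one
    stratified CV split; ``"resubstitution"`` predicts the training sample
    with a model fitted on all of it.
    """
    X, y = _design(records, subset)
    params = train_cv(records, subset, config).best_params
    pred = np.empty(len(y), dtype=object)
    if mode == "resubstitution":
        est = config.make_estimator(params)
        Xs = X
        if config.standardize:
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd[sd == 0] = 1.0
            Xs = (X - mu) / sd
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xs, y)
        return est.predict(Xs)
    if mode != "pooled_cv":
        raise ValueError("mode must be 'pooled_cv' or 'resubstitution'")
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                         random_state=config.seed)
    for train, test in cv.split(X, y):
        est = config.make_estimator(params)
        Xtr, Xte = X[train], X[test]
        if config.standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xtr, y[train])
        pred[test] = est.predict(Xte)
    return pred.astype(str)


def evaluate(observed, predicted, lines=None,
             labels: tuple[str, str] = PHENOTYPE_LABELS) -> EvaluationResult:
    """Confusion matrix and headline metrics from aligned label vectors.

    Overall accuracy is trace/total; the per-class rate is the correctly
    classified members of an observed class over that class's observed
    total.  Percentages are rounded half-up to integers.  When ``lines`` is
    given, misclassification counts are additionally broken down per line.
    """
    cm = ConfusionMatrix.from_labels(observed, predicted, labels)
    per_line = None
    if lines is not None:
        lines = np.asarray(lines)
        observed = np.asarray(observed)
        predicted = np.asarray(predicted)
        rows = []
        for line in pd.unique(lines):
            m = lines == line
            wrong = int((observed[m] != predicted[m]).sum())
            rows.append({"line": line, "n": int(m.sum()),
                         "misclassified": wrong,
                         "pct": round_percent(wrong / max(int(m.sum()), 1))})
        per_line = pd.DataFrame(rows)
    return EvaluationResult(cm, per_line)


def evaluate_counts(bad_as_bad: int, bad_as_good: int, good_as_bad: int,
                    good_as_good: int) -> EvaluationResult:
    """Evaluation metrics straight from 2x2 confusion counts."""
    cm = ConfusionMatrix(np.array([[bad_as_bad, bad_as_good],
                                   [good_as_bad, good_as_good]]))
    return EvaluationResult(cm)


def per_line_models(records: pd.DataFrame, parameters: Sequence[str],
                    config: ClassifierConfig) -> dict[str, SubsetResult]:
    """One CV result per cell line, same protocol as the pooled model.
    Lines with a single phenotype class are skipped with a warning."""
    out: dict[str, SubsetResult] = {}
    for line, df_line in records.groupby("line", sort=True):
        if df_line["phenotype"].nunique() < 2:
            warnings.warn(f"line {line!r} has a single phenotype class; skipped",
                          stacklevel=2)
            continue
        out[str(line)] = train_cv(df_line.reset_index(drop=True),
                                  parameters, config)
    return out


# --------------------------------------------------------------------------
# model / results facade
# --------------------------------------------------------------------------

class PhenotypeClassifier:
    """Phenotype classification study on a descriptor table.

    Bundles the full protocol — full model, exhaustive-subset importance,
    top-k curve, minimal-model selection and whole-sample confusion matrix —
    behind a fit() returning a :class:`PhenotypeClassifierResults`.

    Parameters
    ----------
    records : descriptor table with a ``phenotype`` column.
    parameters : descriptors to use; defaults to the seven colony
        descriptors (or the cellular set when ``unit="cell"``), pre-filtered
        for near-collinear pairs when ``decorrelate`` is set.
    config : classifier family, grid and CV protocol.
    """

    def __init__(self, records: pd.DataFrame,
                 parameters: Sequence[str] | None = None,
                 config: ClassifierConfig | None = None,
                 unit: str = "colony",
                 decorrelate: float | None = None):
        records = records[records["unit"] == unit].reset_index(drop=True)
        if records.empty:
            raise ValueError(f"no records with unit={unit!r}")
        if parameters is None:
            parameters = (COLONY_PARAMETERS if unit == "colony"
                          else CELL_PARAMETERS)
        parameters = list(parameters)
        if decorrelate is not None:
            parameters = drop_correlated(records, parameters, decorrelate)
        self.records = records
        self.parameters = parameters
        self.config = config or ClassifierConfig()
        self.unit = unit

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PhenotypeClassifier":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, per_line: bool = False) -> "PhenotypeClassifierResults":
        full = train_cv(self.records, tuple(self.parameters), self.config)
        imp = importance_table(self.records, self.parameters, self.config)
        curve = topk_curve(self.records, imp, self.config)
        k_star, subset = select_minimal_model(curve)
        pred = pooled_cv_predictions(self.records, subset, self.config)
        evaluation = evaluate(self.records["phenotype"].to_numpy(), pred,
                              lines=self.records["line"].to_numpy())
        line_results = (per_line_models(self.records, subset, self.config)
                        if per_line else None)
        return PhenotypeClassifierResults(
            model=self, full_model=full, importance=imp, curve=curve,
            minimal_k=k_star, minimal_subset=subset, evaluation=evaluation,
            per_line=line_results)


@dataclass
class PhenotypeClassifierResults:
    """Fitted phenotype-classification study."""

    model: PhenotypeClassifier
    full_model: SubsetResult
    importance: ImportanceTable
    curve: list[SubsetResult]
    minimal_k: int
    minimal_subset: tuple[str, ...]
    evaluation: EvaluationResult
    per_line: dict[str, SubsetResult] | None = None

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"k": len(r.subset), "subset": "+".join(r.subset),
             "mean_accuracy": r.mean_accuracy, "sem_accuracy": r.sem_accuracy}
            for r in self.curve
        ])

    def summary(self) -> str:
        cfg = self.model.config
        out = [
            "Phenotype classification study",
            "=" * 34,
            f"unit: {self.model.unit}   records: {len(self.model.records)}",
            f"classifier: {cfg.model_family}   CV: {cfg.cv_repeats} x "
            f"{cfg.cv_folds}-fold (seed {cfg.seed})",
            "",
            f"full model ({len(self.full_model.subset)} descriptors): "
            f"{100 * self.full_model.mean_accuracy:.1f} +/- "
            f"{100 * self.full_model.sem_accuracy:.1f} %",
            "",
            "descriptor importance (mean accuracy over subsets containing it):",
            self.importance.table.to_string(index=False),
            "",
            "accuracy vs number of best descriptors:",
            self.curve_frame().to_string(index=False),
            "",
            f"minimal model: k = {self.minimal_k} "
            f"({', '.join(self.minimal_subset)})",
            "",
            "whole-sample evaluation (pooled out-of-fold predictions):",
            self.evaluation.summary(),
        ]
        if self.per_line:
            out += ["", "per-line models on the minimal subset:"]
            for line, r in self.per_line.items():
                out.append(f"  {line}: {100 * r.mean_accuracy:.1f} +/- "
                           f"{100 * r.sem_accuracy:.1f} %")
        return "\n".join(out)
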