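"""The nine-classifier bank and the two-fold (repetition-wise) cross-validation.

Nine canonical classifier configurations are compared: a fine decision tree
(DTf, Gini criterion, at most 100 splits), three support vector machines
(linear / quadratic / cubic kernel, box constraint C = 1, kernel scale 1,
one-vs-one multiclass), four k-nearest-neighbour variants (fine kNN with
k = 1 and Euclidean distance; cosine, cubic-Minkowski and squared-inverse
weighted kNN with k = 10), and a feed-forward neural network with three
hidden layers trained on a cross-entropy objective for up to 1000 iterations.

Every model is wrapped in an sklearn :class:`~sklearn.pipeline.Pipeline`
whose first step z-scores the features with training-fold statistics, so the
distance- and margin-based learners see comparable scales.  Cross-validation
uses repetition 1 as training set and repetition 2 as test set, then vice
versa, and averages the two 3x3 confusion matrices elementwise.

Model naming follows ``<classifier><combo><segment>``, e.g. ``SVMqaSH`` for
the quadratic SVM fed with shank accelerations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, InputError, InsufficientDataError
from .features import FeatureMatrix
from .synthdata import CONDITIONS

CLASSIFIER_NAMES = (
    "DTf",
    "SVMl",
    "SVMq",
    "SVMc",
    "kNNf",
    "kNNco",
    "kNNcu",
    "kNNw",
    "ANN",
)


def pairwise_distance(metric: str, x, y, exponent: float = 3, weights=None) -> float:
    """The four kNN distances: euclidean, cosine, minkowski, weighted-euclidean.

    Cosine is implemented as ``1 - similarity`` (a similarity cannot serve as
    a distance).  ``weights`` applies per-feature weights w_i to the
    weighted-euclidean form and defaults to all ones.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D vectors of equal length")
    if metric == "euclidean":
        return float(np.sqrt(np.sum((x - y) ** 2)))
    if metric == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            raise InputError("cosine distance is undefined for zero vectors")
        return float(1.0 - np.dot(x, y) / (nx * ny))
    if metric == "minkowski":
        return float(np.sum(np.abs(x - y) ** exponent) ** (1.0 / exponent))
    if metric == "weighted-euclidean":
        w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
        if w.shape != x.shape:
            raise InputError("weights must match the vector length")
        return float(np.sqrt(np.sum(w * (x - y) ** 2)))
    raise ConfigurationError(f"unknown distance metric {metric!r}")


def squared_inverse_weights(distances: np.ndarray) -> np.ndarray:
    """kNN vote weights proportional to 1/d^2; exact matches take all votes."""
    d = np.atleast_2d(np.asarray(distances, dtype=float))
    with np.errstate(divide="ignore"):
        w = 1.0 / d**2
    exact = np.isinf(w)
    rows = exact.any(axis=1)
    w[rows] = exact[rows].astype(float)
    return w.reshape(np.shape(distances))


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the nine canonical configurations (name determines everything)."""

    name: str
    seed: int = 0
    hidden_layer_sizes: tuple[int, ...] = (10, 10, 10)
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ConfigurationError(
                f"unknown classifier {self.name!r}; expected one of {CLASSIFIER_NAMES}"
            )


def canonical_specs(seed: int = 0) -> tuple[ClassifierSpec, ...]:
    return tuple(ClassifierSpec(name=n, seed=seed) for n in CLASSIFIER_NAMES)


def instantiate_classifier(spec: ClassifierSpec | str, seed: int | None = None) -> Pipeline:
    """Build the sklearn estimator for a spec (train/predict contract)."""
    if isinstance(spec, str):
        spec = ClassifierSpec(name=spec, seed=seed or 0)
    name = spec.name
    if name == "DTf":
        # a tree with k splits has k + 1 leaves
        model = DecisionTreeClassifier(
            criterion="gini", max_leaf_nodes=101, random_state=spec.seed
        )
    elif name in ("SVMl", "SVMq", "SVMc"):
        degree = {"SVMl": 1, "SVMq": 2, "SVMc": 3}[name]
        kernel = "linear" if degree == 1 else "poly"
        model = SVC(
            kernel=kernel,
            degree=degree,
            C=1.0,
            gamma=1.0,  # fixed kernel scale (auto mode off)
            coef0=1.0,
            random_state=spec.seed,
        )
    elif name == "kNNf":
        model = KNeighborsClassifier(n_neighbors=1, metric="euclidean")
    elif name == "kNNco":
        model = KNeighborsClassifier(n_neighbors=10, metric="cosine")
    elif name == "kNNcu":
        model = KNeighborsClassifier(n_neighbors=10, metric="minkowski", p=3)
    elif name == "kNNw":
        model = KNeighborsClassifier(
            n_neighbors=10, metric="euclidean", weights=squared_inverse_weights
        )
    elif name == "ANN":
        model = MLPClassifier(
            hidden_layer_sizes=spec.hidden_layer_sizes,
            solver="lbfgs",
            max_iter=1000,
            random_state=spec.seed,
        )
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ConfigurationError(f"unknown classifier {name!r}")

    steps = ([("scale", StandardScaler())] if spec.standardize else []) + [
        ("model", model)
    ]
    return Pipeline(steps)


@dataclass
class ResultRecord:
    """Averaged cross-validated confusion matrix of one classifier-dataset."""

    athlete_id: str
    classifier: str
    segment: str
    combo: str
    cm: np.ndarray  # (3, 3), rows = true condition in CONDITIONS order

    @property
    def name(self) -> str:
        return f"{self.classifier}{self.combo}{self.segment}"


def cross_validate(
    spec: ClassifierSpec | str,
    dataset_rep1: FeatureMatrix,
    dataset_rep2: FeatureMatrix,
    labels: tuple[str, ...] = CONDITIONS,
) -> np.ndarray:
    """Two folds (train rep1 -> test rep2, and vice versa); averaged 3x3 CM."""
    if isinstance(spec, str):
        spec = ClassifierSpec(name=spec)
    if dataset_rep1.feature_names != dataset_rep2.feature_names:
        raise InputError("the two repetitions carry different feature schemas")
    observed = set(dataset_rep1.y) | set(dataset_rep2.y)
    matrices = []
    for train, test in ((dataset_rep1, dataset_rep2), (dataset_rep2, dataset_rep1)):
        missing = observed - set(train.y)
        if missing:
            raise InsufficientDataError(
                f"training fold lacks condition(s) {sorted(missing)}"
            )
        model = instantiate_classifier(spec)
        model.fit(train.X, train.y)
        predicted = model.predict(test.X)
        matrices.append(
            _sk_confusion_matrix(test.y, predicted, labels=list(labels)).astype(float)
        )
    return (matrices[0] + matrices[1]) / 2.0


def run_bank(
    datasets_rep1: dict[tuple[str, str], FeatureMatrix],
    datasets_rep2: dict[tuple[str, str], FeatureMatrix],
    athlete_id: str,
    seed: int = 0,
    specs: tuple[ClassifierSpec, ...] | None = None,
) -> list[ResultRecord]:
    """All classifier x dataset combinations of one athlete (108 by default)."""
    if specs is None:
        specs = canonical_specs(seed=seed)
    keys = sorted(datasets_rep1)
    if sorted(datasets_rep2) != keys:
        raise InputError("the two repetitions expose different dataset keys")
    records: list[ResultRecord] = []
    for key in keys:
        if key not in datasets_rep2:
            raise InputError(f"missing dataset {key!r} in repetition 2")
        segment, combo = key
        for spec in specs:
            cm = cross_validate(spec, datasets_rep1[key], datasets_rep2[key])
            records.append(
                ResultRecord(
                    athlete_id=athlete_id,
                    classifier=spec.name,
                    segment=segment,
                    combo=combo,
                    cm=cm,
                )
            )
    return records
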