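"""Cost-sensitive individual and ensemble classifiers.

The positive class is FoG.  Misclassification cost is a 2x2 matrix with
zero diagonal: ``C_NG`` (cost of calling normal gait FoG, fixed at 1)
and ``C_FoG`` (cost of missing a freeze, typically 1-3).  Costs enter
uniformly through the Bayes rule with cost-adjusted priors: multiplying
each class prior by the cost of missing that class and renormalising is
equivalent to predicting FoG whenever the posterior satisfies

    p(FoG | x) >= C_NG / (C_NG + C_FoG).

Implementing cost this way — as a posterior-threshold shift applied
after fitting — keeps the semantics identical across learner kinds and
makes sensitivity provably non-decreasing in ``C_FoG`` for a fixed
fitted model.

Learner menu:

* individual: RBF-SVM (probability-calibrated), kNN (k=5, distance
  weighted), MLP (one hidden layer of 32 units, early stopping);
* ClsfBagging: heterogeneous bagging over {SVM, kNN, MLP}, one
  bootstrap per member, hard majority vote with cost-directed tie-break;
* ClsfBoost: AdaBoost-style reweighting cycling through the member
  kinds (weighted resampling, since kNN/MLP take no sample weights);
* tree ensembles: AdaBoost, TreeBagger (bagged trees, all features per
  split) and RandomForest (sqrt-features per split).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.feature_selection import VarianceThreshold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .sample_builder import SampleSet

__all__ = [
    "CostSpec",
    "BaseLearnerSpec",
    "TrainedModel",
    "adjust_priors",
    "train_individual",
    "train_clsf_bagging",
    "train_clsf_boost",
    "train_tree_ensembles",
    "train_classifier",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = (
    "svm",
    "knn",
    "mlp",
    "clsf_bagging",
    "clsf_boost",
    "adaboost",
    "treebagger",
    "randomforest",
)

INDIVIDUAL_KINDS = ("svm", "knn", "mlp")


@dataclass(frozen=True)
class CostSpec:
    """Misclassification costs; diagonal (correct decisions) is zero."""

    c_fog: float = 1.0
    c_ng: float = 1.0

    def __post_init__(self) -> None:
        if not (self.c_fog >= self.c_ng >= 1.0):
            raise ValueError("costs must satisfy c_fog >= c_ng >= 1")

    @property
    def matrix(self) -> np.ndarray:
        """Rows = predicted class, columns = true class, order (NG, FoG)."""
        return np.array([[0.0, self.c_fog], [self.c_ng, 0.0]])

    @property
    def threshold(self) -> float:
        """Posterior p(FoG) at or above which FoG is predicted."""
        return self.c_ng / (self.c_ng + self.c_fog)


@dataclass(frozen=True)
class BaseLearnerSpec:
    kind: str = "svm"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in (*INDIVIDUAL_KINDS, "tree"):
            raise ValueError(f"unknown learner kind {self.kind!r}")


def adjust_priors(priors: np.ndarray, cost: CostSpec) -> np.ndarray:
    """Cost-adjusted, renormalised class priors, order (NG, FoG).

    Each prior is multiplied by the cost of misclassifying that class
    (NG by ``c_ng``, FoG by ``c_fog``) and the pair renormalised; equal
    costs leave the priors unchanged.
    """
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (2,) or np.any(priors <= 0) or abs(priors.sum() - 1) > 1e-9:
        raise ValueError("priors must be two positive values summing to 1")
    adjusted = priors * np.array([cost.c_ng, cost.c_fog])
    return adjusted / adjusted.sum()


def _make_estimator(spec: BaseLearnerSpec, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.kind == "svm":
        est = SVC(kernel="rbf", probability=True, random_state=seed, **hp)
    elif spec.kind == "knn":
        est = KNeighborsClassifier(**{"n_neighbors": 5, "weights": "distance", **hp})
    elif spec.kind == "mlp":
        est = MLPClassifier(
            **{
                "hidden_layer_sizes": (32,),
                "max_iter": 400,        # loss-plateau stopping via tol
                "n_iter_no_change": 20,
                "random_state": seed,
                **hp,
            }
        )
    elif spec.kind == "tree":
        raise ValueError("use train_tree_ensembles for tree-based learners")
    else:  # pragma: no cover - guarded by BaseLearnerSpec
        raise ValueError(spec.kind)
    return Pipeline(
        [
            ("drop_constant", VarianceThreshold(threshold=0.0)),
            ("scale", StandardScaler()),
            ("clf", est),
        ]
    )


def _check_train(train: SampleSet) -> None:
    if train.n_fog == 0 or train.n_ng == 0:
        raise ValueError("training set must contain both classes")


def _warn_constant_columns(X: np.ndarray) -> None:
    n_const = int(np.count_nonzero(np.ptp(X, axis=0) == 0))
    if n_const:
        warnings.warn(f"dropping {n_const} constant feature column(s)", stacklevel=3)


def _proba_fog(pipe, X: np.ndarray) -> np.ndarray:
    proba = pipe.predict_proba(X)
    classes = list(pipe.classes_)
    return proba[:, classes.index(1)] if 1 in classes else np.zeros(len(X))


@dataclass
class TrainedModel:
    """A fitted classifier plus its cost-threshold decision rule.

    ``members`` holds ``(kind, fitted pipeline, vote weight)`` triples;
    individual models have a single member.  Prediction is a pure
    function of the input: probabilities (or votes) are combined and the
    cost threshold applied.
    """

    kind: str
    cost: CostSpec
    members: list[tuple[str, object, float]]
    vote: str = "single"        # single | majority | weighted | soft

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean member probability of FoG (soft score in [0, 1])."""
        X = np.asarray(X, dtype=float)
        return np.mean([_proba_fog(pipe, X) for _, pipe, _ in self.members], axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary FoG predictions under the cost-adjusted decision rule."""
        X = np.asarray(X, dtype=float)
        thr = self.cost.threshold
        if self.vote in ("single", "soft"):
            return (self.predict_proba(X) >= thr).astype(np.int8)
        member_votes = np.array(
            [(_proba_fog(pipe, X) >= thr).astype(int) for _, pipe, _ in self.members]
        )
        weights = np.array([w for _, _, w in self.members])[:, None]
        score = (member_votes * weights).sum(axis=0) / weights.sum()
        fog_on_tie = self.cost.c_fog > self.cost.c_ng
        out = np.where(score > 0.5, 1, np.where(score < 0.5, 0, int(fog_on_tie)))
        return out.astype(np.int8)


def train_individual(
    train: SampleSet,
    spec: BaseLearnerSpec,
    cost: CostSpec = CostSpec(),
    seed: int = 0,
) -> TrainedModel:
    """Fit a single cost-sensitive classifier (SVM, kNN or MLP).

    Feature standardisation is fit on the training set only; constant
    columns are dropped with a warning.  The cost enters as the
    posterior threshold of :func:`adjust_priors`.
    """
    _check_train(train)
    _warn_constant_columns(train.X)
    pipe = _make_estimator(spec, seed)
    pipe.fit(train.X, train.y)
    return TrainedModel(kind=spec.kind, cost=cost, members=[(spec.kind, pipe, 1.0)])


def _bootstrap_both_classes(
    rng: np.random.Generator, y: np.ndarray, max_retries: int = 100
) -> np.ndarray:
    n = len(y)
    for _ in range(max_retries):
        idx = rng.integers(n, size=n)
        if len(np.unique(y[idx])) == 2:
            return idx
    raise RuntimeError("could not draw a bootstrap resample containing both classes")


def train_clsf_bagging(
    train: SampleSet,
    members: list[BaseLearnerSpec] | None = None,
    n_bags: int = 3,
    cost: CostSpec = CostSpec(),
    seed: int = 0,
    soft_vote: bool = False,
) -> TrainedModel:
    """Heterogeneous bagging over SVM, kNN and MLP.

    Each member is fit on an independent bootstrap resample; members are
    assigned round-robin from ``members`` when ``n_bags`` exceeds the
    number of kinds.  Prediction is a hard majority vote of the members'
    cost-thresholded decisions, ties broken toward FoG when
    ``c_fog > c_ng`` (soft average-probability voting behind a flag).
    """
    if members is None:
        members = [BaseLearnerSpec(kind=k) for k in INDIVIDUAL_KINDS]
    if n_bags < len(members):
        raise ValueError("n_bags must be at least the number of member kinds")
    _check_train(train)
    _warn_constant_columns(train.X)
    rng = np.random.default_rng(seed)
    fitted = []
    for b in range(n_bags):
        spec = members[b % len(members)]
        idx = _bootstrap_both_classes(rng, train.y)
        pipe = _make_estimator(spec, seed=int(rng.integers(2**31)))
        pipe.fit(train.X[idx], train.y[idx])
        fitted.append((spec.kind, pipe, 1.0))
    return TrainedModel(
        kind="clsf_bagging",
        cost=cost,
        members=fitted,
        vote="soft" if soft_vote else "majority",
    )


def train_clsf_boost(
    train: SampleSet,
    members: list[BaseLearnerSpec] | None = None,
    rounds: int = 3,
    cost: CostSpec = CostSpec(),
    seed: int = 0,
) -> TrainedModel:
    """AdaBoost-style heterogeneous boosting cycling through member kinds.

    kNN and MLP accept no per-sample weights, so each round fits its
    member on a weighted resample of the training set, then reweights
    the distribution by the member's weighted training error.  A round
    with weighted error >= 0.5 stops boosting early, keeping the rounds
    already fitted; the vote is alpha-weighted.
    """
    if members is None:
        members = [BaseLearnerSpec(kind=k) for k in INDIVIDUAL_KINDS]
    _check_train(train)
    _warn_constant_columns(train.X)
    rng = np.random.default_rng(seed)
    n = len(train)
    w = np.full(n, 1.0 / n)
    fitted: list[tuple[str, object, float]] = []
    thr = cost.threshold
    for rd in range(rounds):
        spec = members[rd % len(members)]
        if rd == 0:
            idx = np.arange(n)  # single round == the individual member
        else:
            idx = rng.choice(n, size=n, p=w)
            if len(np.unique(train.y[idx])) < 2:
                idx = _bootstrap_both_classes(rng, train.y)
        pipe = _make_estimator(spec, seed=int(rng.integers(2**31)))
        pipe.fit(train.X[idx], train.y[idx])
        pred = (_proba_fog(pipe, train.X) >= thr).astype(np.int8)
        err = float(w[pred != train.y].sum())
        if err >= 0.5:
            if not fitted:  # keep at least the first member, with nominal weight
                fitted.append((spec.kind, pipe, 1.0))
            break
        err = max(err, 1e-10)
        alpha = 0.5 * math.log((1 - err) / err)
        fitted.append((spec.kind, pipe, alpha))
        mistakes = pred != train.y
        w = w * np.exp(np.where(mistakes, alpha, -alpha))
        w = w / w.sum()
    return TrainedModel(kind="clsf_boost", cost=cost, members=fitted, vote="weighted")


def train_tree_ensembles(
    train: SampleSet,
    variant: str,
    cost: CostSpec = CostSpec(),
    seed: int = 0,
    n_estimators: int = 100,
) -> TrainedModel:
    """Standard tree ensembles with the same cost-threshold contract.

    ``treebagger`` and ``randomforest`` differ only in per-split feature
    subsampling (all features vs sqrt); ``adaboost`` is SAMME over
    shallow trees.
    """
    _check_train(train)
    if variant == "adaboost":
        est = AdaBoostClassifier(n_estimators=n_estimators, random_state=seed)
    elif variant == "treebagger":
        est = RandomForestClassifier(
            n_estimators=n_estimators, max_features=None, random_state=seed
        )
    elif variant == "randomforest":
        est = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt", random_state=seed
        )
    else:
        raise ValueError(f"unknown tree-ensemble variant {variant!r}")
    pipe = Pipeline(
        [("drop_constant", VarianceThreshold(threshold=0.0)), ("clf", est)]
    )
    pipe.fit(train.X, train.y)
    return TrainedModel(kind=variant, cost=cost, members=[(variant, pipe, 1.0)])


def train_classifier(
    name: str,
    train: SampleSet,
    cost: CostSpec = CostSpec(),
    seed: int = 0,
    **kwargs,
) -> TrainedModel:
    """Dispatch on a classifier name from :data:`CLASSIFIER_NAMES`."""
    if name in INDIVIDUAL_KINDS:
        return train_individual(train, BaseLearnerSpec(kind=name), cost, seed)
    if name == "clsf_bagging":
        return train_clsf_bagging(train, cost=cost, seed=seed, **kwargs)
    if name == "clsf_boost":
        return train_clsf_boost(train, cost=cost, seed=seed, **kwargs)
    if name in ("adaboost", "treebagger", "randomforest"):
        return train_tree_ensembles(train, name, cost, seed, **kwargs)
    raise ValueError(f"unknown classifier {name!r}")
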