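"""Binary risk classifiers over CSLV features, scikit-learn style.

Four base families (gradient boosting, feedforward net, logistic
regression, random forest) are built through :func:`make_classifier`; the
package's own contribution is :class:`SuperLearnerClassifier`, a stacked
ensemble whose logistic meta-learner is fit strictly on out-of-fold base
predictions — the super-learner construction. Evaluation follows the
repeated-split protocol: independent stratified train/test splits, a
pair-counting AUC per repeat, and a one-sample t-interval over the repeat
AUCs (with a Shapiro-Wilk normality check reported, not enforced).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lightgbm
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.multiclass import check_classification_targets
from sklearn.utils.validation import check_is_fitted, validate_data

from cslv.cohort import LabeledDataset, SplitPlan, make_splits

__all__ = [
    "FAMILY_ALIASES",
    "AlgorithmSpec",
    "ModelEvaluation",
    "SuperLearnerClassifier",
    "make_classifier",
    "auc",
    "t_interval",
    "evaluate_repeated",
]

FAMILY_ALIASES = {
    "gbm": "gradient_boosting",
    "dnn": "feedforward_net",
    "glm": "logistic",
    "drf": "random_forest",
    "stack": "stacked_ensemble",
}

_FAMILIES = (
    "gradient_boosting",
    "feedforward_net",
    "logistic",
    "random_forest",
    "stacked_ensemble",
)


class QuietLGBMClassifier(lightgbm.LGBMClassifier):
    """LGBMClassifier that scores plain arrays without feature-name warnings.

    lightgbm >= 4.6 records synthetic feature names even when fit on a
    plain array and then warns on every plain-array predict; only that
    warning is silenced.
    """

    def predict(self, X, **kwargs):
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="X does not have valid feature names")
            return super().predict(X, **kwargs)

    def predict_proba(self, X, **kwargs):
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="X does not have valid feature names")
            return super().predict_proba(X, **kwargs)


def make_classifier(family: str, seed: int = 0, **hyperparameters):
    """Build a classifier of the given family with sensible defaults.

    ``hyperparameters`` override the defaults of the underlying estimator.
    Scale-sensitive families (net, logistic) are wrapped in a pipeline with
    standardization; tree families are left unscaled so that TreeSHAP
    contributions stay in raw feature units.
    """
    family = FAMILY_ALIASES.get(family, family)
    if family == "gradient_boosting":
        params = dict(
            n_estimators=200,
            learning_rate=0.05,
            num_leaves=15,
            min_child_samples=20,
            colsample_bytree=0.8,
            random_state=seed,
            n_jobs=1,
            verbose=-1,
        )
        params.update(hyperparameters)
        return QuietLGBMClassifier(**params)
    if family == "feedforward_net":
        params = dict(
            hidden_layer_sizes=(32, 32),
            activation="relu",
            early_stopping=True,
            validation_fraction=0.1,
            max_iter=300,
            random_state=seed,
        )
        params.update(hyperparameters)
        return Pipeline([("scale", StandardScaler()), ("net", MLPClassifier(**params))])
    if family == "logistic":
        params = dict(max_iter=2000)
        params.update(hyperparameters)
        return Pipeline([("scale", StandardScaler()), ("glm", LogisticRegression(**params))])
    if family == "random_forest":
        params = dict(n_estimators=300, min_samples_leaf=3, random_state=seed, n_jobs=1)
        params.update(hyperparameters)
        return RandomForestClassifier(**params)
    if family == "stacked_ensemble":
        return SuperLearnerClassifier(random_state=seed, **hyperparameters)
    raise ValueError(f"unknown family {family!r}; expected one of {_FAMILIES}")


@dataclass(frozen=True)
class AlgorithmSpec:
    """Declarative description of a classifier to train."""

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    base_families: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        family = FAMILY_ALIASES.get(self.family, self.family)
        if family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if family == "stacked_ensemble":
            bases = self.base_families or SuperLearnerClassifier._default_bases
            if len(bases) < 2:
                raise ValueError("a stacked ensemble needs >= 2 base families")

    def build(self):
        kwargs = dict(self.hyperparameters)
        if FAMILY_ALIASES.get(self.family, self.family) == "stacked_ensemble" and self.base_families:
            kwargs.setdefault("base_families", tuple(self.base_families))
        return make_classifier(self.family, seed=self.seed, **kwargs)


class SuperLearnerClassifier(ClassifierMixin, BaseEstimator):
    """Stacked ensemble: logistic meta-learner on out-of-fold base scores.

    For each of ``fold_count`` stratified folds, every base family is fit
    on the training part and predicts the held-out part; the meta-learner
    is fit on the resulting out-of-fold probability matrix and therefore
    never sees in-fold base predictions (the guard against stacking
    leakage). Base estimators are then refit on the full data for scoring
    new samples. A fold whose training part is single-class triggers a
    reshuffle with a new derived seed, at most ``max_refold`` times.

    Parameters
    ----------
    base_families : families passed to :func:`make_classifier`; >= 2.
    base_params : optional per-family hyperparameter overrides.
    fold_count : folds for the out-of-fold construction.
    random_state : master seed for folds and base estimators.

    Attributes
    ----------
    classes_ : class labels.
    base_estimators_ : base estimators refit on the full training data.
    meta_estimator_ : fitted logistic meta-learner.
    oof_predictions_ : (n_samples, n_base) out-of-fold probability matrix.
    fold_indices_ : the (train, val) index pairs actually used.
    """

    _default_bases = ("gradient_boosting", "logistic")

    def __init__(
        self,
        base_families: Sequence[str] = _default_bases,
        base_params: Mapping[str, Mapping[str, object]] | None = None,
        fold_count: int = 5,
        max_refold: int = 5,
        random_state: int | None = None,
    ):
        self.base_families = base_families
        self.base_params = base_params
        self.fold_count = fold_count
        self.max_refold = max_refold
        self.random_state = random_state

    def _make_bases(self, seeds: Sequence[int]):
        params = self.base_params or {}
        return [
            make_classifier(fam, seed=int(seed), **dict(params.get(fam, {})))
            for fam, seed in zip(self.base_families, seeds)
        ]

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        check_classification_targets(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("SuperLearnerClassifier requires exactly 2 classes")
        if len(self.base_families) < 2:
            raise ValueError("need at least 2 base families to stack")
        if X.shape[1] and np.all(np.ptp(X, axis=0) == 0):
            warnings.warn("all features have zero variance; the model can only learn the base rate")

        seed_seq = np.random.SeedSequence(
            self.random_state if self.random_state is not None else 0
        )
        state = seed_seq.generate_state(2 + len(self.base_families) + self.max_refold,
                                        dtype=np.uint32)
        base_seeds = [int(s) % (2**31) for s in state[2 : 2 + len(self.base_families)]]
        fold_seeds = [int(s) % (2**31) for s in
                      np.concatenate([state[:1], state[2 + len(self.base_families):]])]

        folds = None
        for attempt, fold_seed in enumerate(fold_seeds):
            candidate = list(
                StratifiedKFold(
                    n_splits=self.fold_count, shuffle=True, random_state=fold_seed
                ).split(X, y_enc)
            )
            if all(len(np.unique(y_enc[tr])) == 2 for tr, _ in candidate):
                folds = candidate
                break
        if folds is None:
            raise ValueError("could not build folds with both classes in every training part")

        oof = np.zeros((len(y_enc), len(self.base_families)))
        templates = self._make_bases(base_seeds)
        for train_idx, val_idx in folds:
            for j, template in enumerate(templates):
                model = clone(template)
                model.fit(X[train_idx], y_enc[train_idx])
                oof[val_idx, j] = model.predict_proba(X[val_idx])[:, 1]

        self.meta_estimator_ = LogisticRegression(max_iter=2000)
        self.meta_estimator_.fit(oof, y_enc)
        self.base_estimators_ = []
        for template in templates:
            model = clone(template)
            model.fit(X, y_enc)
            self.base_estimators_.append(model)
        self.oof_predictions_ = oof
        self.fold_indices_ = folds
        self.base_seeds_ = base_seeds
        return self

    def _base_matrix(self, X) -> np.ndarray:
        return np.column_stack(
            [m.predict_proba(X)[:, 1] for m in self.base_estimators_]
        )

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.meta_estimator_.predict_proba(self._base_matrix(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.classifier_tags.multi_class = False
        return tags


def auc(scores, labels) -> float:
    """Pair-counting (Mann-Whitney) AUC; ties credited 0.5.

    Equals the probability that a uniformly chosen case outscores a
    uniformly chosen control, with ties counted half. Computed from rank
    sums, which is algebraically the normalized U statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    positive = labels == np.max(labels)
    n_pos = int(positive.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0 or len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)  # average ranks: ties get half credit
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def t_interval(values, confidence: float = 0.95) -> tuple[float, float]:
    """One-sample t confidence interval: mean +/- t_{1-a/2, n-1} * s / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a t-interval")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(values.size))
    if sem == 0.0:
        return mean, mean
    half = float(stats.t.ppf((1 + confidence) / 2, values.size - 1)) * sem
    return mean - half, mean + half


@dataclass
class ModelEvaluation:
    """Repeated-split evaluation summary.

    ``aucs`` holds one held-out AUC per successful repeat; the 95% CI is a
    one-sample t-interval over them, and ``shapiro_p`` reports the
    Shapiro-Wilk normality p-value of the repeat AUCs (a warning, never a
    failure, when < 0.05).
    """

    aucs: list[float]
    mean_auc: float
    ci_low: float
    ci_high: float
    shapiro_p: float
    fold_count: int
    repeats: int
    failures: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_auc <= self.ci_high):
            raise ValueError("CI must contain the mean")
        if any(not 0 <= a <= 1 for a in self.aucs):
            raise ValueError("AUCs must lie in [0, 1]")


def evaluate_repeated(
    dataset: LabeledDataset,
    spec: AlgorithmSpec | BaseEstimator,
    plan: SplitPlan,
) -> ModelEvaluation:
    """Train/score over repeated stratified splits and summarize the AUCs.

    Each repeat refits a fresh clone of the estimator (seeded from the
    plan) on its training part and scores its held-out part. Repeats that
    raise are recorded and skipped; at least two must succeed.
    """
    X = dataset.features.to_numpy()
    y = dataset.labels.to_numpy()
    splits = make_splits(dataset, plan)
    repeat_seeds = plan.repeat_seeds()

    aucs: list[float] = []
    failures: list[str] = []
    for r, (train_idx, test_idx) in enumerate(splits):
        if isinstance(spec, AlgorithmSpec):
            estimator = AlgorithmSpec(
                spec.family, spec.hyperparameters, spec.base_families, seed=repeat_seeds[r]
            ).build()
        else:
            estimator = clone(spec)
            if "random_state" in estimator.get_params():
                estimator.set_params(random_state=repeat_seeds[r])
        try:
            estimator.fit(X[train_idx], y[train_idx])
            test_scores = estimator.predict_proba(X[test_idx])[:, 1]
            aucs.append(auc(test_scores, y[test_idx]))
        except Exception as exc:  # noqa: BLE001 - repeat failures are recorded
            failures.append(f"repeat {r}: {exc!r}")
    if len(aucs) < 2:
        raise RuntimeError(f"fewer than 2 repeats succeeded: {failures}")

    ci_low, ci_high = t_interval(aucs)
    arr = np.asarray(aucs)
    if np.ptp(arr) == 0:
        shapiro_p = float("nan")  # Shapiro undefined on a constant sample
    else:
        shapiro_p = float(stats.shapiro(arr).pvalue)
        if shapiro_p < 0.05:
            warnings.warn(
                f"repeat AUCs fail the Shapiro-Wilk normality check (p={shapiro_p:.3g}); "
                "the t-interval may be approximate"
            )
    return ModelEvaluation(
        aucs=aucs,
        mean_auc=float(arr.mean()),
        ci_low=ci_low,
        ci_high=ci_high,
        shapiro_p=shapiro_p,
        fold_count=plan.fold_count,
        repeats=plan.repeats,
        failures=failures,
    )
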