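"""Classifier grid, repeated stratified cross-validation and consensus.

Seven classical algorithms (RBF-SVM, k-NN, random forest, naive Bayes,
MLP, AdaBoost, XGBoost) are crossed with feature representations — every
single block plus every descriptor x fingerprint pair — and with small
hyperparameter grids. Each candidate is scored by 10x-repeated stratified
5-fold cross-validation; within every fold the preprocessor is fit on the
fold-training portion only and SMOTE is applied to the fold-training rows
only, so the held-out estimates are leakage-free. Finalists are refit on
the full training set and validated externally; a consensus prediction is
the plain average of aligned score vectors.

The classifiers themselves come from scikit-learn/xgboost through a thin
fit/score adapter; the substance here is the harness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import RepeatedStratifiedKFold

from .evaluation import (
    MetricSet,
    auc_score,
    classification_metrics,
    confusion_from_predictions,
)
from .featurization import FeatureBlock, combine_blocks
from .preprocessing import apply_preprocessor, fit_preprocessor
from .resampling import SmoteConfig, smote_oversample

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "GridError",
    "DEFAULT_GRIDS",
    "ALGORITHMS",
    "build_grid",
    "run_repeated_cv",
    "select_top",
    "fit_and_predict_external",
    "consensus_predict",
]


class GridError(ValueError):
    pass


ALGORITHMS = (
    "svm_rbf", "knn", "random_forest", "naive_bayes", "ann", "adaboost",
    "xgboost",
)

# Small per-algorithm grids; RF depth is fixed at 4, the MLP uses the
# stochastic-gradient solver, NB runs at library defaults. All overridable.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm_rbf": {"C": [0.1, 1, 10, 100]},
    "knn": {"n_neighbors": [1, 3, 5, 7, 9]},
    "random_forest": {
        "n_estimators": [50, 100, 200, 500],
        "max_features": ["sqrt", "log2"],
    },
    "naive_bayes": {},
    "ann": {"hidden_layer_sizes": [50, 100, 200]},
    "adaboost": {"n_estimators": [50, 100, 200, 500]},
    "xgboost": {"max_depth": [3, 4, 5, 6], "min_child_weight": [1, 3, 5]},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One algorithm at one hyperparameter setting."""

    algorithm: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise GridError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )

    @property
    def label(self) -> str:
        p = ",".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return f"{self.algorithm}({p})"

    def __hash__(self) -> int:
        return hash((self.algorithm, tuple(sorted(self.params.items())), self.seed))


def make_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn/xgboost estimator behind a spec."""
    p = spec.params
    if spec.algorithm == "svm_rbf":
        from sklearn.svm import SVC

        return SVC(kernel="rbf", C=p.get("C", 1.0), probability=True,
                   random_state=spec.seed)
    if spec.algorithm == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(
            n_neighbors=p.get("n_neighbors", 5), metric="euclidean"
        )
    if spec.algorithm == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100),
            max_features=p.get("max_features", "sqrt"),
            max_depth=4,
            random_state=spec.seed,
        )
    if spec.algorithm == "naive_bayes":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB()
    if spec.algorithm == "ann":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(
            solver="sgd",
            hidden_layer_sizes=(p.get("hidden_layer_sizes", 100),),
            max_iter=500,
            random_state=spec.seed,
        )
    if spec.algorithm == "adaboost":
        from sklearn.ensemble import AdaBoostClassifier

        return AdaBoostClassifier(
            n_estimators=p.get("n_estimators", 100), random_state=spec.seed
        )
    if spec.algorithm == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            max_depth=p.get("max_depth", 4),
            min_child_weight=p.get("min_child_weight", 1),
            n_estimators=p.get("n_estimators", 100),
            random_state=spec.seed,
            eval_metric="logloss",
            verbosity=0,
            n_jobs=1,
        )
    raise GridError(f"unknown algorithm {spec.algorithm!r}")


def enumerate_representations(
    blocks: dict[str, FeatureBlock]
) -> list[tuple[str, ...]]:
    """Every single block plus every descriptor x fingerprint pair.

    Descriptor blocks are the continuous ones, fingerprints the binary
    ones; pairs are ordered (descriptor, fingerprint)."""
    descriptors = [n for n, b in blocks.items() if b.kind == "continuous"]
    fingerprints = [n for n, b in blocks.items() if b.kind == "binary"]
    singles = [(n,) for n in blocks]
    pairs = [(d, f) for d in descriptors for f in fingerprints]
    return singles + pairs


def build_grid(config: dict) -> list[tuple[ClassifierSpec, tuple[str, ...]]]:
    """Cartesian product of algorithms x representations x grid settings.

    ``config`` keys: ``algorithms`` (list of names), either ``blocks``
    (name -> FeatureBlock, auto-enumerated) or ``representations``
    (explicit list of block-name tuples), optional ``grids`` overriding
    :data:`DEFAULT_GRIDS` per algorithm, and ``seed``.
    """
    algorithms = config.get("algorithms", list(ALGORITHMS))
    if not algorithms:
        raise GridError("algorithm list must be non-empty")
    for a in algorithms:
        if a not in ALGORITHMS:
            raise GridError(f"unknown algorithm {a!r}")

    if "representations" in config:
        reps = [tuple(r) for r in config["representations"]]
    elif "blocks" in config:
        reps = enumerate_representations(config["blocks"])
    else:
        raise GridError("config needs 'blocks' or 'representations'")
    if "blocks" in config:
        known = set(config["blocks"])
        for rep in reps:
            unknown = [n for n in rep if n not in known]
            if unknown:
                raise GridError(f"unknown block name(s) {unknown} in {rep}")

    grids = dict(DEFAULT_GRIDS)
    grids.update(config.get("grids", {}))
    seed = config.get("seed", 0)

    out: list[tuple[ClassifierSpec, tuple[str, ...]]] = []
    for algo in algorithms:
        grid = grids.get(algo, {})
        keys = sorted(grid)
        settings = (
            [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]
            if keys else [{}]
        )
        for rep in reps:
            for params in settings:
                out.append((ClassifierSpec(algo, params, seed), rep))
    return out


@dataclass
class CVResult:
    """Fold-level metrics of one model under repeated stratified CV."""

    spec: ClassifierSpec
    feature_combo: tuple[str, ...]
    fold_metrics: list[MetricSet]
    folds: int
    repeats: int

    @property
    def label(self) -> str:
        return f"{self.spec.label} @ {'+'.join(self.feature_combo)}"

    def _values(self, metric: str) -> np.ndarray:
        return np.array([getattr(m, metric) for m in self.fold_metrics], dtype=float)

    def mean(self, metric: str) -> float:
        return float(self._values(metric).mean())

    def sd(self, metric: str) -> float:
        return float(self._values(metric).std(ddof=1))

    def summary(self) -> dict:
        out: dict = {"model": self.label}
        for m in ("SE", "SP", "ACC", "MCC", "AUC"):
            out[f"{m}_mean"] = self.mean(m)
            out[f"{m}_sd"] = self.sd(m)
        return out


def _prepare_fold(
    block: FeatureBlock,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray | None,
    spec_seed: int,
    smote_cfg: SmoteConfig | None,
    preprocess_state=None,
):
    """Preprocess (fit on training rows unless a pre-fit state is given),
    then SMOTE the training portion. Returns (X_train, y_train, X_test)."""
    train_block = block.subset_rows(train_idx)
    state = preprocess_state or fit_preprocessor(train_block)
    X_train = apply_preprocessor(state, train_block).matrix
    y_train = y[train_idx]
    X_test = None
    if test_idx is not None:
        X_test = apply_preprocessor(state, block.subset_rows(test_idx)).matrix
    if smote_cfg is not None:
        X_train, y_train = smote_oversample(X_train, y_train, smote_cfg)
    return X_train, y_train, X_test


def run_repeated_cv(
    y,
    blocks: dict[str, FeatureBlock],
    combo: tuple[str, ...],
    spec: ClassifierSpec,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    smote: bool = True,
    smote_cfg: SmoteConfig | None = None,
    refit_per_fold: bool = True,
) -> CVResult:
    """Repeated stratified k-fold CV of one (spec, representation) pair.

    ``refit_per_fold=False`` is a compatibility mode that fits the
    preprocessor once on all rows instead of per fold (some published
    workflows are ambiguous about this); the default refits per fold.
    """
    y = np.asarray(y).astype(int)
    block = combine_blocks([blocks[name] for name in combo])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < folds:
        raise GridError(
            f"every class needs at least {folds} members for {folds}-fold CV"
        )
    base_state = None if refit_per_fold else fit_preprocessor(block)
    cfg = smote_cfg or SmoteConfig(seed=seed)
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    fold_metrics: list[MetricSet] = []
    for train_idx, test_idx in splitter.split(block.matrix, y):
        X_train, y_train, X_test = _prepare_fold(
            block, y, train_idx, test_idx, spec.seed,
            cfg if smote else None, base_state,
        )
        est = make_estimator(spec)
        est.fit(X_train, y_train)
        scores = est.predict_proba(X_test)[:, 1]
        y_pred = (scores >= 0.5).astype(int)
        cm = confusion_from_predictions(y[test_idx], y_pred)
        ms = classification_metrics(cm)
        fold_metrics.append(
            MetricSet(
                SE=ms.SE, SP=ms.SP, ACC=ms.ACC, MCC=ms.MCC,
                AUC=auc_score(y[test_idx], scores),
                se_undefined=ms.se_undefined, sp_undefined=ms.sp_undefined,
                mcc_degenerate=ms.mcc_degenerate,
            )
        )
    return CVResult(spec, tuple(combo), fold_metrics, folds, repeats)


def select_top(results: list[CVResult], n: int = 5) -> list[CVResult]:
    """Rank by mean AUC descending; ties broken by mean MCC, then mean ACC,
    then model label. Returns the top ``n`` (or all, if fewer)."""
    if not results:
        raise GridError("no CV results to rank")
    ranked = sorted(
        results,
        key=lambda r: (-r.mean("AUC"), -r.mean("MCC"), -r.mean("ACC"), r.label),
    )
    return ranked[:n]


def fit_and_predict_external(
    y_train,
    blocks_train: dict[str, FeatureBlock],
    blocks_external: dict[str, FeatureBlock],
    combo: tuple[str, ...],
    spec: ClassifierSpec,
    smote: bool = True,
    smote_cfg: SmoteConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit once on the full training set (preprocessor + SMOTE + model)
    and score the external molecules. Returns (scores in [0,1], hard
    labels at the 0.5 threshold)."""
    y_train = np.asarray(y_train).astype(int)
    train_block = combine_blocks([blocks_train[name] for name in combo])
    ext_block = combine_blocks([blocks_external[name] for name in combo])
    state = fit_preprocessor(train_block)
    X_train = apply_preprocessor(state, train_block).matrix
    X_ext = apply_preprocessor(state, ext_block).matrix
    yt = y_train
    if smote:
        X_train, yt = smote_oversample(
            X_train, yt, smote_cfg or SmoteConfig(seed=spec.seed)
        )
    est = make_estimator(spec)
    est.fit(X_train, yt)
    scores = est.predict_proba(X_ext)[:, 1]
    return scores, (scores >= 0.5).astype(int)


def consensus_predict(score_lists: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Average >= 2 aligned score vectors per molecule; hard label at 0.5."""
    if len(score_lists) < 2:
        raise GridError("consensus needs at least two score vectors")
    lengths = {len(s) for s in score_lists}
    if len(lengths) != 1:
        raise GridError(f"misaligned score vectors of lengths {sorted(lengths)}")
    scores = np.mean(np.vstack(score_lists), axis=0)
    return scores, (scores >= 0.5).astype(int)
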