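"""Per-parcel sex classification with train-only confound adjustment.

For each parcel the feature vector is that parcel's Fisher-Z connectivity
with all other parcels.  Within each cross-validation fold, strictly on the
training subjects: (1) per-feature OLS betas for the confounds (age by
default) are fitted and used to residualize both training and held-out
features; (2) per-feature z-scoring statistics are estimated; (3) an
RBF-kernel SVM is fitted.  Hyperparameters C and gamma are tuned by an
inner cross-validation per outer fold and, for the final model, combined
as the geometric mean of the per-fold selections.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from joblib import Parallel, delayed
from scipy.spatial.distance import cdist
from sklearn import config_context
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .atlas import Atlas
from .results import AccuracyMap

__all__ = [
    "HyperParams",
    "ConfoundModel",
    "TrainedParcelModel",
    "CVResult",
    "default_grid",
    "default_hyperparams",
    "fit_confound_model",
    "apply_confound_model",
    "tune_hyperparameters",
    "cross_validated_accuracy",
    "train_final_model",
    "predict_external",
    "classify_all_parcels",
    "train_all_parcels",
    "predict_external_all",
    "parcel_features",
    "save_model",
    "load_model",
]

WHOLE_BRAIN_ID = 0


@dataclass(frozen=True)
class HyperParams:
    """RBF-SVM hyperparameters: penalty C and kernel width gamma."""

    c: float
    gamma: float

    def __post_init__(self):
        if not (np.isfinite(self.c) and self.c > 0 and np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError("C and gamma must be finite and positive")


def default_grid() -> list:
    """Log-spaced grid: C in 2^-5..2^15, gamma in 2^-15..2^3, step 2^2."""
    return [
        HyperParams(c=2.0**ec, gamma=2.0**eg)
        for ec in range(-5, 16, 2)
        for eg in range(-15, 4, 2)
    ]


def default_hyperparams(n_features: int) -> HyperParams:
    """Fixed fallback when no tuning is requested: C = 1, gamma = 1/p."""
    return HyperParams(c=1.0, gamma=1.0 / max(n_features, 1))


@dataclass
class ConfoundModel:
    """Per-feature OLS betas (intercept + one slope per confound)."""

    betas: np.ndarray  # (1 + n_confounds, n_features)
    confound_names: list

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("confound betas must be finite")


def _confound_design(confounds: np.ndarray) -> np.ndarray:
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] == 1 and confounds.shape[1] > 1:
        confounds = confounds.T
    return confounds


def fit_confound_model(
    features: np.ndarray,
    confounds: np.ndarray,
    confound_names: Optional[Sequence[str]] = None,
) -> ConfoundModel:
    """OLS of each feature on [intercept, confounds], fitted on training subjects only."""
    x = np.asarray(features, dtype=float)
    c = _confound_design(confounds)
    if x.shape[0] != c.shape[0]:
        raise ValueError("features and confounds must have equal subject counts")
    if x.shape[0] < c.shape[1] + 2:
        raise ValueError("need at least n_confounds + 2 subjects")
    names = list(confound_names) if confound_names is not None else [f"c{j}" for j in range(c.shape[1])]
    const = c.std(axis=0) == 0
    if np.any(const):
        warnings.warn(f"dropping constant confound column(s): {list(np.flatnonzero(const))}", stacklevel=2)
        c = c[:, ~const]
        names = [n for n, drop in zip(names, const) if not drop]
    design = np.column_stack([np.ones(x.shape[0]), c])
    betas, *_ = np.linalg.lstsq(design, x, rcond=None)
    return ConfoundModel(betas=betas, confound_names=names)


def apply_confound_model(model: ConfoundModel, features: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualize features with previously fitted betas (never refit)."""
    x = np.asarray(features, dtype=float)
    c = _confound_design(confounds)
    if c.shape[1] != model.betas.shape[0] - 1:
        raise ValueError("confound dimension does not match the fitted model")
    if x.shape[1] != model.betas.shape[1]:
        raise ValueError("feature dimension does not match the fitted model")
    design = np.column_stack([np.ones(x.shape[0]), c])
    return x - design @ model.betas


@dataclass
class _SvmState:
    """RBF-SVM decision state extracted from a fitted classifier.

    Prediction uses only these arrays, so a serialized model needs no
    fitted estimator object.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    classes: list

    def decision(self, x: np.ndarray) -> np.ndarray:
        k = np.exp(-self.gamma * cdist(x, self.support_vectors, "sqeuclidean"))
        return k @ self.dual_coef + self.intercept

    def predict(self, x: np.ndarray) -> np.ndarray:
        # decision > 0 -> second class; ties (exactly 0) -> first class in label order
        dec = self.decision(x)
        return np.asarray(self.classes)[(dec > 0).astype(int)]


@dataclass
class _FittedFold:
    """Training-fold artifacts: confound betas, scaler, SVM state."""

    confound_model: Optional[ConfoundModel]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    kept: np.ndarray  # indices of non-zero-variance features
    svm: _SvmState
    hyperparams: HyperParams


def _fit_on(x_tr, y_tr, conf_tr, hp: HyperParams) -> _FittedFold:
    cm = None
    if conf_tr is not None:
        cm = fit_confound_model(x_tr, conf_tr)
        x_tr = apply_confound_model(cm, x_tr, conf_tr)
    mu = x_tr.mean(axis=0)
    sd = x_tr.std(axis=0, ddof=0)
    kept = np.flatnonzero(sd > 0)
    xs = (x_tr[:, kept] - mu[kept]) / sd[kept]
    svc = SVC(C=hp.c, kernel="rbf", gamma=hp.gamma)
    with config_context(assume_finite=True, skip_parameter_validation=True):
        svc.fit(xs, y_tr)
    state = _SvmState(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        gamma=hp.gamma,
        classes=[str(c) for c in svc.classes_],
    )
    return _FittedFold(cm, mu, sd, kept, state, hp)


def _predict_with(fold: _FittedFold, x, conf) -> np.ndarray:
    if fold.confound_model is not None:
        x = apply_confound_model(fold.confound_model, x, conf)
    xs = (x[:, fold.kept] - fold.feature_mean[fold.kept]) / fold.feature_sd[fold.kept]
    return fold.svm.predict(xs)


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(str)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes are required")
    return y


def _stratified_folds(y: np.ndarray, k: int, seed: int):
    counts = np.bincount(np.searchsorted(np.unique(y), y))
    if counts.min() < k:
        raise ValueError(f"cannot stratify {counts.min()} subjects of one class into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32))
    return list(skf.split(np.zeros(len(y)), y))


def _select_grid_point(x, y, conf, grid, inner_k, seed) -> HyperParams:
    """Inner-CV grid selection; ties broken toward smallest C, then smallest gamma."""
    order = sorted(range(len(grid)), key=lambda i: (grid[i].c, grid[i].gamma))
    folds = _stratified_folds(y, inner_k, seed)
    best_hp, best_acc = None, -1.0
    for i in order:
        hp = grid[i]
        correct = 0
        for tr, te in folds:
            fold = _fit_on(x[tr], y[tr], None if conf is None else conf[tr], hp)
            pred = _predict_with(fold, x[te], None if conf is None else conf[te])
            correct += int((pred == y[te]).sum())
        acc = correct / len(y)
        if acc > best_acc:
            best_acc, best_hp = acc, hp
    return best_hp


def combine_hyperparams(selected: Sequence[HyperParams]) -> HyperParams:
    """Geometric mean of per-fold selections (arithmetic mean in log space)."""
    if not selected:
        raise ValueError("no hyperparameters to combine")
    if all(h == selected[0] for h in selected):
        return selected[0]
    log_c = np.mean([np.log(h.c) for h in selected])
    log_g = np.mean([np.log(h.gamma) for h in selected])
    return HyperParams(c=float(np.exp(log_c)), gamma=float(np.exp(log_g)))


def tune_hyperparameters(
    features,
    labels,
    confounds=None,
    grid: Optional[Sequence[HyperParams]] = None,
    outer_folds: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
) -> HyperParams:
    """Per-outer-fold inner-CV grid selection, combined by geometric mean."""
    x = np.asarray(features, dtype=float)
    y = _check_labels(labels)
    conf = None if confounds is None else _confound_design(confounds)
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    selected = []
    for f, (tr, _te) in enumerate(_stratified_folds(y, outer_folds, seed)):
        hp = _select_grid_point(
            x[tr], y[tr], None if conf is None else conf[tr], grid, inner_folds, seed + 1000 + f
        )
        selected.append(hp)
    return combine_hyperparams(selected)


@dataclass
class CVResult:
    """Pooled cross-validation outcome for one parcel."""

    parcel_id: int
    accuracy: float
    fold_assignments: np.ndarray
    per_subject_correct: np.ndarray
    hyperparams_used: list

    def __post_init__(self):
        self.per_subject_correct = np.asarray(self.per_subject_correct, dtype=bool)
        assert abs(self.accuracy - self.per_subject_correct.mean()) < 1e-12


def cross_validated_accuracy(
    features,
    labels,
    confounds=None,
    k: int = 10,
    hyperparams: Optional[HyperParams] = None,
    grid: Optional[Sequence[HyperParams]] = None,
    inner_folds: int = 5,
    seed: int = 0,
    parcel_id: int = -1,
    return_fold_models: bool = False,
):
    """Stratified k-fold CV accuracy with all training-fold-only artifacts.

    If ``grid`` is given (and ``hyperparams`` is not), hyperparameters are
    tuned by inner CV within each training fold, so no held-out information
    reaches any fitted component.  Accuracy is pooled over subjects.
    """
    x = np.asarray(features, dtype=float)
    y = _check_labels(labels)
    conf = None if confounds is None else _confound_design(confounds)
    if len(y) < 2 * k:
        raise ValueError("need at least 2k subjects for k folds")
    folds = _stratified_folds(y, k, seed)
    correct = np.zeros(len(y), dtype=bool)
    assign = np.full(len(y), -1, dtype=int)
    hps, fitted = [], []
    for f, (tr, te) in enumerate(folds):
        conf_tr = None if conf is None else conf[tr]
        if hyperparams is not None:
            hp = hyperparams
        elif grid is not None:
            hp = _select_grid_point(x[tr], y[tr], conf_tr, list(grid), inner_folds, seed + 1000 + f)
        else:
            hp = default_hyperparams(x.shape[1])
        fold = _fit_on(x[tr], y[tr], conf_tr, hp)
        pred = _predict_with(fold, x[te], None if conf is None else conf[te])
        correct[te] = pred == y[te]
        assign[te] = f
        hps.append(hp)
        if return_fold_models:
            fitted.append(fold)
    result = CVResult(
        parcel_id=parcel_id,
        accuracy=float(correct.mean()),
        fold_assignments=assign,
        per_subject_correct=correct,
        hyperparams_used=hps,
    )
    return (result, fitted) if return_fold_models else result


@dataclass
class TrainedParcelModel:
    """Final model trained on a full sample, applicable to external cohorts."""

    parcel_id: int
    hyperparams: HyperParams
    confound_model: Optional[ConfoundModel]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    kept_features: np.ndarray
    svm: _SvmState
    training_sample_id: str = ""
    atlas_hash: str = ""


def train_final_model(
    features,
    labels,
    confounds=None,
    grid: Optional[Sequence[HyperParams]] = None,
    hyperparams: Optional[HyperParams] = None,
    outer_folds: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
    parcel_id: int = -1,
    training_sample_id: str = "",
    atlas_hash: str = "",
) -> TrainedParcelModel:
    """Tune on the full sample (geometric-mean fold averaging), then fit on all subjects."""
    x = np.asarray(features, dtype=float)
    y = _check_labels(labels)
    conf = None if confounds is None else _confound_design(confounds)
    if hyperparams is None:
        if grid is not None:
            hyperparams = tune_hyperparameters(x, y, conf, grid, outer_folds, inner_folds, seed)
        else:
            hyperparams = default_hyperparams(x.shape[1])
    fold = _fit_on(x, y, conf, hyperparams)
    return TrainedParcelModel(
        parcel_id=parcel_id,
        hyperparams=hyperparams,
        confound_model=fold.confound_model,
        feature_mean=fold.feature_mean,
        feature_sd=fold.feature_sd,
        kept_features=fold.kept,
        svm=fold.svm,
        training_sample_id=training_sample_id,
        atlas_hash=atlas_hash,
    )


def predict_external(model: TrainedParcelModel, features_b, confounds_b=None, labels_b=None):
    """Classify external subjects with TRAINING betas and TRAINING scaler.

    Returns ``(accuracy, per_subject_correct)`` when labels are given,
    otherwise ``(None, predictions)``.
    """
    x = np.asarray(features_b, dtype=float)
    if x.shape[1] != model.feature_mean.shape[0]:
        raise ValueError("feature dimension mismatch (different atlas?)")
    fold = _FittedFold(
        model.confound_model, model.feature_mean, model.feature_sd, model.kept_features,
        model.svm, model.hyperparams,
    )
    conf = None if confounds_b is None else _confound_design(confounds_b)
    pred = _predict_with(fold, x, conf)
    if labels_b is None:
        return None, pred
    y = np.asarray(labels_b).astype(str)
    correct = pred == y
    return float(correct.mean()), correct


# ---------------------------------------------------------------------------
# whole-map drivers


def parcel_features(z_stack: np.ndarray, atlas: Atlas, parcel_id: int) -> np.ndarray:
    """(n_subjects, P-1) feature matrix for one parcel from a connectome stack."""
    if parcel_id == WHOLE_BRAIN_ID:
        p = atlas.n_parcels
        iu = np.triu_indices(p, k=1)
        return z_stack[:, iu[0], iu[1]]
    i = atlas.index_of(parcel_id)
    return np.delete(z_stack[:, i, :], i, axis=1)


def _parcel_seed(master_seed: int, parcel_id: int) -> int:
    # deterministic regardless of worker count / evaluation order
    return int((int(master_seed) * 1_000_003 + int(parcel_id) + 1) % (2**31 - 1))


def classify_all_parcels(
    z_stack: np.ndarray,
    atlas: Atlas,
    labels,
    confounds=None,
    k: int = 10,
    hyperparams: Optional[HyperParams] = None,
    grid: Optional[Sequence[HyperParams]] = None,
    inner_folds: int = 5,
    seed: int = 0,
    n_jobs: int = 1,
    include_whole_brain: bool = False,
):
    """Run the per-parcel CV routine for every parcel of the atlas.

    Returns ``(AccuracyMap, dict parcel_id -> CVResult)``.  Per-parcel seeds
    are derived from the master seed and parcel id, so results are identical
    across worker counts.  A parcel whose classification fails is recorded
    as NaN in the map (and listed in metadata), never silently dropped.
    """
    pids = list(atlas.parcel_ids) + ([WHOLE_BRAIN_ID] if include_whole_brain else [])

    def one(pid):
        x = parcel_features(z_stack, atlas, pid)
        try:
            res = cross_validated_accuracy(
                x, labels, confounds, k=k, hyperparams=hyperparams, grid=grid,
                inner_folds=inner_folds, seed=_parcel_seed(seed, pid), parcel_id=pid,
            )
            return pid, res, None
        except Exception as exc:  # record, don't drop
            return pid, None, str(exc)

    out = Parallel(n_jobs=n_jobs)(delayed(one)(pid) for pid in pids)
    results, failed, acc = {}, {}, []
    for pid, res, err in out:
        if res is None:
            failed[pid] = err
            acc.append(np.nan)
        else:
            results[pid] = res
            acc.append(res.accuracy)
    amap = AccuracyMap(
        parcel_ids=np.array(pids),
        accuracy=np.array(acc),
        metadata={
            "mode": "cv", "k": k, "seed": seed, "failed": failed,
            "hyperparams": {pid: res.hyperparams_used[0] for pid, res in results.items()}
            if hyperparams is None and grid is None else None,
            "fixed_hyperparams": hyperparams,
        },
    )
    return amap, results


def train_all_parcels(
    z_stack, atlas, labels, confounds=None,
    grid=None, hyperparams=None, outer_folds: int = 10, inner_folds: int = 5,
    seed: int = 0, n_jobs: int = 1, include_whole_brain: bool = False,
    training_sample_id: str = "",
):
    """Final model per parcel, trained on the full sample."""
    pids = list(atlas.parcel_ids) + ([WHOLE_BRAIN_ID] if include_whole_brain else [])

    def one(pid):
        x = parcel_features(z_stack, atlas, pid)
        return pid, train_final_model(
            x, labels, confounds, grid=grid, hyperparams=hyperparams,
            outer_folds=outer_folds, inner_folds=inner_folds,
            seed=_parcel_seed(seed, pid), parcel_id=pid,
            training_sample_id=training_sample_id, atlas_hash=atlas.hash(),
        )

    return dict(Parallel(n_jobs=n_jobs)(delayed(one)(pid) for pid in pids))


def predict_external_all(
    models: Mapping[int, TrainedParcelModel],
    z_stack_b, atlas: Atlas, labels_b, confounds_b=None,
):
    """External-sample accuracy map from per-parcel trained models."""
    if any(m.atlas_hash and m.atlas_hash != atlas.hash() for m in models.values()):
        raise ValueError("atlas mismatch between trained models and external cohort")
    pids, accs, correct = [], [], {}
    for pid, model in models.items():
        x = parcel_features(z_stack_b, atlas, pid)
        a, c = predict_external(model, x, confounds_b, labels_b)
        pids.append(pid)
        accs.append(a)
        correct[pid] = c
    amap = AccuracyMap(
        parcel_ids=np.array(pids), accuracy=np.array(accs),
        metadata={"mode": "external"},
    )
    return amap, correct


# ---------------------------------------------------------------------------
# serialization: documented single-file JSON format


def save_model(model: TrainedParcelModel, path) -> None:
    """Write a trained model to a single JSON file (arrays as nested lists)."""
    doc = {
        "format": "parcelclass-model-v1",
        "parcel_id": int(model.parcel_id),
        "hyperparams": {"c": model.hyperparams.c, "gamma": model.hyperparams.gamma},
        "confound_model": None
        if model.confound_model is None
        else {
            "betas": model.confound_model.betas.tolist(),
            "confound_names": model.confound_model.confound_names,
        },
        "feature_mean": model.feature_mean.tolist(),
        "feature_sd": model.feature_sd.tolist(),
        "kept_features": model.kept_features.tolist(),
        "svm": {
            "support_vectors": model.svm.support_vectors.tolist(),
            "dual_coef": model.svm.dual_coef.tolist(),
            "intercept": model.svm.intercept,
            "gamma": model.svm.gamma,
            "classes": model.svm.classes,
        },
        "training_sample_id": model.training_sample_id,
        "atlas_hash": model.atlas_hash,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> TrainedParcelModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "parcelclass-model-v1":
        raise ValueError("unrecognized model file format")
    cm = doc["confound_model"]
    svm = doc["svm"]
    return TrainedParcelModel(
        parcel_id=doc["parcel_id"],
        hyperparams=HyperParams(**doc["hyperparams"]),
        confound_model=None
        if cm is None
        else ConfoundModel(betas=np.array(cm["betas"]), confound_names=cm["confound_names"]),
        feature_mean=np.array(doc["feature_mean"]),
        feature_sd=np.array(doc["feature_sd"]),
        kept_features=np.array(doc["kept_features"], dtype=int),
        svm=_SvmState(
            support_vectors=np.array(svm["support_vectors"]),
            dual_coef=np.array(svm["dual_coef"]),
            intercept=float(svm["intercept"]),
            gamma=float(svm["gamma"]),
            classes=list(svm["classes"]),
        ),
        training_sample_id=doc["training_sample_id"],
        atlas_hash=doc["atlas_hash"],
    )
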