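"""One-vs-one SVM voting ensemble over substrate classes.

For K classes, one RBF-kernel binary SVM is trained per unordered class
pair — K(K-1)/2 classifiers, 21 for the seven substrate categories — on
the members of just those two classes.  Prediction applies every pairwise
classifier to the query vector and returns the class receiving the most
votes.  A vote tie is broken by the larger summed signed decision margin
over the tied class's pairwise classifiers, and any residual tie by
canonical class order, so prediction is fully deterministic.

Features are standardized (per-feature centre/scale fitted on the full
training set) before the RBF kernel, and a single (cost, gamma) pair —
found by grid search over whole-ensemble cross-validated accuracy — is
shared by all pairwise classifiers.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .composition import CompositionVector
from .metrics import ConfusionMatrix, metrics_report, multiclass_mcc, overall_accuracy

log = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: Default RBF grid, within the conventional cost 2..16 and gamma 2e-5..1 ranges.
DEFAULT_COSTS: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0)
DEFAULT_GAMMAS: tuple[float, ...] = (2e-5, 2e-4, 2e-3, 2e-2, 2e-1, 1.0)


@dataclass
class LabelledDataset:
    """Encoded sequences with class labels.

    All vectors must share one scheme and length; ``classes`` fixes the
    canonical class order used for voting tie-breaks and confusion
    matrices.
    """

    ids: list[str]
    X: np.ndarray
    y: list[str]
    classes: tuple[str, ...]
    scheme: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not (len(self.ids) == len(self.X) == len(self.y)):
            raise ValueError("ids, X and y must have equal length")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        unknown = set(self.y) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside declared classes: {sorted(unknown)}")

    @classmethod
    def from_vectors(
        cls,
        items: Sequence[tuple[str, CompositionVector, str]],
        classes: Sequence[str] | None = None,
    ) -> "LabelledDataset":
        if not items:
            raise ValueError("empty dataset")
        scheme = items[0][1].scheme
        n = len(items[0][1])
        for sid, vec, _ in items:
            if vec.scheme != scheme or len(vec) != n:
                raise ValueError(f"vector for {sid!r} does not match scheme {scheme}")
        ids = [sid for sid, _, _ in items]
        X = np.vstack([vec.values for _, vec, _ in items])
        y = [lbl for _, _, lbl in items]
        if classes is None:
            classes = tuple(dict.fromkeys(y))  # first-appearance order
        return cls(ids=ids, X=X, y=y, classes=tuple(classes), scheme=scheme)

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices: Sequence[int]) -> "LabelledDataset":
        idx = list(indices)
        return LabelledDataset(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            y=[self.y[i] for i in idx],
            classes=self.classes,
            scheme=self.scheme,
        )


@dataclass
class EnsembleModel:
    """K(K-1)/2 pairwise SVMs plus shared preprocessing and hyperparameters."""

    classes: tuple[str, ...]
    pairwise: dict[tuple[str, str], SVC]
    scaler: StandardScaler
    cost: float
    gamma: float
    scheme: str
    n_features: int
    missing_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def n_pairwise(self) -> int:
        return len(self.pairwise)


def build_ensemble(
    data: LabelledDataset,
    cost: float = 8.0,
    gamma: float = 2e-3,
    allow_missing: bool = False,
) -> EnsembleModel:
    """Train one binary RBF SVM per unordered class pair.

    Each pairwise classifier sees only the members of its two classes;
    feature scaling is fitted once on the full training set.  A class with
    no members is an error unless ``allow_missing`` is set, in which case
    the affected pairs are skipped with a warning and recorded on the
    model.
    """
    present = set(data.y)
    absent = [c for c in data.classes if c not in present]
    if absent and not allow_missing:
        raise ValueError(f"class(es) absent from training data: {absent}")
    if absent:
        log.warning("training with absent class(es): %s", absent)

    scaler = StandardScaler().fit(data.X)
    Xs = scaler.transform(data.X)
    y = np.array(data.y)

    pairwise: dict[tuple[str, str], SVC] = {}
    missing: list[tuple[str, str]] = []
    for ci, cj in itertools.combinations(data.classes, 2):
        sel = (y == ci) | (y == cj)
        if ci not in present or cj not in present:
            missing.append((ci, cj))
            continue
        clf = SVC(kernel="rbf", C=cost, gamma=gamma)
        clf.fit(Xs[sel], y[sel])
        pairwise[(ci, cj)] = clf
    return EnsembleModel(
        classes=data.classes,
        pairwise=pairwise,
        scaler=scaler,
        cost=cost,
        gamma=gamma,
        scheme=data.scheme,
        n_features=data.X.shape[1],
        missing_pairs=tuple(missing),
    )


def predict(
    model: EnsembleModel, v: CompositionVector | np.ndarray
) -> tuple[str, dict[str, int]]:
    """Predict by majority vote; returns the class and the full vote tally.

    Every pairwise classifier casts one vote.  Ties on vote count are
    broken by the larger summed signed decision margin accumulated over
    each tied class's pairwise classifiers; a residual tie falls back to
    canonical class order.
    """
    x = v.values if isinstance(v, CompositionVector) else np.asarray(v, dtype=float)
    if x.shape != (model.n_features,):
        raise ValueError(
            f"feature dimension mismatch: got {x.shape[0] if x.ndim == 1 else x.shape}, "
            f"model expects {model.n_features}"
        )
    xs = model.scaler.transform(x.reshape(1, -1))
    votes = {c: 0 for c in model.classes}
    margins = {c: 0.0 for c in model.classes}
    for (ci, cj), clf in model.pairwise.items():
        winner = str(clf.predict(xs)[0])
        votes[winner] += 1
        # decision_function > 0 favours clf.classes_[1]
        f = float(clf.decision_function(xs)[0])
        lo, hi = clf.classes_
        margins[str(hi)] += f
        margins[str(lo)] -= f
    best_votes = max(votes.values())
    tied = [c for c in model.classes if votes[c] == best_votes]
    if len(tied) > 1:
        best_margin = max(margins[c] for c in tied)
        tied = [c for c in tied if margins[c] == best_margin]
    return tied[0], votes


def predict_many(
    model: EnsembleModel, X: np.ndarray | Sequence[CompositionVector]
) -> list[str]:
    """Vectorized batch prediction; agrees exactly with :func:`predict`."""
    if not isinstance(X, np.ndarray):
        X = np.vstack([v.values for v in X])
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: got {X.shape}, "
            f"model expects (*, {model.n_features})"
        )
    Xs = model.scaler.transform(X)
    n = len(Xs)
    cls_idx = {c: i for i, c in enumerate(model.classes)}
    votes = np.zeros((n, len(model.classes)), dtype=int)
    margins = np.zeros((n, len(model.classes)))
    for clf in model.pairwise.values():
        winners = clf.predict(Xs)
        f = clf.decision_function(Xs)
        lo, hi = (str(c) for c in clf.classes_)
        for w in (lo, hi):
            votes[winners == w, cls_idx[w]] += 1
        margins[:, cls_idx[hi]] += f
        margins[:, cls_idx[lo]] -= f
    out: list[str] = []
    for i in range(n):
        best = votes[i].max()
        tied = np.flatnonzero(votes[i] == best)
        if len(tied) > 1:
            tied = tied[margins[i, tied] == margins[i, tied].max()]
        out.append(model.classes[tied[0]])
    return out


def _partition(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded uniform split of range(n) into k near-equal folds."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def _stratified_partition(y: Sequence[str], k: int, seed: int) -> list[np.ndarray]:
    """Seeded split keeping per-class proportions roughly equal per fold."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in dict.fromkeys(y):
        idx = np.array([i for i, lbl in enumerate(y) if lbl == cls])
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[(offset + j) % k].append(int(i))
        offset += len(idx)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class CVResult:
    """Per-fold confusion matrices and fold-level summary statistics."""

    folds: list[ConfusionMatrix]
    fold_assignments: list[np.ndarray]
    hyperparameters: list[tuple[float, float]]

    def summary(self) -> dict[str, tuple[float, float]]:
        """Mean and standard deviation across folds of accuracy and MCC.

        Accuracy is a percentage; MCC stays on [-1, 1].  Presented as
        (mean, sd) pairs, the conventional "m +/- d" across folds.
        """
        accs = np.array([100.0 * overall_accuracy(cm) for cm in self.folds])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mccs = np.array([multiclass_mcc(cm) for cm in self.folds])
            mcc_mean = float(np.nanmean(mccs)) if np.isfinite(mccs).any() else float("nan")
            mcc_sd = float(np.nanstd(mccs, ddof=1)) if np.isfinite(mccs).sum() > 1 else float("nan")
        return {
            "accuracy": (float(accs.mean()), float(accs.std(ddof=1))),
            "mcc": (mcc_mean, mcc_sd),
        }

    def pooled(self) -> ConfusionMatrix:
        total = self.folds[0]
        for cm in self.folds[1:]:
            total = total + cm
        return total


def cross_validate(
    data: LabelledDataset,
    k: int = 5,
    seed: int = 0,
    cost: float = 8.0,
    gamma: float = 2e-3,
    tune: str = "per-fold",
    costs: Sequence[float] = DEFAULT_COSTS,
    gammas: Sequence[float] = DEFAULT_GAMMAS,
    tune_folds: int = 3,
    stratified: bool = False,
) -> CVResult:
    """Seeded k-fold cross-validation of the voting ensemble.

    The dataset is randomly partitioned into k near-equal folds (uniform
    by default; ``stratified=True`` balances class proportions per fold);
    each fold is predicted by an ensemble trained on the other k-1.  ``tune`` selects the hyperparameter protocol: ``"off"``
    uses the given (cost, gamma) everywhere, ``"per-fold"`` grid-searches
    inside each training split (no leakage into the held-out fold), and
    ``"once"`` grid-searches on the full dataset first.  ``k = len(data)``
    gives leave-one-out.  A class missing from a training split is logged;
    the pairs involving it are skipped for that fold.
    """
    n = len(data)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if tune not in ("off", "per-fold", "once"):
        raise ValueError(f"unknown tuning mode {tune!r}")
    if tune == "once":
        cost, gamma = tune_hyperparameters(
            data, costs=costs, gammas=gammas, folds=tune_folds, seed=seed
        )

    if stratified:
        folds = _stratified_partition(data.y, k, seed)
    else:
        folds = _partition(n, k, seed)
    matrices: list[ConfusionMatrix] = []
    hypers: list[tuple[float, float]] = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train = data.subset(train_idx)
        test = data.subset(test_idx)
        c, g = cost, gamma
        if tune == "per-fold":
            c, g = tune_hyperparameters(
                train, costs=costs, gammas=gammas, folds=tune_folds, seed=seed + fi
            )
        model = build_ensemble(train, cost=c, gamma=g, allow_missing=True)
        y_pred = predict_many(model, test.X)
        matrices.append(
            ConfusionMatrix.from_predictions(test.y, y_pred, data.classes)
        )
        hypers.append((c, g))
    return CVResult(folds=matrices, fold_assignments=folds, hyperparameters=hypers)


def loocv(data: LabelledDataset, seed: int = 0, **kwargs) -> CVResult:
    """Leave-one-out cross-validation (k = n)."""
    return cross_validate(data, k=len(data), seed=seed, **kwargs)


def tune_hyperparameters(
    data: LabelledDataset,
    costs: Sequence[float] = DEFAULT_COSTS,
    gammas: Sequence[float] = DEFAULT_GAMMAS,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Grid search (cost, gamma) by whole-ensemble CV accuracy.

    Every grid point is scored with the same seeded fold partition; ties
    are broken toward the smaller cost, then the smaller gamma.
    """
    if len(data) < folds:
        raise ValueError(
            f"dataset has {len(data)} items, fewer than {folds} folds"
        )
    best: tuple[float, float] | None = None
    best_acc = -1.0
    for cost in sorted(costs):
        for gamma in sorted(gammas):
            res = cross_validate(
                data, k=folds, seed=seed, cost=cost, gamma=gamma, tune="off"
            )
            acc = overall_accuracy(res.pooled())
            if acc > best_acc:
                best_acc, best = acc, (cost, gamma)
    assert best is not None
    return best


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Serialize the ensemble as a single versioned archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "classes": model.classes,
        "pairwise": model.pairwise,
        "scaler": model.scaler,
        "cost": model.cost,
        "gamma": model.gamma,
        "scheme": model.scheme,
        "n_features": model.n_features,
        "missing_pairs": model.missing_pairs,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> EnsembleModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return EnsembleModel(
        classes=tuple(payload["classes"]),
        pairwise=payload["pairwise"],
        scaler=payload["scaler"],
        cost=payload["cost"],
        gamma=payload["gamma"],
        scheme=payload["scheme"],
        n_features=payload["n_features"],
        missing_pairs=tuple(payload["missing_pairs"]),
    )
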