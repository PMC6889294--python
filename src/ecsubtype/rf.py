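"""The 12-gene random-forest surrogate for the copy-number groups.

Copy-number low (CNL) vs copy-number high (CNH) status normally requires
genome-wide copy-number profiling; this module trains a random forest on
binary mutation indicators of the 12 non-POLE panel genes to act as an
affordable surrogate.  Protocol: a labeled cohort is split 62/86
(training/validation) stratified on the class label, mtry (features
considered per split) is tuned by stratified 5-fold cross-validation on
the training half, a 1000-tree bagged forest is fit at the chosen mtry,
and the held-out half yields the confusion-matrix metric suite (accuracy
with exact binomial CI, no-information rate, Cohen's kappa, exact McNemar,
sensitivity/specificity/PPV/NPV, prevalence, detection rate/prevalence,
balanced accuracy) plus mean-decrease-Gini variable importances.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from .panel import GenePanel

logger = logging.getLogger(__name__)

LABELS = ("CNL", "CNH")


# ---------------------------------------------------------------------------
# training data container

@dataclass
class TrainingSet:
    """n x 12 binary feature matrix (GenePanel.rf_genes order) with a
    CNL/CNH label per row."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("feature matrix and labels differ in length")
        if not set(np.unique(self.X.to_numpy())) <= {0, 1}:
            raise ValueError("features must be strictly binary")
        bad = set(self.y.unique()) - set(LABELS)
        if bad:
            raise ValueError(f"labels outside {LABELS}: {sorted(bad)}")
        if len(set(self.y.unique())) < 2:
            raise ValueError("both CNL and CNH labels must be present")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.X.columns).encode())
        h.update(self.X.to_numpy(dtype=np.int8).tobytes())
        h.update(",".join(self.y.astype(str)).encode())
        return h.hexdigest()[:16]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label_col: str = "label",
                   panel: GenePanel | None = None) -> "TrainingSet":
        panel = panel or GenePanel()
        missing = [g for g in panel.rf_genes if g not in frame.columns]
        if missing:
            raise ValueError(f"training matrix lacks gene column(s): {missing}")
        return cls(X=frame[list(panel.rf_genes)].astype(int).copy(),
                   y=frame[label_col].astype(str).copy())


def stratified_split(
    data: TrainingSet, n_train: int, seed: int
) -> tuple[TrainingSet, TrainingSet]:
    """Label-stratified split into (train, validation); deterministic per
    seed, label proportions within one sample of the full-set proportion."""
    if not 0 < n_train < data.n:
        raise ValueError("n_train must lie strictly between 0 and n")
    idx_train, idx_val = train_test_split(
        np.arange(data.n), train_size=n_train, stratify=data.y,
        random_state=int(seed) % (2**31),
    )
    train = TrainingSet(data.X.iloc[np.sort(idx_train)].reset_index(drop=True),
                        data.y.iloc[np.sort(idx_train)].reset_index(drop=True))
    val = TrainingSet(data.X.iloc[np.sort(idx_val)].reset_index(drop=True),
                      data.y.iloc[np.sort(idx_val)].reset_index(drop=True))
    return train, val


# ---------------------------------------------------------------------------
# tuning + training

def tune_mtry(
    train: TrainingSet,
    grid: Sequence[int] | None = None,
    folds: int = 5,
    seed: int = 0,
    cv_n_trees: int = 200,
) -> tuple[int, dict[int, float]]:
    """Pick mtry maximizing mean stratified-CV accuracy; ties break toward
    the smaller mtry.  CV forests use ``cv_n_trees`` trees (tuning economy;
    the final model is always trained at its own n_trees)."""
    p = len(train.feature_names)
    grid = list(grid) if grid is not None else list(range(1, p + 1))
    if any(m < 1 or m > p for m in grid):
        raise ValueError(f"mtry grid must lie in [1, {p}]")
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(seed) % (2**31))
    X = train.X.to_numpy(dtype=np.int8)
    y = train.y.to_numpy()
    trace: dict[int, float] = {}
    for mtry in grid:
        accs = []
        for fold_i, (tr, te) in enumerate(skf.split(X, y)):
            if len(set(y[tr])) < 2:
                raise ValueError(f"fold {fold_i} contains a single class")
            clf = RandomForestClassifier(
                n_estimators=cv_n_trees, max_features=mtry,
                random_state=(int(seed) + fold_i) % (2**31), bootstrap=True,
            ).fit(X[tr], y[tr])
            accs.append(float((clf.predict(X[te]) == y[te]).mean()))
        trace[mtry] = float(np.mean(accs))
    best = min(trace, key=lambda m: (-trace[m], m))
    logger.info("mtry tuning trace: %s -> best %d", trace, best)
    return best, trace


@dataclass
class RfModel:
    """Trained forest plus its training-protocol record."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    mtry: int
    n_trees: int
    seed: int
    fingerprint: str
    tuning_trace: dict[int, float] = field(default_factory=dict)

    def _check_features(self, names: Sequence[str]) -> None:
        if tuple(names) != self.feature_names:
            raise ValueError(
                "feature order mismatch: model was trained on "
                f"{self.feature_names}, got {tuple(names)}"
            )

    def predict(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(labels, vote fraction for the predicted label) per row."""
        self._check_features(X.columns)
        proba = self.forest.predict_proba(X.to_numpy(dtype=np.int8))
        classes = self.forest.classes_
        idx = proba.argmax(axis=1)
        labels = classes[idx]
        votes = proba[np.arange(len(X)), idx]
        return labels, votes

    def predict_one(self, gene_status: Mapping[str, int]) -> tuple[str, float]:
        row = pd.DataFrame([[int(gene_status[g]) for g in self.feature_names]],
                           columns=list(self.feature_names))
        labels, votes = self.predict(row)
        return str(labels[0]), float(votes[0])

    def save(self, path: str | Path) -> None:
        """Versioned JSON metadata + joblib sidecar for the forest state."""
        import joblib

        path = Path(path)
        sidecar = path.with_suffix(".joblib")
        joblib.dump(self.forest, sidecar)
        meta = {
            "format_version": 1,
            "feature_names": list(self.feature_names),
            "mtry": self.mtry,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "fingerprint": self.fingerprint,
            "tuning_trace": {str(k): v for k, v in self.tuning_trace.items()},
            "sidecar": sidecar.name,
        }
        path.write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RfModel":
        import joblib

        path = Path(path)
        meta = json.loads(path.read_text())
        if meta.get("format_version") != 1:
            raise ValueError("unsupported model format version")
        forest = joblib.load(path.parent / meta["sidecar"])
        return cls(
            forest=forest,
            feature_names=tuple(meta["feature_names"]),
            mtry=int(meta["mtry"]),
            n_trees=int(meta["n_trees"]),
            seed=int(meta["seed"]),
            fingerprint=meta["fingerprint"],
            tuning_trace={int(k): v for k, v in meta["tuning_trace"].items()},
        )


def train_rf(
    train: TrainingSet,
    mtry: int,
    n_trees: int = 1000,
    seed: int = 0,
) -> RfModel:
    """Fit a bagged forest: ``n_trees`` trees, each grown on a bootstrap
    resample with ``mtry`` candidate features per split; majority-vote
    prediction with the vote fraction exposed.  Reproducible per seed."""
    if not 1 <= mtry <= len(train.feature_names):
        raise ValueError("mtry outside [1, n_features]")
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, bootstrap=True,
        random_state=int(seed) % (2**31),
    ).fit(train.X.to_numpy(dtype=np.int8), train.y.to_numpy())
    return RfModel(
        forest=forest,
        feature_names=train.feature_names,
        mtry=mtry,
        n_trees=n_trees,
        seed=int(seed),
        fingerprint=train.fingerprint(),
    )


def fit_protocol(
    data: TrainingSet,
    n_train: int = 62,
    n_trees: int = 1000,
    folds: int = 5,
    seed: int = 0,
    grid: Sequence[int] | None = None,
    cv_n_trees: int = 200,
) -> tuple[RfModel, "PerformanceReport", TrainingSet, TrainingSet]:
    """Full training protocol: stratified split, mtry tuning by CV on the
    training half, 1000-tree fit, metric suite on the validation half."""
    train, val = stratified_split(data, n_train=n_train, seed=seed)
    best_mtry, trace = tune_mtry(train, grid=grid, folds=folds, seed=seed,
                                 cv_n_trees=cv_n_trees)
    model = train_rf(train, mtry=best_mtry, n_trees=n_trees, seed=seed)
    model.tuning_trace = trace
    pred, _ = model.predict(val.X)
    report = performance_metrics(val.y.to_numpy(), pred, positive_class="CNH")
    return model, report, train, val


# ---------------------------------------------------------------------------
# metric suite

@dataclass
class PerformanceReport:
    confusion: dict[str, int]            # tp, fn, fp, tn w.r.t. positive class
    accuracy: float
    accuracy_ci: tuple[float, float]     # exact (Clopper-Pearson) 95% CI
    no_information_rate: float
    kappa: float
    mcnemar_p: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence: float
    detection_rate: float
    detection_prevalence: float
    balanced_accuracy: float
    positive_class: str = "CNH"
    n: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["accuracy_ci"] = list(self.accuracy_ci)
        return d


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def performance_metrics(
    truth: Sequence[str],
    predicted: Sequence[str],
    positive_class: str = "CNH",
) -> PerformanceReport:
    """Confusion-matrix metric suite for the binary CNL/CNH task.

    Accuracy CI is exact binomial (Clopper-Pearson); McNemar is the exact
    two-sided binomial test on discordant pairs (p = 1 when balanced or no
    discordance); kappa = (po - pe) / (1 - pe) with pe from the marginal
    products.
    """
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape or truth.size == 0:
        raise ValueError("truth/predicted must be equal-length and non-empty")
    bad = (set(truth) | set(predicted)) - set(LABELS)
    if bad:
        raise ValueError(f"labels outside {LABELS}: {sorted(bad)}")
    pos, = [positive_class]
    neg = [l for l in LABELS if l != pos][0]

    tp = int(((truth == pos) & (predicted == pos)).sum())
    fn = int(((truth == pos) & (predicted == neg)).sum())
    fp = int(((truth == neg) & (predicted == pos)).sum())
    tn = int(((truth == neg) & (predicted == neg)).sum())
    n = tp + fn + fp + tn

    accuracy = (tp + tn) / n
    nir = max((tp + fn) / n, (fp + tn) / n)
    # chance agreement from marginal products
    pe = ((tp + fn) / n) * ((tp + fp) / n) + ((fp + tn) / n) * ((fn + tn) / n)
    kappa = (accuracy - pe) / (1 - pe) if pe < 1 else 1.0
    discordant = fn + fp
    mcnemar_p = 1.0 if discordant == 0 else min(
        1.0, float(stats.binomtest(min(fn, fp), discordant, 0.5).pvalue)
    )
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    return PerformanceReport(
        confusion={"tp": tp, "fn": fn, "fp": fp, "tn": tn},
        accuracy=accuracy,
        accuracy_ci=_clopper_pearson(tp + tn, n),
        no_information_rate=nir,
        kappa=kappa,
        mcnemar_p=mcnemar_p,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        prevalence=(tp + fn) / n,
        detection_rate=tp / n,
        detection_prevalence=(tp + fp) / n,
        balanced_accuracy=(sens + spec) / 2,
        positive_class=pos,
        n=n,
    )


def gini_importance(model: RfModel) -> pd.Series:
    """Mean decrease in Gini impurity per gene, sorted descending.

    scikit-learn normalizes importances to sum to 1, so values are on a
    relative scale; features never selected for a split score exactly 0.
    Ranks (not absolute values) are the meaningful output.
    """
    if not hasattr(model.forest, "feature_importances_"):
        raise ValueError("model is not trained")
    imp = pd.Series(model.forest.feature_importances_,
                    index=list(model.feature_names), name="mean_decrease_gini")
    return imp.sort_values(ascending=False, kind="stable")


__all__ = [
    "LABELS", "TrainingSet", "RfModel", "PerformanceReport",
    "stratified_split", "tune_mtry", "train_rf", "fit_protocol",
    "performance_metrics", "gini_importance",
]
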