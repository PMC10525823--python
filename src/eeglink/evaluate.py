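"""Macro metrics, task-wise cross-validation splits and baseline classifiers.

Macro precision P* and recall R* are the unweighted means of the per-class
precision TP/(TP+FP) and recall TP/(TP+FN); F1 is the harmonic mean of the
two macro averages, F1 = 2 P* R* / (P* + R*).  Classes with an undefined
ratio (zero denominator) contribute 0, the usual convention.

Splits are task-wise within subject: for M tasks per subject and a ratio
"a:b" (a+b = M), every subject contributes its recordings of a tasks to
training and b tasks to testing; the fold index rotates which tasks are held
out, giving cross-validation without temporal leakage between train and test
segments of one recording.

Baselines are the standard classifier roster (linear-kernel SVM,
1-nearest-neighbour, LDA, decision tree, Gaussian naive Bayes, AdaBoost,
MLP) from scikit-learn, fed with the classical AR + band-power features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg_io import DatasetManifest

__all__ = [
    "MetricsReport",
    "SplitPlan",
    "macro_metrics",
    "split_by_tasks",
    "run_baseline",
    "BASELINES",
]


@dataclass
class MetricsReport:
    """Per-class and macro-averaged classification metrics."""

    confusion: np.ndarray                 # (Q, Q) counts, rows = true class
    precision_per_class: np.ndarray
    recall_per_class: np.ndarray
    f1_per_class: np.ndarray
    precision: float                      # macro P*
    recall: float                         # macro R*
    f1: float                             # harmonic mean of P*, R*
    labels: list[int] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        total = self.confusion.sum()
        return float(np.trace(self.confusion) / total) if total else 0.0


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def metrics_from_confusion(cm: np.ndarray, labels: list[int] | None = None) -> MetricsReport:
    """Compute the macro metrics from an integer confusion matrix."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    prec = _safe_div(tp, tp + fp)
    rec = _safe_div(tp, tp + fn)
    f1c = _safe_div(2 * prec * rec, prec + rec)
    p_star = float(prec.mean())
    r_star = float(rec.mean())
    f1 = 2 * p_star * r_star / (p_star + r_star) if (p_star + r_star) > 0 else 0.0
    return MetricsReport(
        confusion=cm,
        precision_per_class=prec,
        recall_per_class=rec,
        f1_per_class=f1c,
        precision=p_star,
        recall=r_star,
        f1=float(f1),
        labels=labels or list(range(1, cm.shape[0] + 1)),
    )


def macro_metrics(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> MetricsReport:
    """Macro P*/R*/F1 from 1-based label vectors."""
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 1 or y.max() > n_classes):
            raise ValueError(f"{name} labels outside [1, {n_classes}]")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true - 1, y_pred - 1), 1)
    return metrics_from_confusion(cm)


@dataclass
class SplitPlan:
    """Task-wise train/test split, identical task sets for every subject."""

    train_tasks: list[int]
    test_tasks: list[int]
    ratio: str
    fold: int = 0

    def __post_init__(self) -> None:
        if set(self.train_tasks) & set(self.test_tasks):
            raise ValueError("train and test tasks overlap")

    def train_entries(self, manifest: DatasetManifest) -> list[tuple[str, int, int]]:
        return [e for e in manifest.entries if e[2] in set(self.train_tasks)]

    def test_entries(self, manifest: DatasetManifest) -> list[tuple[str, int, int]]:
        return [e for e in manifest.entries if e[2] in set(self.test_tasks)]


def parse_ratio(ratio: str) -> tuple[int, int]:
    try:
        a, b = (int(v) for v in ratio.split(":"))
    except ValueError:
        raise ValueError(f"ratio must look like 'a:b', got {ratio!r}") from None
    if a < 1 or b < 1:
        raise ValueError(f"both ratio parts must be >= 1, got {ratio!r}")
    return a, b


def split_by_tasks(manifest: DatasetManifest, ratio: str, fold: int = 0) -> SplitPlan:
    """Hold out b of the M tasks per subject for testing (ratio 'a:b', a+b=M).

    The fold index rotates the held-out block through the task list, so folds
    0 .. ceil(M/b)-1 cover every task exactly once when b divides M.
    """
    a, b = parse_ratio(ratio)
    tasks = manifest.tasks
    M = len(tasks)
    if a + b != M:
        raise ValueError(f"ratio {ratio} sums to {a + b}, but dataset has M={M} tasks")
    start = (fold * b) % M
    test = [tasks[(start + j) % M] for j in range(b)]
    train = [t for t in tasks if t not in set(test)]
    return SplitPlan(train_tasks=train, test_tasks=test, ratio=ratio, fold=fold)


def n_folds(manifest: DatasetManifest, ratio: str) -> int:
    """Number of rotation folds that tile the task set."""
    _, b = parse_ratio(ratio)
    M = len(manifest.tasks)
    return int(np.ceil(M / b))


def _make_baseline(name: str, seed: int = 0):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import AdaBoostClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    registry = {
        "svm": lambda: make_pipeline(StandardScaler(), SVC(kernel="linear", random_state=seed)),
        "lda": lambda: LinearDiscriminantAnalysis(),
        "nn": lambda: KNeighborsClassifier(n_neighbors=1),
        "dts": lambda: DecisionTreeClassifier(random_state=seed),
        "bayes": lambda: GaussianNB(),
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "mlp": lambda: make_pipeline(
            StandardScaler(), MLPClassifier(random_state=seed, max_iter=500)
        ),
    }
    try:
        return registry[name]()
    except KeyError:
        raise ValueError(f"unknown baseline {name!r}; choose from {sorted(registry)}") from None


BASELINES = ("svm", "lda", "nn", "dts", "bayes", "adaboost", "mlp")


def run_baseline(
    name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    seed: int = 0,
) -> MetricsReport:
    """Fit one named off-the-shelf classifier and score macro metrics.

    Labels are 1-based; the report's class count is the union of train and
    test labels.
    """
    clf = _make_baseline(name, seed=seed)
    clf.fit(X_train, y_train)
    y_pred = np.asarray(clf.predict(X_test), int)
    n_classes = int(max(y_train.max(), y_test.max(), y_pred.max()))
    return macro_metrics(y_test, y_pred, n_classes)


REPORT_COLUMNS = ("method", "l_tilde", "k_tilde", "ratio", "fold",
                  "precision", "recall", "f1")


def _segment_entries(entries, manifest, fs, l_tilde, k_tilde):
    from .eeg_io import load_recording
    from .segment import SegmentationSpec, horizontal_split, SegmentBatch

    spec = SegmentationSpec(mode="horizontal", l_tilde=l_tilde, k_tilde=k_tilde)
    batches = []
    for i, entry in enumerate(entries):
        rec = load_recording(manifest, entry, fs)
        batches.append(horizontal_split(rec, spec, recording_index=i))
    return SegmentBatch.concat(batches)


def _baseline_features(batch, fs, ar_order):
    from .eeg_io import EEGRecording
    from .preproc import bandpass, extract_features, feature_matrix, zero_mean_normalize
    from .segment import SegmentBatch

    cleaned = []
    for seg in batch.segments:
        rec = EEGRecording(data=seg, fs=fs)
        rec = zero_mean_normalize(bandpass(rec))
        cleaned.append(rec.data)
    clean_batch = SegmentBatch(segments=cleaned, labels=list(batch.labels),
                               provenance=list(batch.provenance))
    feats = extract_features(clean_batch, fs=fs, p=ar_order)
    X, y_subj, _ = feature_matrix(feats)
    return X, y_subj


def run_experiment(
    manifest_path,
    methods: list[str],
    l_tildes: list[int],
    ratios: list[str],
    outdir,
    k_tildes: list[int | None] | None = None,
    folds: int = 1,
    seed: int = 0,
    ar_order: int = 6,
    train_config=None,
):
    """Run a method x l_tilde x k_tilde x ratio x fold grid for user linking.

    Each grid point segments the data, trains the requested method (the LSTM
    model or one of the named baselines on classical features) on the train
    tasks, scores held-out tasks at the segment level, and appends one TSV
    row (method, l_tilde, k_tilde, ratio, fold, precision, recall, F1).
    Returns the report path.
    """
    from pathlib import Path

    from . import esml1
    from .eeg_io import read_manifest

    manifest, fs = read_manifest(manifest_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = outdir / "report.tsv"
    k_tildes = k_tildes or [None]
    with open(report, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for method in methods:
            for l_tilde in l_tildes:
                for k_tilde in k_tildes:
                    for ratio in ratios:
                        for fold in range(folds):
                            plan = split_by_tasks(manifest, ratio, fold)
                            tr = _segment_entries(
                                plan.train_entries(manifest), manifest, fs, l_tilde, k_tilde)
                            te = _segment_entries(
                                plan.test_entries(manifest), manifest, fs, l_tilde, k_tilde)
                            if method == "esml1":
                                cfg = train_config or esml1.TrainConfig(seed=seed)
                                result = esml1.train(tr, cfg)
                                y_pred = esml1.predict_segments(result.model, te)
                                rep = macro_metrics(
                                    te.subject_ids, y_pred, manifest.n_subjects)
                            else:
                                Xtr, ytr = _baseline_features(tr, fs, ar_order)
                                Xte, yte = _baseline_features(te, fs, ar_order)
                                rep = run_baseline(method, Xtr, ytr, Xte, yte, seed=seed)
                            fh.write(
                                f"{method}\t{l_tilde}\t{k_tilde or ''}\t{ratio}\t{fold}"
                                f"\t{rep.precision:.4f}\t{rep.recall:.4f}\t{rep.f1:.4f}\n"
                            )
    return report
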