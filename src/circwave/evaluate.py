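"""Subject-wise nested stratified cross-validation and evaluation metrics.

Splitting is performed on *subjects*, stratified by class: every scan of a
subject travels with it across the outer test / inner train / inner
validation boundaries, so no patient ever contributes to both sides of any
split.  Scalar metrics follow the one-vs-rest confusion-count definitions
(sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
accuracy (TP+TN)/total, F1 2TP/(2TP+FP+FN)); multi-class values are
unweighted macro averages.  ROC areas use the conventional trapezoidal
integral of TPR over FPR; PR areas use the step integral of precision over
recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# fold plan
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Nested subject-level fold assignment.

    ``outer_test[f]`` lists the test subjects of outer fold f; ``inner[f]``
    lists per inner fold a dict with ``train``/``val`` subject lists drawn
    from outer fold f's training subjects.
    """

    K: int
    outer_test: list[list[str]]
    inner: list[list[dict]]
    seed: int

    def outer_train(self, fold: int) -> list[str]:
        test = set(self.outer_test[fold])
        all_subjects = sorted(s for lst in self.outer_test for s in lst)
        return [s for s in all_subjects if s not in test]


def _stratified_deal(subjects_by_class: dict, K: int,
                     rng: np.random.Generator) -> list[list[str]]:
    folds: list[list[str]] = [[] for _ in range(K)]
    for label in sorted(subjects_by_class):
        subs = sorted(subjects_by_class[label])
        rng.shuffle(subs)
        for i, s in enumerate(subs):
            folds[i % K].append(s)
    return folds


def make_fold_plan(manifest: pd.DataFrame, K: int = 5, seed: int = 0,
                   inner_K: int = 4) -> FoldPlan:
    """Build the nested stratified subject-wise fold plan."""
    pairs = manifest[["subject_id", "label"]].drop_duplicates()
    by_class = {lab: grp["subject_id"].tolist()
                for lab, grp in pairs.groupby("label")}
    for lab, subs in by_class.items():
        if len(subs) < K:
            raise ValueError(f"class {lab!r} has {len(subs)} subjects; "
                             f"need at least K={K}")
    rng = np.random.default_rng(seed)
    outer = _stratified_deal(by_class, K, rng)
    label_of = dict(zip(pairs["subject_id"], pairs["label"]))
    inner: list[list[dict]] = []
    for f in range(K):
        train_subjects = [s for g in range(K) if g != f for s in outer[g]]
        by_class_tr: dict[str, list[str]] = {}
        for s in train_subjects:
            by_class_tr.setdefault(label_of[s], []).append(s)
        n_inner = min(inner_K, min(len(v) for v in by_class_tr.values()))
        inner_folds = _stratified_deal(by_class_tr, n_inner, rng)
        inner.append([{"train": sorted(set(train_subjects) - set(val)),
                       "val": sorted(val)} for val in inner_folds])
    return FoldPlan(K=K, outer_test=[sorted(f) for f in outer], inner=inner,
                    seed=seed)


@dataclass
class LeakageReport:
    ok: bool
    violations: list[str] = field(default_factory=list)


def verify_no_leakage(plan: FoldPlan, manifest: pd.DataFrame) -> LeakageReport:
    """Check that outer tests partition the subjects and every nested
    train/validation/test triple is pairwise subject-disjoint."""
    violations: list[str] = []
    all_subjects = set(manifest["subject_id"])
    seen: set[str] = set()
    for f, test in enumerate(plan.outer_test):
        tset = set(test)
        if not tset:
            violations.append(f"outer fold {f}: empty test set")
        dup = tset & seen
        if dup:
            violations.append(f"outer fold {f}: subjects in several test sets: "
                              f"{sorted(dup)}")
        seen |= tset
        for g, split in enumerate(plan.inner[f]):
            tr, va = set(split["train"]), set(split["val"])
            for a, b, names in ((tr, va, "train/val"), (tr, tset, "train/test"),
                                (va, tset, "val/test")):
                bad = a & b
                if bad:
                    violations.append(f"outer {f} inner {g}: {names} overlap "
                                      f"{sorted(bad)}")
            if not tr or not va:
                violations.append(f"outer {f} inner {g}: empty split")
    missing = all_subjects - seen
    if missing:
        violations.append(f"subjects in no outer test set: {sorted(missing)}")
    extra = seen - all_subjects
    if extra:
        violations.append(f"unknown subjects in plan: {sorted(extra)}")
    return LeakageReport(ok=not violations, violations=violations)


# ---------------------------------------------------------------------------
# confusion counts and scalar metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int
    cls: str

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; defining the metric as 0",
                      stacklevel=3)
        return 0.0
    return num / den


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[idx[t], idx[p]] += 1
    return mat


def confusion_and_metrics(y_true, y_pred, classes):
    """One-vs-rest confusion counts per class plus macro-averaged scalars."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    classes = list(classes)
    mat = confusion_matrix(y_true, y_pred, classes)
    total = mat.sum()
    counts: dict[str, ConfusionCounts] = {}
    per_class: dict[str, dict[str, float]] = {}
    for i, c in enumerate(classes):
        tp = int(mat[i, i])
        fn = int(mat[i].sum() - tp)
        fp = int(mat[:, i].sum() - tp)
        tn = int(total - tp - fn - fp)
        counts[c] = cc = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn, cls=c)
        per_class[c] = {
            "ACC": _safe_div(cc.TP + cc.TN, cc.total, f"ACC[{c}]"),
            "SE": _safe_div(cc.TP, cc.TP + cc.FN, f"SE[{c}]"),
            "SP": _safe_div(cc.TN, cc.TN + cc.FP, f"SP[{c}]"),
            "PR": _safe_div(cc.TP, cc.TP + cc.FP, f"PR[{c}]"),
            "F1": _safe_div(2 * cc.TP, 2 * cc.TP + cc.FP + cc.FN, f"F1[{c}]"),
        }
    macro = {m: float(np.mean([per_class[c][m] for c in classes]))
             for m in ("ACC", "SE", "SP", "PR", "F1")}
    macro["multiclass_ACC"] = float(np.trace(mat)) / total if total else 0.0
    return counts, {"macro": macro, "per_class": per_class, "confusion": mat,
                    "classes": classes}


def metrics_from_counts(cc: ConfusionCounts) -> dict[str, float]:
    """Scalar metrics from one hand-built one-vs-rest confusion count."""
    return {
        "ACC": _safe_div(cc.TP + cc.TN, cc.total, "ACC"),
        "SE": _safe_div(cc.TP, cc.TP + cc.FN, "SE"),
        "SP": _safe_div(cc.TN, cc.TN + cc.FP, "SP"),
        "PR": _safe_div(cc.TP, cc.TP + cc.FP, "PR"),
        "F1": _safe_div(2 * cc.TP, 2 * cc.TP + cc.FP + cc.FN, "F1"),
    }


# ---------------------------------------------------------------------------
# ROC / PR curves
# ---------------------------------------------------------------------------

def _binary_roc(y: np.ndarray, s: np.ndarray):
    order = np.argsort(-s, kind="stable")
    y = y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # collapse ties on the score value
    distinct = np.r_[np.diff(s[order]) != 0, True]
    tps, fps = tps[distinct], fps[distinct]
    tpr = np.r_[0.0, tps / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps / max(fps[-1], 1)]
    return fpr, tpr


def _binary_pr(y: np.ndarray, s: np.ndarray):
    order = np.argsort(-s, kind="stable")
    y = y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    distinct = np.r_[np.diff(s[order]) != 0, True]
    tps, fps = tps[distinct], fps[distinct]
    precision = tps / (tps + fps)
    recall = tps / max(tps[-1], 1)
    return np.r_[0.0, recall], np.r_[1.0, precision]


def roc_pr_curves(y_true, scores, classes) -> dict:
    """One-vs-rest ROC and PR curves with their areas, per class + macro."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    classes = list(classes)
    if scores.shape != (len(y_true), len(classes)):
        raise ValueError("scores must be N x n_classes, row-aligned with labels")
    out: dict = {"per_class": {}, "classes": classes}
    roaucs, praucs = [], []
    for i, c in enumerate(classes):
        y = (y_true == c).astype(int)
        if y.sum() == 0:
            warnings.warn(f"class {c!r} absent from y_true; skipped", stacklevel=2)
            continue
        fpr, tpr = _binary_roc(y, scores[:, i])
        roauc = float(np.trapezoid(tpr, fpr))
        recall, precision = _binary_pr(y, scores[:, i])
        prauc = float(np.sum(np.diff(recall) * precision[1:]))
        out["per_class"][c] = {"fpr": fpr, "tpr": tpr, "ROAUC": roauc,
                               "recall": recall, "precision": precision,
                               "PRAUC": prauc}
        roaucs.append(roauc)
        praucs.append(prauc)
    out["macro_ROAUC"] = float(np.mean(roaucs)) if roaucs else float("nan")
    out["macro_PRAUC"] = float(np.mean(praucs)) if praucs else float("nan")
    return out


# ---------------------------------------------------------------------------
# the full experiment loop
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-fold and averaged metrics of one cross-validated experiment."""

    per_fold: list[dict]
    mean: dict[str, float]
    per_class_accuracy: dict[str, float]
    confusion: np.ndarray
    classes: list[str]
    curves: dict | None = None

    @property
    def macro_accuracy(self) -> float:
        return self.mean["ACC"]


@dataclass
class ExperimentConfig:
    """Configuration of one end-to-end phantom study."""

    transform: str = "circwave"
    transform_params: dict = field(default_factory=dict)
    head: str = "msvm"
    K: int = 5
    inner_K: int = 4
    side: int = 64
    preprocess_profile: str = "phantom"
    cnn_epochs: int = 12
    svm_kernel: str = "rbf"
    seeds: dict = field(default_factory=lambda: {"data": 0, "folds": 1,
                                                 "cnn": 2, "head": 3})


@dataclass
class ExperimentResult:
    report: MetricsReport
    plan: FoldPlan
    config: ExperimentConfig
    fold_models: list | None = None
    fold_features: list | None = None
    scan_scores: np.ndarray | None = None
    scan_true: np.ndarray | None = None
    scan_index: np.ndarray | None = None


def prepare_stacks(images: np.ndarray, transform: str, side: int = 64,
                   **params) -> np.ndarray:
    """Transform a batch of preprocessed images into resized sub-band stacks."""
    from .transforms import transform_image

    stacks = [transform_image(img, transform, side=side, **params).data
              for img in images]
    return np.stack(stacks).astype(np.float32)


def run_cv(stacks: np.ndarray, labels: np.ndarray, subjects: np.ndarray,
           plan: FoldPlan, config: ExperimentConfig,
           keep_artifacts: bool = False) -> ExperimentResult:
    """Nested cross-validated train/evaluate loop on prepared stacks.

    Per outer fold: the CNN is trained end-to-end on the first inner split
    (train vs validation, best-validation checkpoint), frozen, and used to
    extract features; the classifier head is tuned on the inner folds and
    refit on the outer-train features; the outer-test scans are scored once.
    """
    from .classify import (MlpConfig, SvmConfig, msvm_fit, predict_scores,
                           train_mlp)
    from .features import CnnConfig, build_feature_cnn, extract_features, train_cnn

    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    classes = sorted(set(labels))
    per_fold, models, feats = [], [], []
    all_scores, all_true, all_pred, all_idx = [], [], [], []
    for f in range(plan.K):
        test_mask = np.isin(subjects, plan.outer_test[f])
        split0 = plan.inner[f][0]
        tr_mask = np.isin(subjects, split0["train"])
        va_mask = np.isin(subjects, split0["val"])
        cnn_cfg = CnnConfig(max_epochs=config.cnn_epochs,
                            seed=int(config.seeds.get("cnn", 0)) + f)
        model = build_feature_cnn(stacks.shape[-1], n_classes=len(classes),
                                  config=cnn_cfg)
        train_cnn(model, stacks[tr_mask], labels[tr_mask], stacks[va_mask],
                  labels[va_mask], classes,
                  train_subjects=subjects[tr_mask],
                  val_subjects=subjects[va_mask])
        outer_train_mask = tr_mask | va_mask
        train_features = extract_features(model, stacks[outer_train_mask],
                                          labels[outer_train_mask],
                                          subjects[outer_train_mask])
        test_features = extract_features(model, stacks[test_mask],
                                         labels[test_mask],
                                         subjects[test_mask])
        head_seed = int(config.seeds.get("head", 0)) + f
        if config.head == "msvm":
            inner_pairs = [(s["train"], s["val"]) for s in plan.inner[f]]
            clf = msvm_fit(train_features, None, None,
                           SvmConfig(kernel=config.svm_kernel, seed=head_seed),
                           inner_folds=inner_pairs)
        elif config.head == "mlp":
            clf = train_mlp(train_features,
                            config=MlpConfig(max_epochs=config.cnn_epochs,
                                             n_classes=len(classes),
                                             seed=head_seed),
                            classes=classes)
        else:
            raise ValueError(f"unknown head {config.head!r}")
        scores = predict_scores(clf, test_features)
        pred = np.asarray(classes)[scores.argmax(1)]
        _, fold_metrics = confusion_and_metrics(labels[test_mask], pred, classes)
        per_fold.append(fold_metrics)
        all_scores.append(scores)
        all_true.append(labels[test_mask])
        all_pred.append(pred)
        all_idx.append(np.flatnonzero(test_mask))
        if keep_artifacts:
            models.append((model, clf))
            feats.append((train_features, test_features))
    mean = {m: float(np.mean([pf["macro"][m] for pf in per_fold]))
            for m in ("ACC", "SE", "SP", "PR", "F1")}
    mean["multiclass_ACC"] = float(np.mean([pf["macro"]["multiclass_ACC"]
                                            for pf in per_fold]))
    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    scores = np.concatenate(all_scores)
    _, pooled = confusion_and_metrics(y_true, y_pred, classes)
    curves = roc_pr_curves(y_true, scores, classes)
    mean["ROAUC"] = curves["macro_ROAUC"]
    mean["PRAUC"] = curves["macro_PRAUC"]
    report = MetricsReport(
        per_fold=per_fold, mean=mean,
        per_class_accuracy={c: pooled["per_class"][c]["ACC"] for c in classes},
        confusion=pooled["confusion"], classes=classes, curves=curves)
    return ExperimentResult(report=report, plan=plan, config=config,
                            fold_models=models if keep_artifacts else None,
                            fold_features=feats if keep_artifacts else None,
                            scan_scores=scores, scan_true=y_true,
                            scan_index=np.concatenate(all_idx))


def run_experiment(spec=None, config: ExperimentConfig | None = None,
                   keep_artifacts: bool = False,
                   dataset=None) -> ExperimentResult:
    """Full phantom study: generate -> preprocess -> transform -> nested CV.

    ``dataset`` may carry a pre-generated ``(manifest, images)`` pair (images
    already preprocessed) to share the expensive stages across transform
    arms; otherwise it is generated from ``spec``.
    """
    from .phantom import PhantomSpec, generate_dataset
    from .preprocess import preprocess_bscan

    config = config or ExperimentConfig()
    if dataset is None:
        spec = spec or PhantomSpec(seed=int(config.seeds.get("data", 0)))
        manifest, scans = generate_dataset(spec)
        images = np.stack([
            preprocess_bscan(s.image, profile=config.preprocess_profile).image
            for s in scans])
    else:
        manifest, images = dataset
    stacks = prepare_stacks(images, config.transform, side=config.side,
                            **config.transform_params)
    plan = make_fold_plan(manifest, K=config.K,
                          seed=int(config.seeds.get("folds", 0)),
                          inner_K=config.inner_K)
    leaks = verify_no_leakage(plan, manifest)
    if not leaks.ok:
        raise RuntimeError(f"fold plan failed the leakage check: {leaks.violations}")
    labels = manifest["label"].to_numpy()
    subjects = manifest["subject_id"].to_numpy()
    return run_cv(stacks, labels, subjects, plan, config,
                  keep_artifacts=keep_artifacts)
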