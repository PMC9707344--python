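"""Normal-vs-abnormal classification, PCA projection, feature importance, and
the subject-wise intra/inter-class distance analysis.

Recordings are rows of a :class:`FeatureTable`; models never see information
from their test folds: median imputation and z-scoring are fitted on the
training folds only, inside a per-fold pipeline.  Two split schemes are
supported — *video* (stratified folds over recordings) and *subject* (folds
over subjects, so no subject spans train and test), the latter measuring
generalization to unseen people.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

try:  # optional; the remaining models cover the same family
    from xgboost import XGBClassifier

    _HAS_XGB = True
except ImportError:  # pragma: no cover
    _HAS_XGB = False

from .skeleton import Test

POSITIVE = "abnormal"


@dataclass
class FeatureTable:
    """Feature matrix plus labels and subject ids for one test."""

    features: pd.DataFrame  # numeric columns only
    labels: np.ndarray      # "normal" / "abnormal"
    subject_ids: np.ndarray
    test: Test

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if len(self.features) != len(self.labels) or len(self.labels) != len(self.subject_ids):
            raise ValueError("features, labels and subject_ids must align")
        all_missing = [c for c in self.features.columns if self.features[c].isna().all()]
        if all_missing:
            raise ValueError(f"all-missing feature columns: {all_missing}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        """Build from a table written by ``write_feature_table``."""
        meta = ["subject_id", "test", "label", "device"]
        feat_cols = [c for c in df.columns if c not in meta]
        tests = df["test"].unique()
        if len(tests) != 1:
            raise ValueError(f"feature table mixes tests: {tests}")
        return cls(
            features=df[feat_cols].apply(pd.to_numeric, errors="coerce"),
            labels=df["label"].to_numpy(),
            subject_ids=df["subject_id"].to_numpy(),
            test=Test(tests[0]),
        )

    @property
    def y(self) -> np.ndarray:
        return (self.labels == POSITIVE).astype(int)


def default_models(seed: int = 0) -> dict[str, object]:
    """The classifier zoo: tree ensembles and gradient-trained parametric models."""
    models = {
        "rf": RandomForestClassifier(n_estimators=500, random_state=seed),
        "gbm": GradientBoostingClassifier(
            n_estimators=200, max_depth=3, learning_rate=0.1, random_state=seed
        ),
        "lr": LogisticRegression(penalty="l2", C=1.0, max_iter=2000, random_state=seed),
        "rsvm": SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed),
        "mlp": MLPClassifier(
            hidden_layer_sizes=(64,),
            activation="relu",
            max_iter=500,
            early_stopping=True,
            random_state=seed,
        ),
    }
    if _HAS_XGB:
        models["xgb"] = XGBClassifier(
            n_estimators=200,
            max_depth=3,
            learning_rate=0.1,
            random_state=seed,
            eval_metric="logloss",
        )
    return models


def make_splits(table: FeatureTable, scheme: str, n_folds: int = 5, seed: int = 0):
    """Fold assignments as (train_idx, test_idx) pairs.

    ``video``: stratified-by-label folds over recordings.  ``subject``: folds
    over subjects, every recording of a subject on the same side of the split
    (with 20 subjects and 5 folds: 16 train / 4 test subjects per fold).
    """
    if scheme == "video":
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(skf.split(np.zeros(len(table.labels)), table.y))
    if scheme == "subject":
        subjects = np.unique(table.subject_ids)
        if len(subjects) < n_folds:
            raise ValueError(f"subject scheme needs >= {n_folds} subjects, got {len(subjects)}")
        rng = np.random.default_rng(seed)
        order = rng.permutation(subjects)
        groups = np.array_split(order, n_folds)
        splits = []
        for g in groups:
            test_mask = np.isin(table.subject_ids, g)
            splits.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
        return splits
    raise ValueError(f"unknown split scheme {scheme!r}")


def _pipeline(model) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("model", model),
        ]
    )


@dataclass
class EvalReport:
    """Fold-averaged metrics per model."""

    metrics: dict[str, dict[str, float]]
    split_scheme: str
    n_folds: int
    seed: int
    warnings: list[str] = field(default_factory=list)

    def best(self, metric: str = "accuracy") -> tuple[str, float]:
        name = max(self.metrics, key=lambda m: self.metrics[m][metric])
        return name, self.metrics[name][metric]


def _fold_metrics(y_true, y_pred, y_score) -> dict[str, float]:
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    acc = (tp + tn) / max(tp + tn + fp + fn, 1)
    prec = tp / (tp + fp) if tp + fp else np.nan
    rec = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    f1 = 2 * prec * rec / (prec + rec) if prec and rec and np.isfinite(prec + rec) and prec + rec > 0 else np.nan
    out = {"accuracy": acc, "precision": prec, "recall": rec, "specificity": spec, "f1": f1}
    if len(np.unique(y_true)) == 2:
        out["auc"] = roc_auc_score(y_true, y_score)
        out["average_precision"] = average_precision_score(y_true, y_score)
    else:
        out["auc"] = np.nan
        out["average_precision"] = np.nan
    return out


def train_eval(
    table: FeatureTable,
    models: dict[str, object] | None = None,
    splits=None,
    scheme: str = "subject",
    n_folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Cross-validated evaluation of each model; metrics averaged over folds."""
    models = models if models is not None else default_models(seed)
    if splits is None:
        splits = make_splits(table, scheme, n_folds, seed)
    X = table.features.to_numpy(dtype=float)
    y = table.y
    report = EvalReport(metrics={}, split_scheme=scheme, n_folds=len(splits), seed=seed)
    for name, model in models.items():
        per_fold = []
        for k, (tr, te) in enumerate(splits):
            if len(np.unique(y[tr])) < 2:
                report.warnings.append(f"{name}: fold {k} skipped (single-class training set)")
                continue
            pipe = _pipeline(model)
            pipe.fit(X[tr], y[tr])
            pred = pipe.predict(X[te])
            try:
                score = pipe.predict_proba(X[te])[:, 1]
            except AttributeError:
                score = pipe.decision_function(X[te])
            per_fold.append(_fold_metrics(y[te], pred, score))
        if per_fold:
            keys = per_fold[0].keys()
            report.metrics[name] = {
                k: float(np.nanmean([m[k] for m in per_fold])) for k in keys
            }
    return report


def pca_project(table: FeatureTable, k: int = 2):
    """Top-k principal-component coordinates of the z-scored features.

    Component signs are fixed by making each component's largest-magnitude
    loading positive, so results are deterministic.
    Returns (coords [n, k], explained_variance_ratio [k]).
    """
    X = table.features.to_numpy(dtype=float)
    X = SimpleImputer(strategy="median").fit_transform(X)
    X = StandardScaler().fit_transform(X)
    keep = np.std(X, axis=0) > 0
    X = X[:, keep]
    if X.shape[1] < 1:
        raise ValueError("no non-constant features")
    pca = PCA(n_components=min(k, X.shape[1], X.shape[0]))
    coords = pca.fit_transform(X)
    for j in range(pca.components_.shape[0]):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1
    return coords, pca.explained_variance_ratio_


def feature_importance(table: FeatureTable, seed: int = 0) -> pd.Series:
    """Impurity-based random-forest importances on the full table, descending."""
    X = SimpleImputer(strategy="median").fit_transform(table.features.to_numpy(dtype=float))
    rf = RandomForestClassifier(n_estimators=500, random_state=seed)
    rf.fit(X, table.y)
    s = pd.Series(rf.feature_importances_, index=table.features.columns)
    return s.sort_values(ascending=False)


def pairwise_distance_analysis(df: pd.DataFrame, feature_subset=None) -> pd.DataFrame:
    """Subject-wise intra/inter-class feature distances across two devices.

    Each subject contributes four recordings: normal and abnormal on each of
    two devices.  Per feature and subject: A-A is the distance between the two
    abnormal recordings, N-N between the two normal ones, and N-A the average
    of the two cross pairs; all are divided by the maximum N-A across subjects
    for that feature, so a feature robust to the device change shows A-A and
    N-N concentrated near zero well below N-A.

    ``df`` must carry subject_id, label, device and feature columns.  Returns
    a long DataFrame with columns (feature, subject_id, kind, distance).
    """
    meta = ["subject_id", "test", "label", "device"]
    feats = feature_subset or [c for c in df.columns if c not in meta]
    devices = sorted(df["device"].unique())
    if len(devices) != 2:
        raise ValueError(f"need exactly 2 devices, got {devices}")
    d0, d1 = devices
    rows = []
    for feat in feats:
        per_subject = []
        for sid, grp in df.groupby("subject_id"):
            def pick(label, device):
                sel = grp[(grp["label"] == label) & (grp["device"] == device)]
                if len(sel) != 1 or not np.isfinite(sel[feat].iloc[0]):
                    return None
                return float(sel[feat].iloc[0])

            n0, n1 = pick("normal", d0), pick("normal", d1)
            a0, a1 = pick("abnormal", d0), pick("abnormal", d1)
            if None in (n0, n1, a0, a1):
                continue  # subject skipped for this feature
            per_subject.append(
                (sid, abs(a1 - a0), abs(n1 - n0), 0.5 * (abs(a1 - n0) + abs(n1 - a0)))
            )
        if not per_subject:
            continue
        na_max = max(p[3] for p in per_subject)
        if na_max <= 0:
            continue
        for sid, aa, nn, na in per_subject:
            rows.append({"feature": feat, "subject_id": sid, "kind": "A-A", "distance": aa / na_max})
            rows.append({"feature": feat, "subject_id": sid, "kind": "N-N", "distance": nn / na_max})
            rows.append({"feature": feat, "subject_id": sid, "kind": "N-A", "distance": na / na_max})
    return pd.DataFrame(rows)
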