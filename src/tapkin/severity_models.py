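"""Severity prediction: multiclass, ordinal-binary, and tiered-binary schemes.

All three schemes share the same scaffolding: a stratified 70/30 split,
z-score normalization fit on training rows only, class balancing of the
training rows (random under-sampling of majority classes to the median class
count followed by SMOTE-style synthetic oversampling of minorities), recursive
feature elimination driven by cross-validated f1, and L2-penalized logistic
regression.  They differ in how rows are relabeled and routed:

* multiclass — one 4-class model over scores 0-3;
* ordinal    — three cumulative dichotomies (0|123, 01|23, 012|3), final
  score = number of models voting above threshold;
* tiered     — a cascade: control vs patient, then (patients only)
  score 1 vs {2,3}, then score 2 vs 3; each tier is trained only on the rows
  it can ever see and selects its own features.

Fitted bundles are plain-JSON serializable; prediction is pure numpy over the
stored coefficients, so a serialized round trip is exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from .errors import (
    CannotSynthesizeError,
    SchemaError,
    StratificationError,
    TierDegeneracyError,
    UndefinedMetricError,
    UsageError,
)
from .features import COVARIATE_NAMES, FEATURE_NAMES

CANDIDATE_FEATURES: list[str] = FEATURE_NAMES + COVARIATE_NAMES  # fixed canonical order
DECISION_THRESHOLD = 0.5  # ties go to the lower-severity branch

SCHEMES = ("multiclass", "ordinal", "tiered")


@dataclass(frozen=True)
class SplitProtocol:
    test_fraction: float = 0.3
    n_folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise UsageError(f"test_fraction must be in (0,1), got {self.test_fraction}")
        if self.n_folds < 2:
            raise UsageError(f"n_folds must be >= 2, got {self.n_folds}")


@dataclass(frozen=True)
class TierSpec:
    """One stage of the tiered cascade."""

    tier_id: int
    name: str
    # row is eligible for this tier's training set
    row_filter: str  # "all" | "score>=1" | "score in {2,3}"
    positive_label: str  # human-readable description of the positive class

    def select_rows(self, score: np.ndarray, is_control: np.ndarray) -> np.ndarray:
        if self.row_filter == "all":
            return np.ones(score.shape, bool)
        if self.row_filter == "score>=1":
            return score >= 1
        if self.row_filter == "score in {2,3}":
            return np.isin(score, (2, 3))
        raise UsageError(f"unknown row filter {self.row_filter}")

    def labels(self, score: np.ndarray, is_control: np.ndarray) -> np.ndarray:
        if self.tier_id == 1:
            return (~is_control).astype(int)  # patient = positive
        if self.tier_id == 2:
            return (score >= 2).astype(int)
        if self.tier_id == 3:
            return (score == 3).astype(int)
        raise UsageError(f"unknown tier {self.tier_id}")


TIER_SPECS: list[TierSpec] = [
    TierSpec(1, "control_vs_patient", "all", "patient"),
    TierSpec(2, "score1_vs_23", "score>=1", "score 2 or 3"),
    TierSpec(3, "score2_vs_3", "score in {2,3}", "score 3"),
]


@dataclass
class MetricsReport:
    """Per-model PR-AUC/f1 and overall per-class recall + confusion matrix."""

    per_model: dict = field(default_factory=dict)
    per_class_accuracy: dict = field(default_factory=dict)
    confusion_matrix: list = field(default_factory=list)
    class_labels: list = field(default_factory=list)
    macro_accuracy: float = float("nan")
    n_nonmonotone_votes: int | None = None  # ordinal scheme only

    def as_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        lines = []
        for name, m in self.per_model.items():
            lines.append(
                f"{name}: PR-AUC={m['pr_auc']:.3f}  f1={m['f1']:.3f}  "
                f"features={', '.join(m['selected_features'])}"
            )
        lines.append("per-class accuracy: " + "  ".join(
            f"{k}: {v:.1%}" for k, v in self.per_class_accuracy.items()))
        lines.append(f"macro accuracy: {self.macro_accuracy:.1%}")
        return "\n".join(lines)


@dataclass
class SeverityModelBundle:
    """A fitted scheme: scaler statistics, per-model features and coefficients."""

    scheme: str
    feature_names: list[str]  # canonical candidate order used for scaling
    scaler_mean: list[float]
    scaler_sd: list[float]
    models: list[dict]  # each: {name, features, coef, intercept, classes}
    protocol: dict
    train_ids: list
    metrics: MetricsReport | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "scheme": self.scheme,
            "feature_names": self.feature_names,
            "scaler_mean": self.scaler_mean,
            "scaler_sd": self.scaler_sd,
            "models": self.models,
            "protocol": self.protocol,
            "train_ids": self.train_ids,
            "metrics": self.metrics.as_dict() if self.metrics else None,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SeverityModelBundle":
        if isinstance(source, Path) or (len(str(source)) < 4096 and Path(str(source)).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        metrics = payload.get("metrics")
        return cls(
            scheme=payload["scheme"],
            feature_names=payload["feature_names"],
            scaler_mean=payload["scaler_mean"],
            scaler_sd=payload["scaler_sd"],
            models=payload["models"],
            protocol=payload["protocol"],
            train_ids=payload["train_ids"],
            metrics=MetricsReport(**metrics) if metrics else None,
        )

    # --- prediction plumbing -------------------------------------------------
    def _scale(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise SchemaError(f"missing feature column(s): {missing}")
        X = table[self.feature_names].to_numpy(dtype=float)
        return (X - np.asarray(self.scaler_mean)) / np.asarray(self.scaler_sd)

    def model_probability(self, model_idx: int, table: pd.DataFrame) -> np.ndarray:
        """Positive-class probability of one constituent binary model."""
        m = self.models[model_idx]
        Xs = self._scale(table)
        cols = [self.feature_names.index(f) for f in m["features"]]
        z = Xs[:, cols] @ np.asarray(m["coef"][0]) + m["intercept"][0]
        return 1.0 / (1.0 + np.exp(-z))

    def multiclass_probabilities(self, table: pd.DataFrame) -> np.ndarray:
        m = self.models[0]
        Xs = self._scale(table)
        cols = [self.feature_names.index(f) for f in m["features"]]
        coef = np.asarray(m["coef"])
        z = Xs[:, cols] @ coef.T + np.asarray(m["intercept"])
        if coef.shape[0] == 1 and len(m["classes"]) == 2:  # binary degenerate case
            p1 = 1.0 / (1.0 + np.exp(-z[:, 0]))
            return np.column_stack([1.0 - p1, p1])
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# class balancing (random under-sample to median count, then SMOTE up)
# --------------------------------------------------------------------------

def balance_classes(
    X: np.ndarray, y: np.ndarray, seed: int = 0, k_neighbors: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts at the median original count.

    Majority classes are randomly under-sampled; minority classes are grown
    with SMOTE-style interpolation: each synthetic point lies uniformly on the
    segment between a random class member and one of its k nearest same-class
    neighbors (k = min(k_neighbors, class size - 1)).  Deterministic under
    ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise UsageError("balance_classes needs at least 2 classes")
    if (counts < 2).any():
        bad = classes[counts < 2]
        raise CannotSynthesizeError(f"class(es) {bad.tolist()} have fewer than 2 rows")
    target = int(round(float(np.median(counts))))
    rng = np.random.default_rng(seed)
    out_X, out_y = [], []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        Xc = X[idx]
        n = idx.size
        if n > target:
            keep = rng.choice(n, size=target, replace=False)
            keep.sort()
            Xc = Xc[keep]
        elif n < target:
            k = min(k_neighbors, n - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, neigh = nn.kneighbors(Xc)  # col 0 is the point itself
            n_new = target - n
            base = rng.integers(0, n, size=n_new)
            pick = rng.integers(0, k, size=n_new)
            partner = neigh[base, 1 + pick]
            lam = rng.random(n_new)
            synth = Xc[base] + lam[:, None] * (Xc[partner] - Xc[base])
            Xc = np.vstack([Xc, synth])
        out_X.append(Xc)
        out_y.append(np.full(len(Xc), cls, dtype=y.dtype))
    return np.vstack(out_X), np.concatenate(out_y)


# --------------------------------------------------------------------------
# recursive feature elimination
# --------------------------------------------------------------------------

def _make_logistic(seed: int, n_classes: int) -> LogisticRegression:
    # default penalty is an L2 ridge at strength C=1
    return LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000, random_state=seed)


def _cv_f1_and_coefs(
    X: np.ndarray, y: np.ndarray, feature_idx: list[int], n_folds: int, seed: int
) -> tuple[float, np.ndarray]:
    """Mean macro-f1 and mean |standardized coefficient| across CV folds."""
    from sklearn.metrics import f1_score

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    f1s, coefs = [], []
    Xf = X[:, feature_idx]
    for tr, te in skf.split(Xf, y):
        if np.unique(y[tr]).size < 2:
            raise StratificationError("a CV training fold contains a single class")
        clf = _make_logistic(seed, np.unique(y).size)
        clf.fit(Xf[tr], y[tr])
        pred = clf.predict(Xf[te])
        f1s.append(f1_score(y[te], pred, average="macro", zero_division=0))
        coefs.append(np.abs(clf.coef_).mean(axis=0))
    return float(np.mean(f1s)), np.mean(coefs, axis=0)


def rfe_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    n_folds: int = 5,
    epsilon: float = 0.005,
    seed: int = 0,
) -> list[str]:
    """Drop least-influential features while CV f1 does not degrade.

    At each step the feature with the smallest mean absolute coefficient
    across folds is removed (ties broken toward the feature latest in the
    canonical order); elimination continues while the cross-validated macro
    f1 drops by no more than ``epsilon`` from the previous accepted set.
    """
    if len(feature_names) < 3:
        raise UsageError("rfe_select needs at least 3 candidate features")
    current = list(range(len(feature_names)))
    score_cur, coefs = _cv_f1_and_coefs(X, y, current, n_folds, seed)
    while len(current) > 1:
        # smallest |coef|; on ties prefer dropping the later canonical position
        order = np.lexsort((-np.array(current), coefs))
        drop_pos = int(order[0])
        trial = current[:drop_pos] + current[drop_pos + 1 :]
        score_trial, coefs_trial = _cv_f1_and_coefs(X, y, trial, n_folds, seed)
        if score_trial >= score_cur - epsilon:
            current = trial
            score_cur = score_trial
            coefs = coefs_trial
        else:
            break
    return [feature_names[i] for i in current]


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _check_table(table: pd.DataFrame, scheme: str) -> None:
    missing = [c for c in CANDIDATE_FEATURES + ["score"] if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing column(s): {missing}")
    if scheme == "tiered" and "is_control" not in table.columns:
        raise SchemaError("tiered scheme requires an is_control column")


def fit_scheme(
    table: pd.DataFrame,
    scheme: str,
    protocol: SplitProtocol = SplitProtocol(),
    rfe_epsilon: float = 0.005,
) -> SeverityModelBundle:
    """Fit one of the three schemes end to end and evaluate on the held-out split.

    All training-derived state (scaler statistics, balanced rows, selected
    features, coefficients) is computed from the 70% training rows only; the
    30% test rows are touched exclusively by the final evaluation.
    """
    if scheme not in SCHEMES:
        raise UsageError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    _check_table(table, scheme)

    y_all = table["score"].to_numpy(dtype=int)
    ids = np.asarray(table.index)
    strat = y_all if protocol.stratified else None
    train_ids, test_ids = train_test_split(
        ids, test_size=protocol.test_fraction, stratify=strat, random_state=protocol.seed
    )
    train = table.loc[train_ids]
    test = table.loc[test_ids]

    X_train = train[CANDIDATE_FEATURES].to_numpy(dtype=float)
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs_train = (X_train - mean) / sd

    score_tr = train["score"].to_numpy(dtype=int)
    ctrl_tr = (
        train["is_control"].to_numpy(dtype=bool)
        if "is_control" in train.columns
        else score_tr == 0
    )

    models: list[dict] = []
    if scheme == "multiclass":
        models.append(_fit_constituent(
            "multiclass", Xs_train, score_tr, protocol, rfe_epsilon))
    elif scheme == "ordinal":
        for th in (0, 1, 2):
            labels = (score_tr > th).astype(int)
            models.append(_fit_constituent(
                f"score<={th}_vs_above", Xs_train, labels, protocol, rfe_epsilon))
    else:  # tiered
        for spec in TIER_SPECS:
            rows = spec.select_rows(score_tr, ctrl_tr)
            labels = spec.labels(score_tr[rows], ctrl_tr[rows])
            if np.unique(labels).size < 2:
                raise TierDegeneracyError(
                    f"tier {spec.tier_id} training subset has a single class"
                )
            models.append(_fit_constituent(
                spec.name, Xs_train[rows], labels, protocol, rfe_epsilon))

    bundle = SeverityModelBundle(
        scheme=scheme,
        feature_names=list(CANDIDATE_FEATURES),
        scaler_mean=mean.tolist(),
        scaler_sd=sd.tolist(),
        models=models,
        protocol=asdict(protocol),
        train_ids=[_jsonable(i) for i in train_ids],
    )
    bundle.metrics = evaluate(bundle, test)
    return bundle


def _jsonable(x):
    return x.item() if isinstance(x, np.generic) else x


def _fit_constituent(
    name: str,
    Xs: np.ndarray,
    labels: np.ndarray,
    protocol: SplitProtocol,
    rfe_epsilon: float,
) -> dict:
    Xb, yb = balance_classes(Xs, labels, seed=protocol.seed)
    selected = rfe_select(
        Xb, yb, CANDIDATE_FEATURES, n_folds=protocol.n_folds,
        epsilon=rfe_epsilon, seed=protocol.seed,
    )
    cols = [CANDIDATE_FEATURES.index(f) for f in selected]
    clf = _make_logistic(protocol.seed, np.unique(yb).size)
    clf.fit(Xb[:, cols], yb)
    return {
        "name": name,
        "features": selected,
        "coef": clf.coef_.tolist(),
        "intercept": clf.intercept_.tolist(),
        "classes": clf.classes_.tolist(),
    }


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

def route_tiered(probs: np.ndarray, threshold: float = DECISION_THRESHOLD) -> np.ndarray:
    """Cascade routing rule over per-tier positive probabilities (n, 3).

    Tier-1 probability <= threshold stops at score 0; otherwise tier 2
    decides between score 1 (<= threshold) and higher, and tier 3 between
    2 and 3.  Ties at the threshold go to the lower-severity branch.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    scores = np.zeros(probs.shape[0], dtype=int)
    pd_mask = probs[:, 0] > threshold
    hi_mask = pd_mask & (probs[:, 1] > threshold)
    scores[pd_mask] = 1
    scores[hi_mask] = 2
    scores[hi_mask & (probs[:, 2] > threshold)] = 3
    return scores


def route_ordinal(probs: np.ndarray, threshold: float = DECISION_THRESHOLD) -> np.ndarray:
    """Cumulative-dichotomy sum rule: score = number of above-threshold votes."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    return (probs > threshold).sum(axis=1).astype(int)


def predict_tiered(bundle: SeverityModelBundle, table: pd.DataFrame):
    """Route rows through the cascade; returns (scores, per-tier probabilities)."""
    if bundle.scheme != "tiered":
        raise UsageError(f"bundle scheme is {bundle.scheme!r}, expected 'tiered'")
    probs = np.column_stack([bundle.model_probability(i, table) for i in range(3)])
    return route_tiered(probs), probs


def predict_ordinal(bundle: SeverityModelBundle, table: pd.DataFrame):
    """Cumulative-dichotomy aggregation: score = number of above-threshold votes.

    Returns (scores, votes); non-monotone vote patterns (e.g. 1,0,1) are
    resolved by the same sum rule and can be counted from ``votes``.
    """
    if bundle.scheme != "ordinal":
        raise UsageError(f"bundle scheme is {bundle.scheme!r}, expected 'ordinal'")
    probs = np.column_stack([bundle.model_probability(i, table) for i in range(3)])
    votes = (probs > DECISION_THRESHOLD).astype(int)
    return route_ordinal(probs), votes


def predict_multiclass(bundle: SeverityModelBundle, table: pd.DataFrame):
    if bundle.scheme != "multiclass":
        raise UsageError(f"bundle scheme is {bundle.scheme!r}, expected 'multiclass'")
    probs = bundle.multiclass_probabilities(table)
    classes = np.asarray(bundle.models[0]["classes"])
    return classes[np.argmax(probs, axis=1)], probs


def predict(bundle: SeverityModelBundle, table: pd.DataFrame) -> np.ndarray:
    if bundle.scheme == "tiered":
        return predict_tiered(bundle, table)[0]
    if bundle.scheme == "ordinal":
        return predict_ordinal(bundle, table)[0]
    return predict_multiclass(bundle, table)[0]


def count_nonmonotone_votes(votes: np.ndarray) -> int:
    """Number of rows whose cumulative votes are not of the form 1..10..0."""
    diffs = np.diff(votes.astype(int), axis=1)
    return int((diffs > 0).any(axis=1).sum())


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray, labels: list) -> np.ndarray:
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    pos = {lab: i for i, lab in enumerate(labels)}
    for t, p in zip(y_true, y_pred):
        cm[pos[t], pos[p]] += 1
    return cm


def binary_prf(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """Precision, recall, f1 of the positive (1) class; 0 when undefined."""
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def evaluate(bundle: SeverityModelBundle, test: pd.DataFrame) -> MetricsReport:
    """PR-AUC and f1 per constituent model plus overall per-class recall.

    ``test`` must be disjoint (by index) from the bundle's training rows.
    """
    overlap = set(bundle.train_ids) & {_jsonable(i) for i in test.index}
    if overlap:
        raise UsageError(f"test rows overlap training rows: {sorted(overlap)[:5]} ...")
    y_true = test["score"].to_numpy(dtype=int)
    if np.unique(y_true).size < 2:
        raise UndefinedMetricError("test set contains a single class; metrics undefined")
    ctrl = (
        test["is_control"].to_numpy(dtype=bool)
        if "is_control" in test.columns
        else y_true == 0
    )

    report = MetricsReport()
    if bundle.scheme == "multiclass":
        y_pred, probs = predict_multiclass(bundle, test)
        classes = [int(c) for c in bundle.models[0]["classes"]]
        aucs, weights = [], []
        for j, cls in enumerate(classes):
            pos = (y_true == cls).astype(int)
            if pos.sum() in (0, len(pos)):
                continue
            aucs.append(average_precision_score(pos, probs[:, j]))
            weights.append(pos.sum())
        pr_auc = float(np.average(aucs, weights=weights)) if aucs else float("nan")
        from sklearn.metrics import f1_score

        report.per_model["multiclass"] = {
            "pr_auc": pr_auc,
            "f1": float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
            "selected_features": bundle.models[0]["features"],
        }
    elif bundle.scheme == "ordinal":
        y_pred, votes = predict_ordinal(bundle, test)
        report.n_nonmonotone_votes = count_nonmonotone_votes(votes)
        for i, th in enumerate((0, 1, 2)):
            labels = (y_true > th).astype(int)
            p = bundle.model_probability(i, test)
            pred_i = (p > DECISION_THRESHOLD).astype(int)
            _, _, f1 = binary_prf(labels, pred_i)
            auc = (
                float(average_precision_score(labels, p))
                if 0 < labels.sum() < len(labels)
                else float("nan")
            )
            report.per_model[bundle.models[i]["name"]] = {
                "pr_auc": auc, "f1": f1,
                "selected_features": bundle.models[i]["features"],
            }
    else:  # tiered
        y_pred, _ = predict_tiered(bundle, test)
        for i, spec in enumerate(TIER_SPECS):
            rows = spec.select_rows(y_true, ctrl)
            labels = spec.labels(y_true[rows], ctrl[rows])
            p = bundle.model_probability(i, test.loc[rows])
            pred_i = (p > DECISION_THRESHOLD).astype(int)
            _, _, f1 = binary_prf(labels, pred_i)
            auc = (
                float(average_precision_score(labels, p))
                if 0 < labels.sum() < len(labels)
                else float("nan")
            )
            report.per_model[spec.name] = {
                "pr_auc": auc, "f1": f1,
                "selected_features": bundle.models[i]["features"],
            }

    labels = sorted(set(int(v) for v in y_true) | set(int(v) for v in y_pred))
    cm = confusion_counts(y_true, y_pred, labels)
    report.class_labels = labels
    report.confusion_matrix = cm.tolist()
    recalls = {}
    for i, lab in enumerate(labels):
        total = cm[i].sum()
        if total:
            recalls[str(lab)] = float(cm[i, i] / total)
    report.per_class_accuracy = recalls
    report.macro_accuracy = float(np.mean(list(recalls.values())))
    return report
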