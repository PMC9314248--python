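"""Case-level finding profiles and UIP / non-UIP prediction.

Tile classifications are aggregated per case (summing over a case's slides)
into finding-frequency profiles. At 5x magnification, tiles classified as
"complete normal" are excluded from the denominator — the amount of normal
lung in a surgical specimen reflects sampling, not disease. Profiles feed a
random-forest regressor (score = mean tree vote) or an RBF support-vector
machine with probability calibration; performance is summarised by ROC AUC
with a DeLong confidence interval, two models are compared by a paired
case-level bootstrap of the AUC difference, and operating-point sensitivity
and specificity are reported at a score threshold (default 0.5).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVC

from .integration import FindingScheme

logger = logging.getLogger("mixture.diagnosis")

__all__ = ["CaseFindingProfile", "DiagnosisConfig", "ROCResult",
           "aggregate_case", "profiles_to_features", "split_cases",
           "train_uip_model", "predict_scores", "roc_auc",
           "compare_auc_bootstrap", "threshold_metrics", "feature_importance"]


@dataclasses.dataclass
class CaseFindingProfile:
    case_id: str
    level: str
    counts: dict                 # class name -> tile count (all classes)
    proportions: dict            # retained classes -> fraction, sums to 1
    n_tiles_total: int
    n_tiles_retained: int
    valid: bool = True


@dataclasses.dataclass
class DiagnosisConfig:
    algorithm: str = "random_forest"      # or "svm"
    train_fraction: float = 126.0 / 180.0
    score_threshold: float = 0.5
    n_bootstrap: int = 5000
    n_trees: int = 500
    svm_kernel: str = "rbf"
    include_other: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_bootstrap < 100:
            raise ValueError("n_bootstrap must be >= 100")
        if self.algorithm not in ("random_forest", "svm"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclasses.dataclass
class ROCResult:
    auc: float
    ci_lower: float
    ci_upper: float
    method: str
    fpr: np.ndarray
    tpr: np.ndarray


def aggregate_case(predictions: pd.DataFrame, level: str,
                   scheme: FindingScheme) -> list:
    """Aggregate tile predictions into per-case profiles.

    ``predictions`` needs columns ``case_id`` and ``label``; counts are
    summed across all of a case's slides/rows. Classes listed in the
    scheme's frequency exclusions ("complete normal" at 5x) are counted but
    dropped from the proportion denominator. A case whose retained count is
    zero is flagged invalid and should be excluded downstream.
    """
    excluded = set(scheme.special_excluded_from_frequencies)
    retained_classes = [c for c in scheme.class_names if c not in excluded]
    profiles = []
    for case_id, grp in predictions.groupby("case_id", sort=True):
        counts = {c: 0 for c in scheme.class_names}
        for lbl in grp["label"]:
            if lbl not in counts:
                raise ValueError(f"label {lbl!r} not in scheme")
            counts[lbl] += 1
        total = int(sum(counts.values()))
        retained = int(sum(counts[c] for c in retained_classes))
        if retained == 0:
            logger.warning("case %s has no retained tiles at %s; flagged invalid",
                           case_id, level)
            profiles.append(CaseFindingProfile(str(case_id), level, counts, {},
                                               total, 0, valid=False))
            continue
        props = {c: counts[c] / retained for c in retained_classes}
        profiles.append(CaseFindingProfile(str(case_id), level, counts, props,
                                           total, retained))
    return profiles


def profiles_to_features(profiles: list, include_other: bool = True
                         ) -> pd.DataFrame:
    """Feature table (cases x finding proportions), one level per call.

    Multi-magnification features are built by concatenating the per-level
    tables column-wise on ``case_id``.
    """
    rows = {}
    for p in profiles:
        if not p.valid:
            continue
        rows[p.case_id] = {f"{p.level}:{c}": v for c, v in p.proportions.items()
                           if include_other or c != "other"}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index().fillna(0.0)


def split_cases(labels: np.ndarray, config: DiagnosisConfig):
    """Stratified train/validation split of case indices.

    The train size is ``round(train_fraction * n)``; per-class allocation
    uses largest remainders so class prevalence differs by at most one case
    between partitions. 180 cases at the default fraction give 126/54.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to stratify")
    rng = np.random.default_rng(config.seed)
    n = len(labels)
    n_train = int(round(config.train_fraction * n))
    per_class = {c: np.flatnonzero(labels == c) for c in classes}
    raw = {c: config.train_fraction * len(idx) for c, idx in per_class.items()}
    take = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n_train - sum(take.values())
    for c in sorted(classes, key=lambda c: -(raw[c] - take[c]))[:max(short, 0)]:
        take[c] += 1
    train_idx, val_idx = [], []
    for c, idx in per_class.items():
        idx = rng.permutation(idx)
        train_idx.extend(idx[:take[c]])
        val_idx.extend(idx[take[c]:])
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


class _Scorer:
    def __init__(self, model, algorithm: str, feature_names: list):
        self.model = model
        self.algorithm = algorithm
        self.feature_names = feature_names

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature dimension mismatch")
        if self.algorithm == "random_forest":
            return np.clip(self.model.predict(X), 0.0, 1.0)
        return self.model.predict_proba(X)[:, 1]


def train_uip_model(features, labels, config: DiagnosisConfig) -> _Scorer:
    """Fit the diagnosis scorer on finding-proportion features.

    The random forest follows the regressor convention: the score is the
    mean vote of the trees over the 0/1 label, already in [0, 1]. The SVM
    uses an RBF kernel with probability calibration.
    """
    X = np.asarray(features, dtype=float)
    names = (list(features.columns) if isinstance(features, pd.DataFrame)
             else [f"f{i}" for i in range(X.shape[1])])
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("features and labels differ in length")
    if config.algorithm == "random_forest":
        model = RandomForestRegressor(
            n_estimators=config.n_trees, max_features="sqrt",
            random_state=config.seed & 0x7FFFFFFF).fit(X, y.astype(float))
    else:
        model = SVC(kernel=config.svm_kernel, probability=True,
                    random_state=config.seed & 0x7FFFFFFF).fit(X, y)
    return _Scorer(model, config.algorithm, names)


def predict_scores(scorer: _Scorer, features) -> np.ndarray:
    return scorer.score(np.asarray(features, dtype=float))


def _concordance_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(equal), via midranks."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    order = np.argsort(np.concatenate([pos, neg]), kind="mergesort")
    ranks = np.empty(len(order), dtype=float)
    sorted_scores = np.concatenate([pos, neg])[order]
    # midranks for ties
    i = 0
    r = np.empty(len(order))
    while i < len(order):
        j = i
        while j + 1 < len(order) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        r[i:j + 1] = 0.5 * (i + j) + 1.0
        i = j + 1
    ranks[order] = r
    m = len(pos)
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * len(neg)))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    psi = (pos > neg) + 0.5 * (pos == neg)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels, ci_method: str = "delong", alpha: float = 0.05,
            n_bootstrap: int = 2000, seed: int = 0) -> ROCResult:
    """AUC with confidence interval (DeLong default, bootstrap optional)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = _concordance_auc(scores, labels)
    if ci_method == "delong":
        se = np.sqrt(_delong_variance(scores, labels))
        z = norm.ppf(1 - alpha / 2)
        lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        reps = []
        for _ in range(n_bootstrap):
            idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
            reps.append(_concordance_auc(scores[idx], labels[idx]))
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        lo, hi = min(lo, auc), max(hi, auc)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    # ROC points (threshold sweep over unique scores)
    thr = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = [(scores[labels == 1] >= t).mean() for t in thr]
    fpr = [(scores[labels == 0] >= t).mean() for t in thr]
    return ROCResult(auc, float(lo), float(hi), ci_method,
                     np.asarray(fpr), np.asarray(tpr))


def compare_auc_bootstrap(scores_a, scores_b, labels, n_bootstrap: int = 5000,
                          seed: int = 0):
    """Paired bootstrap test of AUC_a - AUC_b on identical cases.

    Cases are resampled with replacement, stratified by class so each
    replicate contains both classes; both scorers are evaluated on the same
    resample (cases are the exchangeable unit). The two-sided p-value is the
    fraction-based 2 * min(P(delta <= 0), P(delta >= 0)), capped at 1.
    Returns ``(p_value, delta_observed, delta_distribution)``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(a) == len(b) == len(labels)):
        raise ValueError("score vectors and labels must be aligned")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    deltas = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        la = labels[idx]
        deltas[i] = _concordance_auc(a[idx], la) - _concordance_auc(b[idx], la)
    p = min(1.0, 2.0 * min((deltas <= 0).mean(), (deltas >= 0).mean()))
    observed = _concordance_auc(a, labels) - _concordance_auc(b, labels)
    return float(p), float(observed), deltas


def threshold_metrics(scores, labels, threshold: float = 0.5):
    """(sensitivity, specificity) with positives called at score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    return tp / (tp + fn), tn / (tn + fp)


def feature_importance(scorer: _Scorer) -> pd.Series:
    """Node-purity importances of the random forest, one per finding."""
    if scorer.algorithm != "random_forest":
        raise NotImplementedError("feature importance requires a random forest")
    return pd.Series(scorer.model.feature_importances_,
                     index=scorer.feature_names, name="importance")
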