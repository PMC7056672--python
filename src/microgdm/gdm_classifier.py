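"""Forward-selection linear-discriminant case classifier.

Greedy forward feature selection over genus abundances and clinical
indices, scored by leave-one-out cross-validated AUC, with a two-class LDA
on pooled within-class covariance, DeLong confidence intervals, and frozen
external-validation evaluation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import OtuTable, ValidationError

__all__ = [
    "ClassifierModel",
    "RocResult",
    "fit_lda",
    "loocv_performance",
    "forward_select",
    "roc_auc_ci",
    "evaluate_external",
    "compare_models",
    "genus_feature_frame",
]

log = logging.getLogger(__name__)

RIDGE = 1e-6
PSEUDO_FRACTION = 1e-6


@dataclass
class ClassifierModel:
    selected_features: list
    weights: dict  # feature -> raw-scale weight
    intercept: float
    score_threshold: float
    training_summary: list  # per-step dicts: feature, auc, accuracy
    metric: str = "auc"

    def __post_init__(self) -> None:
        if not self.selected_features:
            raise ValidationError("selected_features must be non-empty")
        if len(set(self.selected_features)) != len(self.selected_features):
            raise ValidationError("selected_features contains duplicates")
        for f, w in self.weights.items():
            if not math.isfinite(w):
                raise ValidationError(f"non-finite weight for {f!r}")

    def score(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise ValidationError(f"feature(s) missing from input: {missing}")
        m = X[self.selected_features].to_numpy(dtype=float)
        w = np.array([self.weights[f] for f in self.selected_features])
        return m @ w + self.intercept

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    curve: list  # (fpr, tpr) points
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float


def _as_bool_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype == bool:
        return y
    levels = np.unique(y)
    if set(levels) <= {0, 1}:
        return y.astype(bool)
    if set(levels) <= {"case", "control"}:
        return y == "case"
    raise ValidationError(f"cannot interpret labels with levels {list(levels)}")


def fit_lda(X: np.ndarray, y) -> tuple[np.ndarray, float]:
    """Two-class LDA on standardized features; returns raw-scale (w, b).

    Positive score => case. Pooled within-class covariance with ridge
    RIDGE x trace; exactly collinear features are rejected by name.
    """
    X = np.asarray(X, dtype=float)
    y = _as_bool_labels(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValidationError("both classes must be present")
    mean = X.mean(axis=0)
    sd_all = X.std(axis=0, ddof=1)
    varying = sd_all > 0
    sd = np.where(varying, sd_all, 1.0)
    Z = (X - mean) / sd
    m1 = Z[y].mean(axis=0)
    m0 = Z[~y].mean(axis=0)
    z1 = Z[y] - m1
    z0 = Z[~y] - m0
    n = len(y)
    S = (z1.T @ z1 + z0.T @ z0) / max(n - 2, 1)
    w_std = np.zeros(X.shape[1])
    # constant columns carry no information: weight 0, solve on the rest
    v = np.flatnonzero(varying)
    if v.size:
        Sv = S[np.ix_(v, v)]
        dv = (m1 - m0)[v]
        tr = np.trace(Sv)
        if tr <= 1e-300:
            # no within-class scatter (perfectly separated constants):
            # fall back to the mean-difference direction
            w_std[v] = dv
        else:
            eigval, eigvec = np.linalg.eigh(Sv)
            if eigval[0] < 1e-10 * tr:
                loading = np.abs(eigvec[:, 0])
                bad = v[np.flatnonzero(loading > 0.3)]
                raise ValidationError(
                    f"singular pooled covariance; collinear feature "
                    f"column(s) at index {list(bad)}"
                )
            Sv = Sv + RIDGE * tr * np.eye(Sv.shape[0])
            w_std[v] = np.linalg.solve(Sv, dv)
    b_std = -float(w_std @ (m1 + m0)) / 2.0
    w_raw = w_std / sd
    b_raw = b_std - float(w_raw @ mean)
    return w_raw, b_raw


def _loocv_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Held-out LDA score for every sample; NaN when the fold is degenerate."""
    n = len(y)
    scores = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        yt = y[mask]
        if yt.sum() == 0 or (~yt).sum() == 0:
            log.warning("loocv: fold %d leaves a single-class training set", i)
            mask[i] = True
            continue
        w, b = fit_lda(X[mask], yt)
        scores[i] = X[i] @ w + b
        mask[i] = True
    return scores


def _pair_count_auc(scores: np.ndarray, y: np.ndarray) -> float:
    r = rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def loocv_performance(X, y, feature_subset=None) -> tuple[float, float]:
    """Leave-one-out (auc, accuracy) of an LDA on the given feature columns."""
    if isinstance(X, pd.DataFrame):
        cols = list(feature_subset) if feature_subset is not None else list(X.columns)
        M = X[cols].to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        if feature_subset is not None:
            M = M[:, list(feature_subset)]
    y = _as_bool_labels(y)
    if len(y) < 10:
        raise ValidationError("LOOCV needs at least 10 samples")
    scores = _loocv_scores(M, y)
    ok = np.isfinite(scores)
    auc = _pair_count_auc(scores[ok], y[ok])
    acc = float(((scores[ok] > 0) == y[ok]).mean())
    return auc, acc


def forward_select(X: pd.DataFrame, y, candidates, max_features: int = 10,
                   metric: str = "auc") -> ClassifierModel:
    """Greedy forward selection scored by LOOCV; the final model is the
    prefix of the greedy path with the globally best score (ties: fewer
    features, then candidate order)."""
    if max_features < 1:
        raise ValidationError("max_features must be >= 1")
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("candidate list is empty")
    missing = [c for c in candidates if c not in X.columns]
    if missing:
        raise ValidationError(f"candidate(s) not in X: {missing}")
    if metric not in ("auc", "accuracy"):
        raise ValueError("metric must be 'auc' or 'accuracy'")
    y = _as_bool_labels(y)
    selected: list = []
    remaining = list(candidates)
    trajectory = []
    key = 0 if metric == "auc" else 1
    while remaining and len(selected) < max_features:
        best_feat, best_perf = None, None
        for feat in remaining:
            perf = loocv_performance(X, y, selected + [feat])
            if best_perf is None or perf[key] > best_perf[key] + 1e-12 or (
                abs(perf[key] - best_perf[key]) <= 1e-12
                and perf[1 - key] > best_perf[1 - key] + 1e-12
            ):
                best_feat, best_perf = feat, perf
        selected.append(best_feat)
        remaining.remove(best_feat)
        trajectory.append({
            "feature": best_feat, "auc": best_perf[0], "accuracy": best_perf[1],
        })
    # globally best prefix; ties resolved toward fewer features
    scores = [step[metric] for step in trajectory]
    best_score = max(scores)
    best_len = next(k + 1 for k, s in enumerate(scores)
                    if s >= best_score - 1e-12)
    final_features = [step["feature"] for step in trajectory[:best_len]]
    M = X[final_features].to_numpy(dtype=float)
    w, b = fit_lda(M, y)
    scores_in = M @ w + b
    threshold = _youden_threshold(scores_in, y)
    return ClassifierModel(
        selected_features=final_features,
        weights={f: float(wi) for f, wi in zip(final_features, w)},
        intercept=float(b),
        score_threshold=float(threshold),
        training_summary=trajectory,
        metric=metric,
    )


def _roc_points(scores: np.ndarray, y: np.ndarray):
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    n1 = int(y.sum())
    n0 = len(y) - n1
    tps = np.cumsum(ys)
    fps = np.cumsum(~ys)
    # collapse ties: keep last point of each threshold run
    distinct = np.r_[np.diff(ss) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n1]
    fpr = np.r_[0.0, fps[distinct] / n0]
    thresholds = np.r_[np.inf, ss[distinct]]
    return fpr, tpr, thresholds


def _youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    fpr, tpr, thr = _roc_points(scores, y)
    j = tpr - fpr
    k = int(np.argmax(j))
    return float(thr[k]) if np.isfinite(thr[k]) else float(scores.max() + 1)


def _delong_variance(scores: np.ndarray, y: np.ndarray, auc: float) -> float:
    pos = scores[y]
    neg = scores[~y]
    n1, n0 = len(pos), len(neg)
    # placements via midranks
    allr = rankdata(np.concatenate([pos, neg]))
    rpos = rankdata(pos)
    rneg = rankdata(neg)
    v10 = (allr[:n1] - rpos) / n0
    v01 = 1.0 - (allr[n1:] - rneg) / n1
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return s10 / n1 + s01 / n0


def roc_auc_ci(scores, labels, threshold: float | None = None) -> RocResult:
    """AUC by Mann-Whitney pair counting with a 95% DeLong interval.

    ``threshold`` defaults to the Youden-optimal point on this curve;
    accuracy/sensitivity/specificity are evaluated there.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if y.all() or not y.any():
        raise ValidationError("both classes must be present")
    auc = _pair_count_auc(scores, y)
    var = _delong_variance(scores, y, auc)
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    fpr, tpr, _ = _roc_points(scores, y)
    if threshold is None:
        threshold = _youden_threshold(scores, y)
    pred = scores >= threshold
    sens = float(pred[y].mean())
    spec = float((~pred[~y]).mean())
    acc = float((pred == y).mean())
    return RocResult(
        auc=float(auc),
        ci_low=float(max(auc - half, 0.0)),
        ci_high=float(min(auc + half, 1.0)),
        curve=[(float(a), float(b)) for a, b in zip(fpr, tpr)],
        accuracy=acc, sensitivity=sens, specificity=spec,
        threshold=float(threshold),
    )


def evaluate_external(model: ClassifierModel, X_val: pd.DataFrame,
                      y_val) -> RocResult:
    """Apply frozen weights and threshold to an external set; no refitting."""
    scores = model.score(X_val)
    return roc_auc_ci(scores, y_val, threshold=model.score_threshold)


def genus_feature_frame(table: OtuTable, min_prevalence: float = 0.1,
                        pseudo: float = PSEUDO_FRACTION) -> pd.DataFrame:
    """log10(relative abundance + pseudo) of genera present in at least
    ``min_prevalence`` of samples; candidate features for the classifier."""
    rel = table.relative_abundance()
    prevalence = (table.counts > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    cols = [f for f, k in zip(table.feature_ids, keep) if k]
    data = np.log10(rel[:, keep] + pseudo)
    return pd.DataFrame(data, index=table.sample_ids, columns=cols)


def compare_models(X: pd.DataFrame, y, X_val: pd.DataFrame, y_val,
                   genus_candidates, clinical_candidates,
                   max_features: int = 10, metric: str = "auc") -> dict:
    """Forward-selected models from combined / genus-only / clinical-only
    candidate pools, each with discovery-LOOCV and external-validation ROC."""
    pools = {
        "combined": list(genus_candidates) + list(clinical_candidates),
        "genus_only": list(genus_candidates),
        "clinical_only": list(clinical_candidates),
    }
    y = _as_bool_labels(y)
    y_val = _as_bool_labels(y_val)
    out = {}
    for name, pool in pools.items():
        if not pool:
            continue
        model = forward_select(X, y, pool, max_features=max_features,
                               metric=metric)
        loo = _loocv_scores(X[model.selected_features].to_numpy(dtype=float), y)
        ok = np.isfinite(loo)
        disc = roc_auc_ci(loo[ok], y[ok])
        val = evaluate_external(model, X_val, y_val)
        out[name] = {"model": model, "discovery": disc, "validation": val}
    return out
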