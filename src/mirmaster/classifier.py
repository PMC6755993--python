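"""Mesenchymal-vs-rest subtype classifier.

Two-step gene selection (differential expression, then per-gene AUC) followed
by a nearest-shrunken-centroid (PAM) model. The NSC formulation: per-feature
class deviation d_ik = (xbar_ik - xbar_i) / (m_k (s_i + s0)) with
m_k = sqrt(1/n_k - 1/n), soft-thresholded at Delta, shrunken centroids
xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik, Gaussian-discriminant posteriors
with class priors. Delta is chosen by stratified 10-fold cross-validated
accuracy (ties broken toward the sparsest model).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import differential_expression_table, select_features
from .io import AnalysisConfig, ExpressionMatrix, ValidationError

logger = logging.getLogger("mirmaster")

DEFAULT_DELTA_GRID = tuple(np.round(np.linspace(0.0, 3.0, 13), 4))


def auc_mann_whitney(values, positive_mask) -> float:
    """Area under the ROC curve via the Mann-Whitney identity U/(n+ n-).

    U counts (negative, positive) pairs with negative < positive; ties count
    one half.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(positive_mask, dtype=bool)
    pos = values[mask]
    neg = values[~mask]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("AUC needs at least one positive and one negative sample")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").statistic
    return float(u) / (pos.size * neg.size)


def two_step_feature_selection(
    m: ExpressionMatrix,
    group_mask,
    config: AnalysisConfig | None = None,
) -> list[str]:
    """DE filter (log2FC/FDR), then AUC filter, then cap at n_classifier_genes.

    Expects a z-normalized matrix. Survivors are ordered by AUC descending;
    ties break by |log2FC| descending, then lexicographic feature id.
    """
    cfg = config or AnalysisConfig()
    mask = np.asarray(group_mask, dtype=bool)
    table = differential_expression_table(m, mask, test="welch_t")
    step1 = select_features(table, "greater_than", cfg.de_lfc_classifier, cfg.de_fdr_classifier)
    if not step1:
        raise ValidationError(
            "no gene passed the differential-expression filter "
            f"(log2FC > {cfg.de_lfc_classifier}, BH P < {cfg.de_fdr_classifier}); "
            "consider relaxing thresholds"
        )
    lfc = table.set_index("feature_id")["log2fc"]
    rows = []
    for fid in step1:
        auc = auc_mann_whitney(m.data.loc[fid].to_numpy(), mask)
        if auc > cfg.auc_min:
            rows.append((fid, auc, abs(lfc[fid])))
    if not rows:
        raise ValidationError(
            f"no differentially expressed gene reached AUC > {cfg.auc_min}; "
            "consider lowering auc_min"
        )
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return [fid for fid, _, _ in rows[: cfg.n_classifier_genes]]


@dataclass
class ShrunkenCentroidModel:
    feature_ids: list[str]
    classes: list[str]
    overall_centroid: np.ndarray        # (p,)
    class_centroids: np.ndarray         # (p, K) unshrunken
    shrunken_centroids: np.ndarray      # (p, K)
    shrunken_deviations: np.ndarray     # (p, K) d'_ik
    pooled_sd: np.ndarray               # (p,) s_i
    s0: float
    delta: float
    priors: np.ndarray                  # (K,)
    norm_mean: np.ndarray               # training-cohort per-feature mean
    norm_sd: np.ndarray                 # training-cohort per-feature sd

    def to_json(self, path) -> None:
        payload = {
            "feature_ids": self.feature_ids,
            "classes": self.classes,
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "shrunken_deviations": self.shrunken_deviations.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "delta": self.delta,
            "priors": self.priors.tolist(),
            "norm_mean": self.norm_mean.tolist(),
            "norm_sd": self.norm_sd.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ShrunkenCentroidModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_ids=d["feature_ids"],
            classes=d["classes"],
            overall_centroid=np.asarray(d["overall_centroid"]),
            class_centroids=np.asarray(d["class_centroids"]),
            shrunken_centroids=np.asarray(d["shrunken_centroids"]),
            shrunken_deviations=np.asarray(d["shrunken_deviations"]),
            pooled_sd=np.asarray(d["pooled_sd"]),
            s0=float(d["s0"]),
            delta=float(d["delta"]),
            priors=np.asarray(d["priors"]),
            norm_mean=np.asarray(d["norm_mean"]),
            norm_sd=np.asarray(d["norm_sd"]),
        )


def _fit_nsc(values: np.ndarray, y: np.ndarray, classes: list, delta: float):
    """Core NSC fit on a (p, n) array; returns the centroid geometry."""
    n = values.shape[1]
    xbar = values.mean(axis=1)
    class_cent = np.stack([values[:, y == c].mean(axis=1) for c in classes], axis=1)
    counts = np.array([(y == c).sum() for c in classes])
    # pooled within-class variance with n - K denominator
    within = np.zeros(values.shape[0])
    for j, c in enumerate(classes):
        sub = values[:, y == c]
        within += ((sub - class_cent[:, [j]]) ** 2).sum(axis=1)
    s = np.sqrt(within / (n - len(classes)))
    s0 = float(np.median(s))
    m_k = np.sqrt(1.0 / counts - 1.0 / n)
    denom = m_k[None, :] * (s + s0)[:, None]
    d = (class_cent - xbar[:, None]) / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    cent_shrunk = xbar[:, None] + denom * d_shrunk
    priors = counts / n
    return xbar, class_cent, cent_shrunk, d_shrunk, s, s0, priors


def _discriminant(values: np.ndarray, cent_shrunk, s, s0, priors) -> np.ndarray:
    """delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k; (n, K)."""
    scale = (s + s0)[:, None]
    scores = []
    for k in range(cent_shrunk.shape[1]):
        diff = (values - cent_shrunk[:, [k]]) / scale
        scores.append((diff ** 2).sum(axis=0) - 2.0 * np.log(priors[k]))
    return np.stack(scores, axis=1)


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Round-robin class-stratified fold assignment (reproducible)."""
    fold = np.empty(y.size, dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def train_nsc(
    m: ExpressionMatrix,
    labels,
    delta_grid=DEFAULT_DELTA_GRID,
    n_folds: int = 10,
    seed: int = 0,
) -> ShrunkenCentroidModel:
    """Train an NSC model; Delta picked by stratified CV accuracy.

    ``labels`` is a per-sample class label array in the matrix's sample
    order (e.g. "mesenchymal"/"rest"). Ties in CV accuracy resolve to the
    largest Delta (sparsest model).
    """
    y = np.asarray(labels)
    if y.size != m.n_samples:
        raise ValidationError("labels must cover all samples")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValidationError("need >= 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValidationError(f"classes with < 2 samples: {small}")

    values = m.values
    delta_grid = sorted(set(float(d) for d in delta_grid))
    if len(delta_grid) > 1:
        rng = np.random.default_rng(seed)
        n_folds_eff = min(n_folds, min(counts.values()))
        fold = _stratified_folds(y, n_folds_eff, rng)
        accuracy = np.zeros(len(delta_grid))
        for f in range(n_folds_eff):
            tr, te = fold != f, fold == f
            if len(np.unique(y[tr])) < len(classes):
                continue
            fit = _fit_nsc(values[:, tr], y[tr], classes, 0.0)
            xbar, class_cent, _, _, s, s0, priors = fit
            counts_tr = np.array([(y[tr] == c).sum() for c in classes])
            m_k = np.sqrt(1.0 / counts_tr - 1.0 / tr.sum())
            denom = m_k[None, :] * (s + s0)[:, None]
            d = (class_cent - xbar[:, None]) / denom
            for gi, delta in enumerate(delta_grid):
                d_shr = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
                cent = xbar[:, None] + denom * d_shr
                scores = _discriminant(values[:, te], cent, s, s0, priors)
                pred = np.asarray(classes)[scores.argmin(axis=1)]
                accuracy[gi] += (pred == y[te]).sum()
        best = max(range(len(delta_grid)),
                   key=lambda gi: (accuracy[gi], delta_grid[gi]))
        delta = delta_grid[best]
    else:
        delta = delta_grid[0]

    xbar, class_cent, cent_shrunk, d_shrunk, s, s0, priors = _fit_nsc(
        values, y, classes, delta)
    logger.info("NSC trained: %d features, classes %s, delta=%.3f, "
                "%d features with nonzero deviation",
                len(m.feature_ids), classes, delta,
                int((np.abs(d_shrunk).sum(axis=1) > 0).sum()))
    return ShrunkenCentroidModel(
        feature_ids=m.feature_ids,
        classes=classes,
        overall_centroid=xbar,
        class_centroids=class_cent,
        shrunken_centroids=cent_shrunk,
        shrunken_deviations=d_shrunk,
        pooled_sd=s,
        s0=s0,
        delta=delta,
        priors=priors,
        norm_mean=values.mean(axis=1),
        norm_sd=values.std(axis=1, ddof=1),
    )


def predict_nsc(
    model: ShrunkenCentroidModel,
    m_new: ExpressionMatrix,
    posterior_threshold: float = 0.5,
    call_class: str = "mesenchymal",
) -> pd.DataFrame:
    """Classify a (z-normalized) cohort; posteriors via stable softmax.

    Returns one row per sample: per-class posteriors, ``predicted`` class and
    a boolean ``call`` for ``call_class`` exceeding ``posterior_threshold``
    (when that class is in the model).
    """
    missing = [f for f in model.feature_ids if f not in m_new.data.index]
    if missing:
        raise ValidationError(f"model features absent from input matrix: {missing}")
    values = m_new.data.loc[model.feature_ids].to_numpy()
    scores = _discriminant(values, model.shrunken_centroids, model.pooled_sd,
                           model.s0, model.priors)
    z = -0.5 * scores
    z -= z.max(axis=1, keepdims=True)
    post = np.exp(z)
    post /= post.sum(axis=1, keepdims=True)
    out = pd.DataFrame(post, columns=model.classes,
                       index=pd.Index(m_new.sample_ids, name="sample_id"))
    out["predicted"] = np.asarray(model.classes)[post.argmax(axis=1)]
    if call_class in model.classes:
        out["call"] = out[call_class] > posterior_threshold
    return out
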