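"""Joint logistic-regression refinement of the unsure variant set.

Two regularized logistic submodels are trained on the labeled (positive vs
negative) keys with a liblinear solver: an L1-penalized model on the
standardized quality features and an L2-penalized model on the one-hot
sequence features.  Their positive-class probabilities are combined by a
thresholded weighted mean,

    P(pos) = 1/2 * sum_{P in (P_seq, P_pos)} w(P) * P,   w(P) = 1 if P >= 0.5 else 0,

and a key is called positive when P(pos) >= threshold (default 0.5).  The
model is fit on a stratified 3:1 train/test split with random oversampling
of the minority class, and its held-out performance is reported as the AUC
of the joint probability.  Applying the fitted model to the unsure set
expands the core positive set (refinement only ever adds keys).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .errors import ModelingError
from .features import DesignMatrices
from .variants_io import VariantKey

log = logging.getLogger(__name__)


def joint_probability(
    p_seq: float | np.ndarray, p_pos: float | np.ndarray, w_cutoff: float = 0.5
) -> float | np.ndarray:
    """Combine the two submodel probabilities with the thresholded weighted mean.

    Each probability contributes only if it reaches ``w_cutoff``; the
    attainable range is {0} union [w_cutoff/2, 1].
    """
    p_seq = np.asarray(p_seq, dtype=float)
    p_pos = np.asarray(p_pos, dtype=float)
    for name, arr in (("p_seq", p_seq), ("p_pos", p_pos)):
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"{name} outside [0, 1]")
    w_seq = (p_seq >= w_cutoff).astype(float)
    w_pos = (p_pos >= w_cutoff).astype(float)
    out = 0.5 * (w_seq * p_seq + w_pos * p_pos)
    return float(out) if out.ndim == 0 else out


def split_train_test(
    y: np.ndarray, seed: int, test_fraction: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified-by-class random 3:1 split of row indices, deterministic."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ModelingError("need >= 2 rows of each class to stratify the split")
    if len(y) < 8:
        raise ModelingError(f"need >= 8 labeled rows to split, got {len(y)}")
    train_idx, test_idx = train_test_split(
        np.arange(len(y)),
        test_size=test_fraction,
        stratify=y,
        random_state=seed,
        shuffle=True,
    )
    return np.sort(train_idx), np.sort(test_idx)


def oversample_minority(y: np.ndarray, seed: int) -> np.ndarray:
    """Row indices after random oversampling of the minority class.

    Minority rows are resampled with replacement until the classes balance;
    majority rows are untouched.  Returns the original indices followed by
    the replicated ones, deterministic given the seed.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ModelingError("oversampling requires exactly two classes")
    if counts[0] == counts[1]:
        return np.arange(len(y))
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    rng = np.random.default_rng(seed)
    minority_idx = np.flatnonzero(y == minority)
    extra = rng.choice(minority_idx, size=deficit, replace=True)
    return np.concatenate([np.arange(len(y)), extra])


def auc_score(y: np.ndarray, scores: np.ndarray) -> float | None:
    """Rank-based AUC (ties averaged); ``None`` when only one class is present."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        return None
    return float(roc_auc_score(y, scores))


def _fit_liblinear(X: np.ndarray, y: np.ndarray, penalty: str, C: float, seed: int):
    l1_ratio = 1.0 if penalty == "l1" else 0.0
    for max_iter in (1000, 10000):
        model = LogisticRegression(
            l1_ratio=l1_ratio, C=C, solver="liblinear", random_state=seed, max_iter=max_iter
        )
        model.fit(X, y)
        if int(np.max(model.n_iter_)) < max_iter:
            return model
    raise ModelingError(
        f"liblinear did not converge within {max_iter} iterations "
        f"(penalty={penalty}, C={C}, n={len(y)})"
    )


@dataclass
class JlrModel:
    """Fitted submodel coefficients plus the joint decision rule."""

    quality_coefs: np.ndarray
    quality_intercept: float
    sequence_coefs: np.ndarray
    sequence_intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    quality_columns: tuple[str, ...]
    sequence_columns: tuple[str, ...]
    c_quality: float
    c_sequence: float
    threshold: float
    w_cutoff: float
    seed: int
    test_auc: float | None

    def predict(self, X_quality: np.ndarray, X_sequence: np.ndarray):
        """Return (p_pos, p_seq, p_joint, call) arrays for the given rows."""
        Xq = (np.asarray(X_quality, dtype=float) - self.scaler_mean) / self.scaler_scale
        z_q = Xq @ self.quality_coefs + self.quality_intercept
        z_s = np.asarray(X_sequence, dtype=float) @ self.sequence_coefs + self.sequence_intercept
        p_pos = 1.0 / (1.0 + np.exp(-z_q))
        p_seq = 1.0 / (1.0 + np.exp(-z_s))
        p_joint = joint_probability(p_seq, p_pos, self.w_cutoff)
        return p_pos, p_seq, np.atleast_1d(p_joint), np.atleast_1d(p_joint) >= self.threshold

    def to_dict(self) -> dict:
        return {
            "quality_coefs": dict(zip(self.quality_columns, map(float, self.quality_coefs))),
            "quality_intercept": float(self.quality_intercept),
            "sequence_coefs": dict(zip(self.sequence_columns, map(float, self.sequence_coefs))),
            "sequence_intercept": float(self.sequence_intercept),
            "scaler_mean": dict(zip(self.quality_columns, map(float, self.scaler_mean))),
            "scaler_scale": dict(zip(self.quality_columns, map(float, self.scaler_scale))),
            "c_quality": self.c_quality,
            "c_sequence": self.c_sequence,
            "threshold": self.threshold,
            "w_cutoff": self.w_cutoff,
            "seed": self.seed,
            "test_auc": self.test_auc,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def fit_jlr(
    labeled: DesignMatrices,
    seed: int,
    c_quality: float = 1.0,
    c_sequence: float = 1.0,
    threshold: float = 0.5,
    w_cutoff: float = 0.5,
) -> JlrModel:
    """Train both submodels on the labeled keys and evaluate on the held-out split.

    Quality features are z-scored with statistics from the (oversampled)
    training rows; one-hot sequence features are left unscaled.
    """
    if labeled.y is None:
        raise ModelingError("labeled design matrices carry no y vector")
    if not (0 < threshold < 1):
        raise ModelingError(f"threshold must lie in (0, 1), got {threshold}")
    y = labeled.y
    train_idx, test_idx = split_train_test(y, seed)
    os_rows = oversample_minority(y[train_idx], seed)
    rows = train_idx[os_rows]

    Xq_train = labeled.X_quality[rows]
    mean = Xq_train.mean(axis=0)
    scale = Xq_train.std(axis=0)
    scale[scale == 0] = 1.0

    q_model = _fit_liblinear((Xq_train - mean) / scale, y[rows], "l1", c_quality, seed)
    s_model = _fit_liblinear(labeled.X_sequence[rows], y[rows], "l2", c_sequence, seed)

    model = JlrModel(
        quality_coefs=q_model.coef_.ravel().copy(),
        quality_intercept=float(q_model.intercept_[0]),
        sequence_coefs=s_model.coef_.ravel().copy(),
        sequence_intercept=float(s_model.intercept_[0]),
        scaler_mean=mean,
        scaler_scale=scale,
        quality_columns=tuple(labeled.quality_columns),
        sequence_columns=tuple(labeled.sequence_columns),
        c_quality=c_quality,
        c_sequence=c_sequence,
        threshold=threshold,
        w_cutoff=w_cutoff,
        seed=seed,
        test_auc=None,
    )
    _, _, p_joint, _ = model.predict(
        labeled.X_quality[test_idx], labeled.X_sequence[test_idx]
    )
    model.test_auc = auc_score(y[test_idx], p_joint)
    if model.test_auc is None:
        log.warning("held-out test set is single-class; AUC undefined")
    return model


def refine_unsure(
    model: JlrModel, unsure: DesignMatrices
) -> tuple[list[VariantKey], pd.DataFrame]:
    """Apply the fitted joint model to the unsure set.

    Returns the keys called positive plus a per-key prediction table.
    Raises :class:`ModelingError` on a feature-schema mismatch.
    """
    if (
        tuple(unsure.quality_columns) != tuple(model.quality_columns)
        or tuple(unsure.sequence_columns) != tuple(model.sequence_columns)
    ):
        raise ModelingError("unsure design matrices do not match the model's feature schema")
    if unsure.n_rows == 0:
        cols = ["chrom", "pos", "ref", "alt", "p_pos", "p_seq", "p_joint", "call"]
        return [], pd.DataFrame(columns=cols)
    p_pos, p_seq, p_joint, call = model.predict(unsure.X_quality, unsure.X_sequence)
    table = pd.DataFrame(
        {
            "chrom": [k.chrom for k in unsure.keys],
            "pos": [k.pos for k in unsure.keys],
            "ref": [k.ref for k in unsure.keys],
            "alt": [k.alt for k in unsure.keys],
            "p_pos": p_pos,
            "p_seq": p_seq,
            "p_joint": p_joint,
            "call": call,
        }
    )
    refined = [k for k, c in zip(unsure.keys, call) if c]
    return refined, table


def final_positive_set(
    core_positives: Sequence[VariantKey], refined: Sequence[VariantKey]
) -> dict[VariantKey, str]:
    """Union of core and refined positives with provenance per key."""
    out = {k: "core" for k in core_positives}
    for k in refined:
        out.setdefault(k, "refined")
    return out
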