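"""Feature extraction for the two submodels of the joint classifier.

Quality features (per call, aggregated per key across supporting cells):
variant quality, read depth, variant allele fraction, the min-normalized
Phred genotype-likelihood triple, and the two allele depths.

Sequence features (per key): a 6-way one-hot over pyrimidine-centric
mutation types, a 96-way one-hot over SBS96 trinucleotide classes, and —
when a reference signature matrix is supplied — one component per
signature equal to that signature's probability mass at the variant's
SBS96 class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pyfaidx import Fasta

from .core import CohortLabeling
from .errors import ModelingError, VcfFormatError
from .variants_io import (
    MUTATION_TYPES,
    SBS96_LABELS,
    CellCall,
    VariantKey,
    trinucleotide_context,
)

log = logging.getLogger(__name__)

QUALITY_FEATURE_NAMES = ("qual", "dp", "vaf", "pl_rr", "pl_ra", "pl_aa", "ad_ref", "ad_alt")
AGGREGATIONS = ("mean", "max_qual")


def quality_features(call: CellCall) -> np.ndarray:
    """Per-call quality feature vector in :data:`QUALITY_FEATURE_NAMES` order."""
    if call.dp <= 0:
        raise ModelingError(f"{call.key}: dp=0 call reached feature extraction")
    if call.pl is None:
        raise ModelingError(f"{call.key}: call lacks a PL triple")
    pl = np.asarray(call.pl, dtype=float)
    pl = pl - pl.min()  # idempotent min-normalization
    return np.array(
        [call.qual, call.dp, call.vaf, pl[0], pl[1], pl[2], call.ad_ref, call.ad_alt],
        dtype=float,
    )


def aggregate_quality(calls: Sequence[CellCall], how: str = "mean") -> np.ndarray:
    """Aggregate per-call quality features across a key's supporting cells.

    ``mean`` (default) is symmetric in the cells; ``max_qual`` takes the
    single highest-quality call's features.
    """
    if how not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {how!r}")
    mat = np.vstack([quality_features(c) for c in calls])
    if how == "mean":
        return mat.mean(axis=0)
    return mat[int(np.argmax(mat[:, 0]))]


def sequence_feature_names(signature_names: Sequence[str] = ()) -> tuple[str, ...]:
    return (
        tuple(f"type_{mt}" for mt in MUTATION_TYPES)
        + tuple(f"ctx_{lab}" for lab in SBS96_LABELS)
        + tuple(f"sig_{name}" for name in signature_names)
    )


def sequence_features(
    key: VariantKey,
    reference: Fasta,
    signatures: tuple[Sequence[str], np.ndarray] | None = None,
) -> np.ndarray | None:
    """Sequence feature vector for one key, or ``None`` if its context has N."""
    _, cls = trinucleotide_context(key, reference)
    if cls is None:
        return None
    type_onehot = np.zeros(len(MUTATION_TYPES))
    type_onehot[cls // 16] = 1.0
    ctx_onehot = np.zeros(96)
    ctx_onehot[cls] = 1.0
    parts = [type_onehot, ctx_onehot]
    if signatures is not None:
        _, matrix = signatures
        parts.append(np.asarray(matrix)[:, cls].astype(float))
    return np.concatenate(parts)


def load_signature_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a reference signature matrix: rows = signatures, 96 columns in
    canonical SBS96 order with trinucleotide labels in the header."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(SBS96_LABELS):
        raise VcfFormatError(
            f"{path}: signature matrix columns must be the 96 canonical labels "
            f"starting {SBS96_LABELS[0]}"
        )
    matrix = df.to_numpy(dtype=float)
    if np.any(matrix < 0) or np.any(matrix > 1):
        raise VcfFormatError(f"{path}: signature entries must lie in [0, 1]")
    return list(df.index.astype(str)), matrix


@dataclass
class DesignMatrices:
    """Aligned quality/sequence design matrices, one row per key (sorted)."""

    keys: list[VariantKey]
    X_quality: np.ndarray
    X_sequence: np.ndarray
    quality_columns: tuple[str, ...]
    sequence_columns: tuple[str, ...]
    y: np.ndarray | None = None
    excluded_keys: list[VariantKey] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.keys)

    def schema(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return (self.quality_columns, self.sequence_columns)


def _build(
    keys_labels: Sequence[tuple[VariantKey, int | None]],
    calls_by_key: Mapping[VariantKey, Sequence[CellCall]],
    reference: Fasta,
    signatures: tuple[Sequence[str], np.ndarray] | None,
    aggregate: str,
) -> DesignMatrices:
    sig_names = tuple(signatures[0]) if signatures is not None else ()
    q_rows, s_rows, kept_keys, ys, excluded = [], [], [], [], []
    for key, y in keys_labels:
        seq = sequence_features(key, reference, signatures)
        if seq is None:
            excluded.append(key)
            continue
        q_rows.append(aggregate_quality(calls_by_key[key], how=aggregate))
        s_rows.append(seq)
        kept_keys.append(key)
        ys.append(y)
    if excluded:
        log.info("excluded %d key(s) with undefined trinucleotide context", len(excluded))
    n_seq_cols = len(sequence_feature_names(sig_names))
    return DesignMatrices(
        keys=kept_keys,
        X_quality=np.vstack(q_rows) if q_rows else np.empty((0, len(QUALITY_FEATURE_NAMES))),
        X_sequence=np.vstack(s_rows) if s_rows else np.empty((0, n_seq_cols)),
        quality_columns=QUALITY_FEATURE_NAMES,
        sequence_columns=sequence_feature_names(sig_names),
        y=None if any(y is None for y in ys) else np.asarray(ys, dtype=int),
        excluded_keys=excluded,
    )


def build_design_matrices(
    labeling: CohortLabeling,
    reference: Fasta,
    signatures: tuple[Sequence[str], np.ndarray] | None = None,
    aggregate: str = "mean",
) -> tuple[DesignMatrices, DesignMatrices]:
    """Build (labeled, unsure) design matrices from a cohort labeling.

    Labeled rows combine the positive (y=1) and negative (y=0) sets; unsure
    rows carry no labels.  Row order is deterministic (sorted by key) and
    the column layout of the two results is identical by construction.
    Raises :class:`ModelingError` if either training class is empty.
    """
    positives = labeling.keys_with("positive")
    negatives = labeling.keys_with("negative")
    if not positives or not negatives:
        raise ModelingError(
            f"cannot train with {len(positives)} positive and {len(negatives)} negative keys; "
            "relax the filtering thresholds"
        )
    labeled_spec = sorted([(k, 1) for k in positives] + [(k, 0) for k in negatives])
    unsure_spec = [(k, None) for k in labeling.keys_with("unsure")]
    labeled = _build(labeled_spec, labeling.calls, reference, signatures, aggregate)
    unsure = _build(unsure_spec, labeling.calls, reference, signatures, aggregate)
    return labeled, unsure
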