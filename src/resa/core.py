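"""The filtering-and-labeling engine for recurrently expressed SNVs.

The central assumption: cancer cells evolve clonally, so a true expressed
somatic SNV recurs across cells, while library/amplification artefacts are
scattered with little recurrence and germline polymorphisms are seen in
almost every cell.  After annotation-level removal (non-exonic, RNA-editing,
germline-listed sites), candidate SNVs from the primary caller (G) are
cross-checked against the secondary caller (S):

* set A — called by both pipelines in a cell (dual-caller consensus);
* set B — called only by the primary pipeline in that cell.

Candidates are then partitioned at the cohort level:

* ``positive``  — at least one quality-passing set-A call and recurrence
  within [L, U], where L = max(floor, ceil(lower_frac * n_cells)) and
  U = floor(upper_frac * n_cells);
* ``negative``  — set-B only, no quality-passing call, no cross-cell
  recurrence (seen in exactly one cell);
* ``removed``   — non-exonic / editing / germline-listed / recurrence > U;
* ``unsure``    — everything else, deferred to the joint classifier.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError
from .variants_io import CellCall, ExonIntervals, SiteList, VariantKey

log = logging.getLogger(__name__)

LABELS = ("positive", "negative", "unsure", "removed")
REMOVAL_REASONS = ("non_exonic", "editing", "germline_list", "over_recurrent", "none")

_EPS = 1e-9  # guards ceil/floor against binary-float artefacts (0.1*30 != 3.0)


@dataclass
class CohortConfig:
    """Thresholds for quality filtering and cross-cell recurrence.

    Defaults: minimum read depth 3; recurrence floor 3 with the lower bound
    at 10% and the upper bound at 80% of the cohort size; QD >= 2.0 and
    FS <= 30.0 (the classic strict RNA-seq variant filter).
    """

    n_cells: int
    min_depth: int = 3
    recurrence_floor: int = 3
    recurrence_lower_frac: float = 0.10
    recurrence_upper_frac: float = 0.80
    qd_min: float = 2.0
    fs_max: float = 30.0
    negative_max_recurrence: int = 1
    require_same_cell_a_pass: bool = True
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.recurrence_floor < 1:
            raise ConfigError("recurrence_floor must be >= 1")
        if not (0 < self.recurrence_lower_frac < self.recurrence_upper_frac <= 1):
            raise ConfigError(
                "need 0 < recurrence_lower_frac < recurrence_upper_frac <= 1, got "
                f"{self.recurrence_lower_frac} / {self.recurrence_upper_frac}"
            )
        lower, upper = self.bounds()
        if lower > upper:
            raise ConfigError(
                f"effective recurrence bounds inverted: L={lower} > U={upper} at n_cells={self.n_cells}"
            )

    def bounds(self) -> tuple[int, int]:
        """Effective (L, U) recurrence bounds for this cohort size."""
        lower = max(
            self.recurrence_floor,
            math.ceil(self.recurrence_lower_frac * self.n_cells - _EPS),
        )
        upper = math.floor(self.recurrence_upper_frac * self.n_cells + _EPS)
        return lower, upper


def quality_pass(call: CellCall, cfg: CohortConfig) -> bool:
    """Quality predicate for one call: depth, QD, FS and alt support.

    Absent FS/QD pass their thresholds (absence of evidence of bias is not
    evidence of bias).
    """
    return (
        call.dp >= cfg.min_depth
        and (call.qd is None or call.qd >= cfg.qd_min)
        and (call.fs is None or call.fs <= cfg.fs_max)
        and call.ad_alt >= 1
    )


def annotation_filter(
    calls: Iterable[CellCall],
    exons: ExonIntervals,
    editing: SiteList | None,
    germline: Sequence[SiteList] = (),
) -> tuple[list[CellCall], Counter, dict[VariantKey, str]]:
    """Remove non-exonic, RNA-editing and germline-listed keys, in that order.

    Returns (kept calls, per-reason ledger counting distinct keys, removal
    reason per removed key).  The first matching reason wins, so a key that
    is both at an editing site and in a germline list is recorded as
    ``editing``.
    """
    if exons.n_intervals == 0:
        raise ConfigError("exon interval set is empty: every candidate would be removed")
    if not germline:
        log.warning("no germline site list supplied; germline removal is disabled")
    reason_by_key: dict[VariantKey, str] = {}
    kept: list[CellCall] = []
    decided: dict[VariantKey, str | None] = {}
    for call in calls:
        key = call.key
        if key not in decided:
            if not exons.contains(key.chrom, key.pos):
                decided[key] = "non_exonic"
            elif editing is not None and key in editing:
                decided[key] = "editing"
            elif any(key in gl for gl in germline):
                decided[key] = "germline_list"
            else:
                decided[key] = None
        reason = decided[key]
        if reason is None:
            kept.append(call)
        else:
            reason_by_key[key] = reason
    ledger = Counter(reason_by_key.values())
    return kept, ledger, reason_by_key


def assign_sets(
    calls_g_by_cell: Mapping[str, Sequence[CellCall]],
    calls_s_by_cell: Mapping[str, Iterable[CellCall]],
) -> dict[str, dict[VariantKey, str]]:
    """Per cell, assign each primary-caller key to consensus set A or B.

    A = present in both callers' calls for that cell; B = primary-only.
    Secondary-only keys are ignored (the primary pipeline is the reference).
    A cell absent from the secondary caller contributes only B keys.
    """
    membership: dict[str, dict[VariantKey, str]] = {}
    for cell_id, g_calls in calls_g_by_cell.items():
        if cell_id not in calls_s_by_cell:
            log.warning("cell %s has no secondary-caller calls; all its keys enter set B", cell_id)
        s_keys = {c.key for c in calls_s_by_cell.get(cell_id, ())}
        membership[cell_id] = {
            key: ("A" if key in s_keys else "B") for key in {c.key for c in g_calls}
        }
    return membership


def recurrence_counts(
    calls_g_by_cell: Mapping[str, Sequence[CellCall]],
) -> Counter:
    """Number of distinct cells in which each key was detected (pseudo-bulk).

    Counted on post-annotation, pre-quality primary-caller calls: the
    negative-set criterion ("no cross-cell recurrence") would be circular if
    quality-failing detections did not count as detections.
    """
    counts: Counter = Counter()
    for calls in calls_g_by_cell.values():
        for key in {c.key for c in calls}:
            counts[key] += 1
    return counts


@dataclass
class CohortLabeling:
    """The cohort-level partition of candidate keys with provenance."""

    n_cells: int
    config: CohortConfig
    label: dict[VariantKey, str] = field(default_factory=dict)
    reason: dict[VariantKey, str] = field(default_factory=dict)
    recurrence: dict[VariantKey, int] = field(default_factory=dict)
    calls: dict[VariantKey, list[CellCall]] = field(default_factory=dict)
    a_cells: dict[VariantKey, frozenset[str]] = field(default_factory=dict)

    def keys_with(self, label: str) -> list[VariantKey]:
        return sorted(k for k, lab in self.label.items() if lab == label)

    def counts(self) -> Counter:
        return Counter(self.label.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": k.chrom,
                "pos": k.pos,
                "ref": k.ref,
                "alt": k.alt,
                "label": self.label[k],
                "reason": self.reason.get(k, "none"),
                "recurrence": self.recurrence.get(k, 0),
            }
            for k in sorted(self.label)
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "label", "reason", "recurrence"]
        )


def label_cohort(
    calls_g_by_cell: Mapping[str, Sequence[CellCall]],
    membership: Mapping[str, Mapping[VariantKey, str]],
    recurrence: Mapping[VariantKey, int],
    cfg: CohortConfig,
    annotation_removed: Mapping[VariantKey, str] | None = None,
) -> CohortLabeling:
    """Partition candidate keys into positive / negative / unsure / removed.

    ``calls_g_by_cell`` must hold the post-annotation primary-caller calls;
    keys removed at annotation enter the labeling as ``removed`` with their
    recorded reason so that labels partition the full candidate universe.
    """
    observed = len(calls_g_by_cell)
    if cfg.n_cells != observed:
        raise ConfigError(f"config says {cfg.n_cells} cells but {observed} were observed")
    lower, upper = cfg.bounds()

    labeling = CohortLabeling(n_cells=cfg.n_cells, config=cfg)
    for key, reason in (annotation_removed or {}).items():
        labeling.label[key] = "removed"
        labeling.reason[key] = reason
        labeling.recurrence[key] = 0

    by_key: dict[VariantKey, list[CellCall]] = {}
    a_cells: dict[VariantKey, set[str]] = {}
    a_pass: dict[VariantKey, bool] = {}
    any_pass: dict[VariantKey, bool] = {}
    for cell_id, calls in calls_g_by_cell.items():
        cell_sets = membership.get(cell_id, {})
        for call in calls:
            key = call.key
            by_key.setdefault(key, []).append(call)
            passed = quality_pass(call, cfg)
            any_pass[key] = any_pass.get(key, False) or passed
            if cell_sets.get(key) == "A":
                a_cells.setdefault(key, set()).add(cell_id)
                if passed:
                    a_pass[key] = True

    for key in by_key:
        rec = recurrence.get(key, 0)
        labeling.recurrence[key] = rec
        labeling.calls[key] = sorted(by_key[key], key=lambda c: (c.cell_id, c.caller))
        labeling.a_cells[key] = frozenset(a_cells.get(key, ()))
        has_a = bool(a_cells.get(key))
        if cfg.require_same_cell_a_pass:
            positive_evidence = a_pass.get(key, False)
        else:
            positive_evidence = has_a and any_pass.get(key, False)
        if rec > upper:
            labeling.label[key] = "removed"
            labeling.reason[key] = "over_recurrent"
        elif positive_evidence and lower <= rec:
            labeling.label[key] = "positive"
            labeling.reason[key] = "none"
        elif (
            not has_a
            and not any_pass.get(key, False)
            and rec <= cfg.negative_max_recurrence
        ):
            labeling.label[key] = "negative"
            labeling.reason[key] = "none"
        else:
            labeling.label[key] = "unsure"
            labeling.reason[key] = "none"
    return labeling
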