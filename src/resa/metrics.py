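"""Evaluation against a truth set, SBS96 spectra, and stage enrichment.

Precision, sensitivity and the precision-weighted F0.5 score

    F0.5 = 1.25 * (precision * sensitivity) / (0.25 * precision + sensitivity)

evaluate a predicted SNV set against an exome-derived (or simulated) truth
set.  The overlap coefficient |X & Y| / min(|X|, |Y|) measures replicate
consistency.  Mutational spectra are 96-class counts over trinucleotide
contexts compared by cosine similarity.  Stage-specific enrichment of
mutated genes uses the upper-tail hypergeometric test at p < 0.05 (raw, as
the headline flag; Benjamini-Hochberg values are reported alongside).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, VcfFormatError
from .variants_io import SBS96_LABELS, VariantKey, trinucleotide_context

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float | None
    sensitivity: float | None
    f_half: float | None


def f_half(precision: float | None, sensitivity: float | None) -> float | None:
    """F0.5: the F-beta score at beta = 0.5, weighting precision over sensitivity."""
    if precision is None or sensitivity is None:
        return None
    if not (0 <= precision <= 1 and 0 <= sensitivity <= 1):
        raise ValueError("precision and sensitivity must lie in [0, 1]")
    if precision == 0 and sensitivity == 0:
        return None
    return 1.25 * (precision * sensitivity) / (0.25 * precision + sensitivity)


def evaluate_against_truth(
    predicted: Iterable[VariantKey], truth: Iterable[VariantKey]
) -> EvalResult:
    """Count TP/FP/FN and compute precision, sensitivity and F0.5.

    0/0 ratios are reported as undefined (``None``), not 0.
    """
    predicted, truth = set(predicted), set(truth)
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    if not predicted:
        log.warning("empty predicted set: precision undefined")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    return EvalResult(tp, fp, fn, precision, sensitivity, f_half(precision, sensitivity))


def overlap_coefficient(x: Iterable, y: Iterable) -> float | None:
    """|X & Y| / min(|X|, |Y|); undefined (``None``) when either set is empty."""
    x, y = set(x), set(y)
    if not x or not y:
        return None
    return len(x & y) / min(len(x), len(y))


@dataclass
class SpectrumSBS96:
    """96-class substitution counts in canonical order."""

    counts: np.ndarray
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "SpectrumSBS96") -> "SpectrumSBS96":
        return SpectrumSBS96(self.counts + other.counts, self.n_excluded + other.n_excluded)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"context": SBS96_LABELS, "count": self.counts.astype(int)})


def spectrum(keys: Iterable[VariantKey], reference: Fasta) -> SpectrumSBS96:
    """Count each key's SBS96 class; N-context keys are excluded and tallied."""
    counts = np.zeros(96, dtype=int)
    n_excluded = 0
    keys = set(keys)
    if not keys:
        log.warning("empty key set: all-zero spectrum")
    for key in keys:
        _, cls = trinucleotide_context(key, reference)
        if cls is None:
            n_excluded += 1
        else:
            counts[cls] += 1
    return SpectrumSBS96(counts, n_excluded)


def cosine_similarity(a, b) -> float | None:
    """Cosine of two 96-vectors (or spectra); undefined for a zero vector."""
    va = np.asarray(a.counts if isinstance(a, SpectrumSBS96) else a, dtype=float)
    vb = np.asarray(b.counts if isinstance(b, SpectrumSBS96) else b, dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return None
    return float(va @ vb / (na * nb))


# ---------------------------------------------------------------------------
# Stage-specific enrichment
# ---------------------------------------------------------------------------

def stage_enrichment(
    carriers: pd.DataFrame,
    stage_sizes: Mapping[str, int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of mutant-cell counts per stage.

    ``carriers`` needs columns gene, stage, carriers (k = mutant cells of
    that gene in that stage); ``stage_sizes`` gives n cells per stage.  For
    each (gene, stage): N = total cells, K = that gene's carriers over all
    stages, and p = P[X >= k] for X ~ Hypergeometric(N, K, n), inclusive of
    the observed k.  ``enriched`` applies the raw alpha threshold; a
    Benjamini-Hochberg column is emitted for transparency.
    """
    required = {"gene", "stage", "carriers"}
    if not required.issubset(carriers.columns):
        raise ValueError(f"carriers table needs columns {sorted(required)}")
    unknown = set(carriers["stage"]) - set(stage_sizes)
    if unknown:
        raise ConsistencyError(f"stages {sorted(unknown)} missing from stage_sizes")
    N = int(sum(stage_sizes.values()))
    stages = sorted(stage_sizes)
    rows = []
    for gene, sub in carriers.groupby("gene", sort=True):
        k_by_stage = dict(zip(sub["stage"], sub["carriers"].astype(int)))
        K = int(sum(k_by_stage.values()))
        for stage in stages:
            n = int(stage_sizes[stage])
            k = int(k_by_stage.get(stage, 0))
            if k > min(n, K):
                raise ConsistencyError(
                    f"gene {gene} stage {stage}: k={k} exceeds min(n={n}, K={K})"
                )
            p = float(hypergeom.sf(k - 1, N, K, n))  # upper tail including k
            rows.append(
                {"gene": gene, "stage": stage, "k": k, "n": n, "K": K, "N": N, "p_value": p}
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["enriched"] = table["p_value"] < alpha
    else:
        table["p_bh"] = []
        table["enriched"] = []
    return table


def load_gene_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read gene spans from a 4-column BED (chrom, start, end, name)."""
    from .variants_io import _open_text

    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise VcfFormatError(f"{path}: gene BED needs 4 columns (line {lineno})")
            genes.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return genes


def assign_gene(
    key: VariantKey, genes: Sequence[tuple[str, int, int, str]]
) -> str | None:
    """First overlapping gene for a key, ties broken alphabetically."""
    hits = sorted(
        name for chrom, start, end, name in genes if chrom == key.chrom and start < key.pos <= end
    )
    return hits[0] if hits else None


def carrier_table(
    mutant_cells_by_key: Mapping[VariantKey, Iterable[str]],
    genes: Sequence[tuple[str, int, int, str]],
    stage_by_cell: Mapping[str, str],
) -> pd.DataFrame:
    """Per (gene, stage) mutant-cell counts from per-key carrier cells.

    A cell carries a gene if it carries at least one mutant key of that
    gene; keys outside every gene span are dropped.
    """
    cells_by_gene: dict[str, set[str]] = {}
    for key, cells in mutant_cells_by_key.items():
        gene = assign_gene(key, genes)
        if gene is None:
            continue
        cells_by_gene.setdefault(gene, set()).update(cells)
    rows = []
    for gene in sorted(cells_by_gene):
        per_stage: dict[str, int] = {}
        for cell in cells_by_gene[gene]:
            per_stage[stage_by_cell[cell]] = per_stage.get(stage_by_cell[cell], 0) + 1
        for stage in sorted(per_stage):
            rows.append({"gene": gene, "stage": stage, "carriers": per_stage[stage]})
    return pd.DataFrame(rows, columns=["gene", "stage", "carriers"])
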