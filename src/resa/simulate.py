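"""Synthetic paired-caller cohorts with known ground truth.

A desk-scale stand-in for BAM-level spike-in benchmarking: instead of
planting reads, the simulator plants *calls*.  It emits, per cell, a pair
of VCFs (primary caller G with full quality fields; secondary caller S
with PASS-gated records), together with the reference FASTA, exon/gene
BEDs, a gnomAD-style germline list, an editing-site list, a truth VCF and
a full per-key truth ledger.  Four variant classes are emulated:

* clonal somatic SNVs — present in a cell with probability
  prevalence_clone * (1 - dropout); contexts drawn from a configurable
  SBS96 spectrum (UV-like C>T-heavy by default);
* germline SNVs — present in nearly every cell and listed in the
  population site list;
* RNA-editing sites — moderate prevalence, listed in the editing list;
* per-cell artefacts — fresh Poisson draws at random exonic positions
  with low-quality values, so recurrence across cells is rare.

Quality fields (QUAL/QD/FS, depth, VAF) are drawn from class-conditional
distributions: true variants score high, artefacts low, with enough
overlap that the unsure set is non-empty and the joint classifier has a
learnable but non-trivial problem.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .features import QUALITY_FEATURE_NAMES, DesignMatrices, sequence_feature_names
from .variants_io import (
    BASES,
    CellCall,
    VariantKey,
    sbs96_class_from_context,
    write_cell_vcf,
    write_sites_vcf,
)

log = logging.getLogger(__name__)


def uv_like_spectrum() -> np.ndarray:
    """A C>T-dominated 96-vector resembling a UV-exposure spectrum.

    75% of the mass sits on C>T classes (doubled again at pyrimidine 5'
    neighbours); the remainder is spread uniformly.
    """
    w = np.ones(96)
    w[32:48] = 0.0
    w *= 0.25 / w.sum()
    ct = np.ones(16)
    for five in ("C", "T"):
        i = BASES.index(five) * 4
        ct[i : i + 4] *= 2.0
    w[32:48] = 0.75 * ct / ct.sum()
    return w


@dataclass(frozen=True)
class QualityModel:
    """Class-conditional distributions for one variant class.

    QUAL ~ Normal(qual_mean, qual_sd) clipped at 1; QD ~ Normal clipped to
    [0, 60]; FS ~ Exponential(fs_scale); depth ~ NegativeBinomial with the
    given mean and dispersion (variance = mean + mean^2/dispersion).
    """

    qual_mean: float
    qual_sd: float
    qd_mean: float
    qd_sd: float
    fs_scale: float
    depth_mean: float
    depth_dispersion: float


TRUE_QUALITY = QualityModel(100.0, 30.0, 15.0, 4.0, 3.0, 12.0, 3.0)
ARTEFACT_QUALITY = QualityModel(25.0, 12.0, 3.0, 2.5, 20.0, 6.0, 3.0)


@dataclass
class SimConfig:
    """Cohort-generation parameters; the defaults define the default preset."""

    n_cells: int = 50
    n_somatic: int = 200
    somatic_prevalence: tuple[float, ...] = (0.4,)
    n_germline: int = 100
    germline_prevalence: float = 0.95
    n_editing: int = 30
    editing_prevalence: float = 0.30
    n_artefact_per_cell: float = 20.0
    dropout: float = 0.6
    vaf_somatic: tuple[float, float] = (8.0, 8.0)
    vaf_germline: tuple[float, float] = (10.0, 10.0)
    vaf_editing: tuple[float, float] = (6.0, 6.0)
    vaf_artefact: tuple[float, float] = (1.5, 6.0)
    true_quality: QualityModel = TRUE_QUALITY
    artefact_quality: QualityModel = ARTEFACT_QUALITY
    caller_s_sensitivity: float = 0.85
    artefact_in_s: float = 0.05
    spectrum_bias: np.ndarray | None = None  # None -> uv_like_spectrum()
    ref_length: int = 100_000
    exon_fraction: float = 0.5
    n_genes: int = 40
    stages: tuple[str, ...] = ("T0", "phase1", "phase2", "phase3")
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_cells < 4:
            raise ConfigError("n_cells must be >= 4")
        probs = (
            self.germline_prevalence,
            self.editing_prevalence,
            self.dropout,
            self.caller_s_sensitivity,
            self.artefact_in_s,
            *self.somatic_prevalence,
        )
        if any(not (0 <= p <= 1) for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if not self.somatic_prevalence:
            raise ConfigError("need at least one somatic clone prevalence")
        if any(p >= self.germline_prevalence for p in self.somatic_prevalence):
            raise ConfigError("clone prevalences must be below germline prevalence")
        if self.spectrum_bias is not None:
            bias = np.asarray(self.spectrum_bias, dtype=float)
            if bias.shape != (96,) or np.any(bias < 0) or bias.sum() <= 0:
                raise ConfigError("spectrum_bias must be a non-negative 96-vector")


#: Named study conditions.  ``tiny`` is sized for smoke tests; ``default``
#: is the standard benchmark cohort; ``high_burden`` exercises the regime
#: with an order of magnitude more somatic mutations.
PRESETS: dict[str, SimConfig] = {
    "tiny": SimConfig(
        n_cells=12,
        n_somatic=20,
        somatic_prevalence=(0.5,),
        n_germline=20,
        n_editing=8,
        n_artefact_per_cell=8.0,
        dropout=0.3,
        ref_length=30_000,
        n_genes=15,
        stages=("T0", "treated"),
    ),
    "default": SimConfig(),
    "high_burden": SimConfig(n_somatic=2000, ref_length=400_000, n_genes=120),
}


def preset_config(name: str, seed: int | None = None) -> SimConfig:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return replace(cfg, seed=seed) if seed is not None else replace(cfg)


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

@dataclass
class ReferenceBundle:
    """A toy genome: one contig plus exon and gene spans (0-based half-open)."""

    chrom: str
    sequence: str
    exons: list[tuple[int, int]]
    genes: list[tuple[int, int, str]]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "reference.fa"
        with open(fasta, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.sequence), 60):
                fh.write(self.sequence[i : i + 60] + "\n")
        exons_bed = outdir / "exons.bed"
        with open(exons_bed, "w") as fh:
            for s, e in self.exons:
                fh.write(f"{self.chrom}\t{s}\t{e}\n")
        genes_bed = outdir / "genes.bed"
        with open(genes_bed, "w") as fh:
            for s, e, name in self.genes:
                fh.write(f"{self.chrom}\t{s}\t{e}\t{name}\n")
        return {"fasta": fasta, "exons_bed": exons_bed, "genes_bed": genes_bed}


def generate_reference(
    length: int = 100_000,
    seed: int = 0,
    exon_fraction: float = 0.5,
    n_genes: int = 40,
    chrom: str = "chr1",
) -> ReferenceBundle:
    """Random A/C/G/T genome with genes tiling the contig and one central
    exon per gene covering ``exon_fraction`` of the gene span."""
    if length < 10_000:
        raise ConfigError(f"reference length must be >= 10 kb, got {length}")
    if not (0 < exon_fraction <= 1):
        raise ConfigError("exon_fraction must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    sequence = "".join(rng.choice(list("ACGT"), size=length))
    exons, genes = [], []
    for i in range(n_genes):
        gs = i * length // n_genes
        ge = (i + 1) * length // n_genes
        pad = int(round((ge - gs) * (1 - exon_fraction) / 2))
        exons.append((gs + pad, ge - pad))
        genes.append((gs, ge, f"GENE{i + 1:03d}"))
    return ReferenceBundle(chrom=chrom, sequence=sequence, exons=exons, genes=genes)


# ---------------------------------------------------------------------------
# Cohort planting
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground-truth ledger: class, clone and carrier cells per emitted key."""

    class_by_key: dict[VariantKey, str]
    clone_by_key: dict[VariantKey, int | None]
    cells_by_key: dict[VariantKey, tuple[str, ...]]

    def keys_of(self, cls: str) -> set[VariantKey]:
        return {k for k, c in self.class_by_key.items() if c == cls}


@dataclass
class SimCohort:
    config: SimConfig
    bundle: ReferenceBundle
    cell_ids: list[str]
    stage_by_cell: dict[str, str]
    calls_g: dict[str, list[CellCall]]
    calls_s: dict[str, list[CellCall]]
    truth: SimTruth


def _pl_from_counts(dp: int, ad_alt: int) -> tuple[int, int, int]:
    """Phred genotype likelihoods for (0/0, 0/1, 1/1) under a binomial read model."""
    from scipy.stats import binom

    lls = np.array([binom.logpmf(ad_alt, dp, p) for p in (0.02, 0.5, 0.98)])
    pl = np.round(-10.0 * (lls - lls.max()) / np.log(10.0)).astype(int)
    return tuple(int(min(x, 990)) for x in pl)


def _draw_call(
    rng: np.random.Generator,
    key: VariantKey,
    cell_id: str,
    qm: QualityModel,
    vaf_beta: tuple[float, float],
) -> CellCall:
    p_nb = qm.depth_dispersion / (qm.depth_dispersion + qm.depth_mean)
    dp = max(1, int(rng.negative_binomial(qm.depth_dispersion, p_nb)))
    vaf = float(rng.beta(*vaf_beta))
    ad_alt = 0
    for _ in range(100):
        ad_alt = int(rng.binomial(dp, vaf))
        if ad_alt >= 1:
            break
    ad_alt = max(1, min(ad_alt, dp))
    return CellCall(
        key=key,
        cell_id=cell_id,
        caller="G",
        dp=dp,
        ad_ref=dp - ad_alt,
        ad_alt=ad_alt,
        qual=round(max(1.0, float(rng.normal(qm.qual_mean, qm.qual_sd))), 2),
        pl=_pl_from_counts(dp, ad_alt),
        fs=round(min(float(rng.exponential(qm.fs_scale)), 500.0), 2),
        qd=round(float(np.clip(rng.normal(qm.qd_mean, qm.qd_sd), 0.0, 60.0)), 2),
        pass_flag=True,
    )


def _as_s_call(call: CellCall) -> CellCall:
    return dataclasses.replace(call, caller="S", pass_flag=True)


def plant_cohort(cfg: SimConfig, bundle: ReferenceBundle) -> SimCohort:
    """Plant all variant classes and synthesize both callers' per-cell calls.

    Site positions are sampled without collision across the planted classes
    (somatic/germline/editing); artefact positions are drawn per cell from
    the remaining exonic positions, so cross-cell artefact recurrence only
    arises by chance collision.  Every planted variant is guaranteed to be
    observed in at least one cell (presence vectors are redrawn when empty,
    i.e. conditioned on detectability).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    seq = bundle.sequence
    chrom = bundle.chrom

    positions = [
        p
        for (s, e) in bundle.exons
        for p in range(max(s + 1, 2), min(e, len(seq) - 1) + 1)
    ]
    n_planted = cfg.n_somatic + cfg.n_germline + cfg.n_editing
    if n_planted > len(positions) // 2:
        raise ConfigError(
            f"{n_planted} planted sites need more than half of {len(positions)} exonic bases; "
            "use a longer reference"
        )

    # class -> candidate (pos, alt) pool, for spectrum-faithful somatic sampling
    class_pool: dict[int, list[tuple[int, str]]] = {c: [] for c in range(96)}
    for p in positions:
        ref = seq[p - 1]
        tri = seq[p - 2 : p + 1]
        for alt in BASES:
            if alt == ref:
                continue
            cls = sbs96_class_from_context(ref, alt, tri)
            if cls is not None:
                class_pool[cls].append((p, alt))

    bias = (
        np.asarray(cfg.spectrum_bias, dtype=float)
        if cfg.spectrum_bias is not None
        else uv_like_spectrum()
    ).copy()
    for c in range(96):
        if not class_pool[c]:
            bias[c] = 0.0
    bias /= bias.sum()

    used_pos: set[int] = set()
    somatic_keys: list[VariantKey] = []
    for cls in rng.choice(96, size=cfg.n_somatic, p=bias):
        pool = class_pool[int(cls)]
        for _ in range(10_000):
            pos, alt = pool[int(rng.integers(len(pool)))]
            if pos not in used_pos:
                break
        else:
            raise ConfigError(f"candidate pool for SBS96 class {cls} exhausted")
        used_pos.add(pos)
        somatic_keys.append(VariantKey(chrom, pos, seq[pos - 1], alt))

    def _draw_site() -> VariantKey:
        for _ in range(100_000):
            pos = positions[int(rng.integers(len(positions)))]
            if pos not in used_pos:
                break
        else:
            raise ConfigError("exonic position pool exhausted")
        used_pos.add(pos)
        ref = seq[pos - 1]
        alt = [b for b in BASES if b != ref][int(rng.integers(3))]
        return VariantKey(chrom, pos, ref, alt)

    germline_keys = [_draw_site() for _ in range(cfg.n_germline)]
    editing_keys = [_draw_site() for _ in range(cfg.n_editing)]

    n_clones = len(cfg.somatic_prevalence)
    clone_of = [i * n_clones // cfg.n_somatic for i in range(cfg.n_somatic)]
    expected_rec = max(cfg.somatic_prevalence) * (1 - cfg.dropout) * cfg.n_cells
    if expected_rec < 3:
        log.warning(
            "expected somatic recurrence %.1f is below the default recurrence floor of 3; "
            "the core filter may find nothing",
            expected_rec,
        )

    def _presence(p: float) -> np.ndarray:
        while True:
            v = rng.random(cfg.n_cells) < p
            if v.any():
                return v

    plan: list[tuple[VariantKey, str, int | None, np.ndarray, QualityModel, tuple[float, float]]] = []
    for i, key in enumerate(somatic_keys):
        p = cfg.somatic_prevalence[clone_of[i]] * (1 - cfg.dropout)
        plan.append((key, "somatic", clone_of[i], _presence(p), cfg.true_quality, cfg.vaf_somatic))
    for key in germline_keys:
        plan.append((key, "germline", None, _presence(cfg.germline_prevalence), cfg.true_quality, cfg.vaf_germline))
    for key in editing_keys:
        plan.append((key, "editing", None, _presence(cfg.editing_prevalence), cfg.true_quality, cfg.vaf_editing))

    cell_ids = [f"cell{i:03d}" for i in range(cfg.n_cells)]
    stage_by_cell = {c: cfg.stages[int(rng.integers(len(cfg.stages)))] for c in cell_ids}
    calls_g: dict[str, list[CellCall]] = {c: [] for c in cell_ids}
    calls_s: dict[str, list[CellCall]] = {c: [] for c in cell_ids}
    class_by_key: dict[VariantKey, str] = {}
    clone_by_key: dict[VariantKey, int | None] = {}
    cells_by_key: dict[VariantKey, list[str]] = {}

    for key, cls_name, clone, present, qm, vaf_beta in plan:
        class_by_key[key] = cls_name
        clone_by_key[key] = clone
        cells_by_key[key] = []
        for i, cell in enumerate(cell_ids):
            if not present[i]:
                continue
            call = _draw_call(rng, key, cell, qm, vaf_beta)
            calls_g[cell].append(call)
            cells_by_key[key].append(cell)
            if rng.random() < cfg.caller_s_sensitivity:
                calls_s[cell].append(_as_s_call(call))

    artefact_pool = np.array([p for p in positions if p not in used_pos])
    for cell in cell_ids:
        count = min(int(rng.poisson(cfg.n_artefact_per_cell)), len(artefact_pool))
        art_pos = rng.choice(artefact_pool, size=count, replace=False)
        for pos in art_pos:
            pos = int(pos)
            ref = seq[pos - 1]
            alt = [b for b in BASES if b != ref][int(rng.integers(3))]
            key = VariantKey(chrom, pos, ref, alt)
            call = _draw_call(rng, key, cell, cfg.artefact_quality, cfg.vaf_artefact)
            calls_g[cell].append(call)
            class_by_key.setdefault(key, "artefact")
            clone_by_key.setdefault(key, None)
            cells_by_key.setdefault(key, []).append(cell)
            if rng.random() < cfg.artefact_in_s:
                calls_s[cell].append(_as_s_call(call))

    truth = SimTruth(
        class_by_key=class_by_key,
        clone_by_key=clone_by_key,
        cells_by_key={k: tuple(sorted(v)) for k, v in cells_by_key.items()},
    )
    return SimCohort(
        config=cfg,
        bundle=bundle,
        cell_ids=cell_ids,
        stage_by_cell=stage_by_cell,
        calls_g=calls_g,
        calls_s=calls_s,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort as the on-disk inputs the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = cohort.bundle.write(outdir)
    contigs = {cohort.bundle.chrom: len(cohort.bundle.sequence)}
    cells_dir = outdir / "cells"
    cells_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for cell in cohort.cell_ids:
        g_path = cells_dir / f"{cell}.G.vcf"
        s_path = cells_dir / f"{cell}.S.vcf"
        _write_cell_or_empty(cohort.calls_g[cell], g_path, contigs, cell)
        _write_cell_or_empty(cohort.calls_s[cell], s_path, contigs, cell)
        manifest_rows.append(
            (cell, f"cells/{cell}.G.vcf", f"cells/{cell}.S.vcf", cohort.stage_by_cell[cell])
        )
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("cell_id\tpath_vcf_G\tpath_vcf_S\tstage\n")
        for row in manifest_rows:
            fh.write("\t".join(row) + "\n")

    germline_tsv = outdir / "germline.tsv"
    with open(germline_tsv, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for k in sorted(cohort.truth.keys_of("germline")):
            fh.write(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\n")
    editing_tsv = outdir / "editing.tsv"
    with open(editing_tsv, "w") as fh:
        fh.write("chrom\tpos\n")
        for k in sorted(cohort.truth.keys_of("editing")):
            fh.write(f"{k.chrom}\t{k.pos}\n")
    truth_vcf = outdir / "truth.vcf"
    write_sites_vcf(truth_vcf, cohort.truth.keys_of("somatic"), contigs)

    sim_truth = outdir / "sim_truth.tsv"
    with open(sim_truth, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tclass\tclone\tn_cells_present\n")
        for k in sorted(cohort.truth.class_by_key):
            clone = cohort.truth.clone_by_key[k]
            fh.write(
                f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\t{cohort.truth.class_by_key[k]}\t"
                f"{'' if clone is None else clone}\t{len(cohort.truth.cells_by_key[k])}\n"
            )
    stages_tsv = outdir / "stages.tsv"
    with open(stages_tsv, "w") as fh:
        fh.write("cell_id\tstage\n")
        for cell in cohort.cell_ids:
            fh.write(f"{cell}\t{cohort.stage_by_cell[cell]}\n")

    cfg_dict = dataclasses.asdict(cohort.config)
    if cfg_dict["spectrum_bias"] is not None:
        cfg_dict["spectrum_bias"] = [float(x) for x in cfg_dict["spectrum_bias"]]
    (outdir / "sim_config.json").write_text(json.dumps(cfg_dict, indent=2, sort_keys=True) + "\n")

    paths.update(
        manifest=manifest,
        germline_tsv=germline_tsv,
        editing_tsv=editing_tsv,
        truth_vcf=truth_vcf,
        sim_truth=sim_truth,
        stages_tsv=stages_tsv,
    )
    return paths


def _write_cell_or_empty(calls, path, contigs, cell_id):
    if calls:
        write_cell_vcf(calls, path, contigs)
    else:
        _write_empty_cell_vcf(path, contigs, cell_id)


def _write_empty_cell_vcf(path, contigs, cell_id):
    import pysam

    from .variants_io import _base_header

    header = _base_header(contigs)
    header.add_sample(cell_id)
    with pysam.VariantFile(str(path), "w", header=header):
        pass


def end_to_end_fixture(
    preset: str, outdir: str | Path, seed: int | None = None
) -> tuple[dict[str, Path], SimCohort]:
    """Generate a named preset and write every input the pipeline needs.

    Returns the path map and the in-memory cohort (with its truth ledger).
    Deterministic: the same preset and seed reproduce the directory
    byte-for-byte.
    """
    cfg = preset_config(preset, seed)
    bundle = generate_reference(
        length=cfg.ref_length,
        seed=cfg.seed,
        exon_fraction=cfg.exon_fraction,
        n_genes=cfg.n_genes,
    )
    cohort = plant_cohort(cfg, bundle)
    paths = write_cohort(cohort, outdir)
    return paths, cohort


# ---------------------------------------------------------------------------
# Synthetic labeled feature sets (classifier calibration)
# ---------------------------------------------------------------------------

#: True standardized-scale weights used by :func:`synthetic_design`.
SYNTHETIC_WEIGHTS = {"qual": 1.5, "vaf": 4.0}


def synthetic_design(
    n: int, seed: int, informative: bool = True
) -> tuple[DesignMatrices, dict[str, float]]:
    """Labeled design matrices drawn from a known logistic model.

    Quality features are sampled from plausible marginals; when
    ``informative``, labels follow a logistic model over the standardized
    qual and vaf columns (near-separable); otherwise labels are independent
    Bernoulli(0.5) noise.  Sequence contexts are uniform over the 96
    classes, carrying no label signal either way.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    qual = rng.normal(60.0, 25.0, size=n).clip(1.0)
    dp = rng.negative_binomial(3, 3 / 15, size=n) + 1
    vaf = rng.beta(2.0, 2.0, size=n)
    pl_rr = rng.uniform(0, 200, size=n)
    pl_ra = np.zeros(n)
    pl_aa = rng.uniform(0, 200, size=n)
    ad_alt = np.maximum(1, np.round(vaf * dp))
    ad_ref = dp - ad_alt
    Xq = np.column_stack([qual, dp, vaf, pl_rr, pl_ra, pl_aa, ad_ref, ad_alt]).astype(float)

    if informative:
        z = np.zeros(n)
        for name, w in SYNTHETIC_WEIGHTS.items():
            col = Xq[:, QUALITY_FEATURE_NAMES.index(name)]
            sd = col.std() or 1.0
            z += w * (col - col.mean()) / sd
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-z))).astype(int)
    else:
        y = (rng.random(n) < 0.5).astype(int)
    # guarantee both classes for tiny n
    if y.sum() == 0:
        y[0] = 1
    elif y.sum() == n:
        y[0] = 0

    classes = rng.integers(0, 96, size=n)
    Xs = np.zeros((n, 102))
    Xs[np.arange(n), classes // 16] = 1.0
    Xs[np.arange(n), 6 + classes] = 1.0

    keys = [VariantKey("chrS", i + 2, "C", "A") for i in range(n)]
    design = DesignMatrices(
        keys=keys,
        X_quality=Xq,
        X_sequence=Xs,
        quality_columns=QUALITY_FEATURE_NAMES,
        sequence_columns=sequence_feature_names(),
        y=y,
    )
    return design, dict(SYNTHETIC_WEIGHTS)
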