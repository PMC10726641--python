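"""End-to-end orchestration: cohort run, refinement, and their file outputs.

``run_cohort_files`` reads a cell manifest plus annotation resources and
produces the cohort labeling; ``refine_cohort`` trains the joint classifier
on the labeled sets and expands the positive set from the unsure set.  The
file writers emit deterministic, sorted outputs (``labels.tsv``,
``calls.tsv``, per-label VCFs, ``run_log.json``, ``model.json``,
``predictions.tsv``, ``final_positive.vcf``) so identical inputs and seed
reproduce byte-identical results regardless of manifest row order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import core, jlr
from .core import CohortConfig, CohortLabeling
from .errors import VcfFormatError
from .features import build_design_matrices
from .variants_io import (
    CellCall,
    ExonIntervals,
    SiteList,
    VariantKey,
    load_site_list,
    parse_cell_vcf,
    write_sites_vcf,
)

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("cell_id", "path_vcf_G", "path_vcf_S")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the cell manifest; paths resolve relative to it.

    Rows are sorted by cell_id so downstream results are independent of the
    order cells are listed in.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise VcfFormatError(f"{path}: manifest lacks required column(s) {missing}")
    if df["cell_id"].duplicated().any():
        raise VcfFormatError(f"{path}: duplicate cell_id rows")
    base = path.parent
    for col in ("path_vcf_G", "path_vcf_S"):
        df[col] = [str(p) if Path(p).is_absolute() else str(base / p) for p in df[col]]
    return df.sort_values("cell_id").reset_index(drop=True)


@dataclass
class RunResult:
    labeling: CohortLabeling
    ledger: Mapping[str, int]
    config: CohortConfig
    stage_by_cell: dict[str, str] | None = None


def run_cohort_files(
    manifest: str | Path,
    exons: str | Path,
    editing: str | Path | None = None,
    germline: Sequence[str | Path] = (),
    matched_normal: str | Path | None = None,
    config: CohortConfig | None = None,
    **config_overrides,
) -> RunResult:
    """Run the full filtering-and-labeling stage from files.

    Per cell, both callers' VCFs are parsed and normalized; the primary
    calls pass the annotation filters; dual-caller consensus sets,
    cross-cell recurrence and quality verdicts are combined into the
    cohort labeling.
    """
    mdf = read_manifest(manifest)
    calls_g: dict[str, list[CellCall]] = {}
    calls_s: dict[str, list[CellCall]] = {}
    for row in mdf.itertuples(index=False):
        calls_g[row.cell_id] = parse_cell_vcf(row.path_vcf_G, "G", row.cell_id)
        calls_s[row.cell_id] = parse_cell_vcf(row.path_vcf_S, "S", row.cell_id)

    exon_ivs = ExonIntervals.from_bed(exons)
    editing_list = load_site_list(editing, "editing") if editing else None
    germline_lists: list[SiteList] = [
        load_site_list(p, "germline_population") for p in germline
    ]
    if matched_normal:
        germline_lists.append(load_site_list(matched_normal, "germline_matched_normal"))

    pooled = [c for cell in sorted(calls_g) for c in calls_g[cell]]
    kept, ledger, removed = core.annotation_filter(pooled, exon_ivs, editing_list, germline_lists)
    kept_by_cell: dict[str, list[CellCall]] = {cell: [] for cell in calls_g}
    for call in kept:
        kept_by_cell[call.cell_id].append(call)

    membership = core.assign_sets(kept_by_cell, calls_s)
    recurrence = core.recurrence_counts(kept_by_cell)
    cfg = config or CohortConfig(n_cells=len(kept_by_cell), **config_overrides)
    labeling = core.label_cohort(kept_by_cell, membership, recurrence, cfg, removed)

    stages = None
    if "stage" in mdf.columns:
        stages = dict(zip(mdf["cell_id"], mdf["stage"]))
    return RunResult(labeling=labeling, ledger=dict(ledger), config=cfg, stage_by_cell=stages)


# ---------------------------------------------------------------------------
# Run outputs
# ---------------------------------------------------------------------------

def _contig_names(keys) -> list[str]:
    return sorted({k.chrom for k in keys})


def write_run_outputs(result: RunResult, outdir: str | Path) -> dict[str, Path]:
    """Write labels.tsv, calls.tsv, per-label VCFs and run_log.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labeling = result.labeling

    labels_tsv = outdir / "labels.tsv"
    labeling.to_frame().to_csv(labels_tsv, sep="\t", index=False)

    calls_tsv = outdir / "calls.tsv"
    rows = []
    for key in sorted(labeling.calls):
        a_cells = labeling.a_cells.get(key, frozenset())
        for call in labeling.calls[key]:
            pl = call.pl or (0, 0, 0)
            rows.append(
                {
                    "chrom": key.chrom,
                    "pos": key.pos,
                    "ref": key.ref,
                    "alt": key.alt,
                    "cell_id": call.cell_id,
                    "dp": call.dp,
                    "ad_ref": call.ad_ref,
                    "ad_alt": call.ad_alt,
                    "qual": call.qual,
                    "pl_rr": pl[0],
                    "pl_ra": pl[1],
                    "pl_aa": pl[2],
                    "fs": "" if call.fs is None else call.fs,
                    "qd": "" if call.qd is None else call.qd,
                    "set": "A" if call.cell_id in a_cells else "B",
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "cell_id", "dp", "ad_ref", "ad_alt",
            "qual", "pl_rr", "pl_ra", "pl_aa", "fs", "qd", "set",
        ],
    ).to_csv(calls_tsv, sep="\t", index=False)

    info_defs = (
        ("LABEL", "1", "String", "Cohort label"),
        ("RECURRENCE", "1", "Integer", "Distinct cells with a detection"),
    )
    paths: dict[str, Path] = {"labels_tsv": labels_tsv, "calls_tsv": calls_tsv}
    contigs = _contig_names(labeling.label)
    for label in ("positive", "negative", "unsure"):
        keys = labeling.keys_with(label)
        vcf_path = outdir / f"{label}.vcf"
        write_sites_vcf(
            vcf_path,
            keys,
            contigs,
            annotations={
                k: {"LABEL": label, "RECURRENCE": labeling.recurrence.get(k, 0)} for k in keys
            },
            info_defs=info_defs,
        )
        paths[f"{label}_vcf"] = vcf_path

    lower, upper = result.config.bounds()
    run_log = {
        "config": dataclasses.asdict(result.config),
        "effective_bounds": {"lower": lower, "upper": upper},
        "annotation_ledger": dict(result.ledger),
        "label_counts": dict(labeling.counts()),
        "n_cells": labeling.n_cells,
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    paths["run_log"] = log_path
    return paths


def load_run(outdir: str | Path) -> RunResult:
    """Reconstruct a labeling from a run's labels.tsv / calls.tsv / run_log.json."""
    outdir = Path(outdir)
    run_log = json.loads((outdir / "run_log.json").read_text())
    cfg = CohortConfig(**run_log["config"])
    labeling = CohortLabeling(n_cells=run_log["n_cells"], config=cfg)

    labels = pd.read_csv(outdir / "labels.tsv", sep="\t")
    for row in labels.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        labeling.label[key] = row.label
        labeling.reason[key] = row.reason
        labeling.recurrence[key] = int(row.recurrence)

    calls = pd.read_csv(outdir / "calls.tsv", sep="\t")
    a_cells: dict[VariantKey, set[str]] = {}
    for row in calls.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        call = CellCall(
            key=key,
            cell_id=str(row.cell_id),
            caller="G",
            dp=int(row.dp),
            ad_ref=int(row.ad_ref),
            ad_alt=int(row.ad_alt),
            qual=float(row.qual),
            pl=(int(row.pl_rr), int(row.pl_ra), int(row.pl_aa)),
            fs=None if pd.isna(row.fs) else float(row.fs),
            qd=None if pd.isna(row.qd) else float(row.qd),
        )
        labeling.calls.setdefault(key, []).append(call)
        if row.set == "A":
            a_cells.setdefault(key, set()).add(str(row.cell_id))
    labeling.a_cells = {k: frozenset(v) for k, v in a_cells.items()}
    return RunResult(
        labeling=labeling, ledger=run_log["annotation_ledger"], config=cfg, stage_by_cell=None
    )


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------

@dataclass
class RefineResult:
    model: jlr.JlrModel
    refined_keys: list[VariantKey]
    final: dict[VariantKey, str]  # key -> "core" | "refined"
    predictions: pd.DataFrame

    @property
    def final_keys(self) -> list[VariantKey]:
        return sorted(self.final)


def refine_cohort(
    labeling: CohortLabeling,
    reference: Fasta,
    signatures=None,
    seed: int | None = None,
    c_quality: float = 1.0,
    c_sequence: float = 1.0,
    threshold: float = 0.5,
    w_cutoff: float = 0.5,
    aggregate: str = "mean",
) -> RefineResult:
    """Train the joint classifier and expand the positive set from the unsure set."""
    seed = labeling.config.seed if seed is None else seed
    labeled, unsure = build_design_matrices(labeling, reference, signatures, aggregate)
    model = jlr.fit_jlr(
        labeled,
        seed=seed,
        c_quality=c_quality,
        c_sequence=c_sequence,
        threshold=threshold,
        w_cutoff=w_cutoff,
    )
    refined, predictions = jlr.refine_unsure(model, unsure)
    final = jlr.final_positive_set(labeling.keys_with("positive"), refined)
    return RefineResult(model=model, refined_keys=refined, final=final, predictions=predictions)


def write_refine_outputs(result: RefineResult, outdir: str | Path) -> dict[str, Path]:
    """Write final_positive.vcf (with provenance), model.json and predictions.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    final_vcf = outdir / "final_positive.vcf"
    write_sites_vcf(
        final_vcf,
        result.final,
        _contig_names(result.final),
        annotations={k: {"PROV": prov} for k, prov in result.final.items()},
        info_defs=(("PROV", "1", "String", "core or refined"),),
    )
    model_json = outdir / "model.json"
    result.model.save(model_json)
    predictions_tsv = outdir / "predictions.tsv"
    result.predictions.to_csv(predictions_tsv, sep="\t", index=False)
    return {"final_vcf": final_vcf, "model_json": model_json, "predictions_tsv": predictions_tsv}
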