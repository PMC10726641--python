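"""Readers, writers and normalization for the formats the pipeline touches.

The pipeline consumes per-cell VCFs from two variant-calling pipelines
("caller G", a STAR/HaplotypeCaller-style caller whose records carry
QUAL/DP/AD/PL/FS/QD, and "caller S", a Minimap2/Strelka-style caller whose
records are gated on its own PASS flag), plus BED exon intervals, TSV/VCF
site lists (RNA-editing databases, population or matched-normal germline
lists, exome truth sets) and an indexed FASTA reference used to resolve
trinucleotide context.

Conventions
-----------
* VCF positions are 1-based; BED intervals 0-based half-open; every
  position held in memory is 1-based.
* Only biallelic SNVs enter the data model: multi-allelic records are
  split into per-alt calls, indels/MNVs are skipped (and counted).
* Editing-site lists are matched by (chrom, pos) only — editing databases
  are site-level; germline and truth lists are matched on the full
  (chrom, pos, ref, alt) key.
"""

from __future__ import annotations

import gzip
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from pyfaidx import Fasta

from .errors import ConsistencyError, ReferenceMismatchError, VcfFormatError

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The six pyrimidine-centric substitution types, canonical order.
MUTATION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 single-base-substitution classes in canonical order:
#: lexicographic by (mutation type, 5' base, 3' base); class 0 is A[C>A]A.
SBS96_LABELS = tuple(
    f"{five}[{mt}]{three}" for mt in MUTATION_TYPES for five in BASES for three in BASES
)

SITE_LIST_KINDS = (
    "editing",
    "germline_population",
    "germline_matched_normal",
    "exome_truth",
)


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a genomic SNV: the unit of cross-cell recurrence counting.

    ``pos`` is 1-based.  ``ref`` and ``alt`` must be distinct single bases;
    indels and MNVs are rejected on ingest so the candidate universe is
    SNV-only.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single A/C/G/T bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class CellCall:
    """One caller's observation of a :class:`VariantKey` in one cell.

    Carries the quality evidence used by filtering and by the quality
    submodel: total depth, allele depths, variant quality, min-normalized
    Phred genotype likelihoods, Fisher strand bias (FS), quality-by-depth
    (QD) and positional-bias rank-sum.  FS/QD/read_pos_bias may be absent
    (``None``) — absence is *not* zero and is treated as passing the
    corresponding threshold.
    """

    key: VariantKey
    cell_id: str
    caller: str  # "G" or "S"
    dp: int
    ad_ref: int
    ad_alt: int
    qual: float
    pl: tuple[int, int, int] | None = None
    fs: float | None = None
    qd: float | None = None
    read_pos_bias: float | None = None
    pass_flag: bool = True

    def __post_init__(self) -> None:
        if self.caller not in ("G", "S"):
            raise ValueError(f"caller must be 'G' or 'S', got {self.caller!r}")
        if self.dp < 0 or self.ad_ref < 0 or self.ad_alt < 0:
            raise ValueError("depths must be non-negative")
        if self.ad_ref + self.ad_alt > self.dp:
            raise ValueError(
                f"AD sum {self.ad_ref}+{self.ad_alt} exceeds DP {self.dp} at {self.key}"
            )
        if self.pl is not None:
            pl = tuple(int(x) for x in self.pl)
            if len(pl) != 3:
                raise ValueError(f"PL must have exactly 3 entries, got {self.pl}")
            self.pl = (
                pl
                if min(pl) == 0
                else tuple(x - min(pl) for x in pl)  # min-normalize on ingest
            )

    @property
    def vaf(self) -> float | None:
        """Variant allele fraction ad_alt/dp; undefined when dp == 0."""
        return self.ad_alt / self.dp if self.dp > 0 else None


@dataclass(frozen=True)
class SiteList:
    """A set of known sites used for removal or evaluation.

    ``editing`` lists are site-level (matched on chrom+pos); every other
    kind is allele-level (matched on the full key).
    """

    kind: str
    keys: frozenset = frozenset()  # of VariantKey (allele-level kinds)
    sites: frozenset = frozenset()  # of (chrom, pos) (site-level kinds)

    @property
    def site_level(self) -> bool:
        return self.kind == "editing"

    def __contains__(self, key: VariantKey) -> bool:
        if self.site_level:
            return (key.chrom, key.pos) in self.sites
        return key in self.keys

    def __len__(self) -> int:
        return len(self.sites) if self.site_level else len(self.keys)


class ExonIntervals:
    """Per-chromosome merged, sorted, half-open 0-based intervals.

    Queries take 1-based positions (the internal convention) and convert.
    """

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in intervals.items():
            merged = _merge_intervals(list(ivs))
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    @classmethod
    def from_bed(cls, path: str | Path) -> "ExonIntervals":
        intervals: dict[str, list[tuple[int, int]]] = {}
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise VcfFormatError(f"{path}: malformed BED row at line {lineno}")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise VcfFormatError(f"{path}: malformed BED row at line {lineno}") from exc
                intervals.setdefault(parts[0], []).append((start, end))
        return cls(intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff 1-based ``pos`` falls inside an interval on ``chrom``."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, pos - 1) - 1
        return i >= 0 and pos - 1 < self._ends[chrom][i]

    @property
    def n_intervals(self) -> int:
        return sum(len(s) for s in self._starts.values())

    @property
    def total_bases(self) -> int:
        return sum(
            e - s
            for chrom in self._starts
            for s, e in zip(self._starts[chrom], self._ends[chrom])
        )

    def items(self):
        for chrom in sorted(self._starts):
            yield chrom, list(zip(self._starts[chrom], self._ends[chrom]))


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _open_text(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# VCF parsing
# ---------------------------------------------------------------------------

def _pl_for_alt(pl: Sequence[int] | None, alt_index: int) -> tuple[int, int, int] | None:
    """Extract the (0/0, 0/a, a/a) PL triple for alt allele ``alt_index`` (1-based)
    from a VCF PL vector in standard genotype ordering, min-normalized."""
    if pl is None:
        return None
    a = alt_index
    i_het = a * (a + 1) // 2
    i_hom = i_het + a
    if i_hom >= len(pl) or any(pl[i] is None for i in (0, i_het, i_hom)):
        return None
    triple = (int(pl[0]), int(pl[i_het]), int(pl[i_hom]))
    m = min(triple)
    return tuple(x - m for x in triple)


def _get_field(mapping, key):
    """Fetch an INFO/FORMAT value, treating undeclared header IDs as absent."""
    try:
        return mapping.get(key)
    except (KeyError, ValueError):
        return None


def parse_cell_vcf(path: str | Path, caller: str, cell_id: str) -> list[CellCall]:
    """Parse one cell's VCF into normalized :class:`CellCall` records.

    Multi-allelic records are split into per-alt calls with alt-specific
    allele depth; non-SNV alleles are skipped with a logged count.  For
    ``caller="S"`` only records whose FILTER is PASS are ingested (the
    caller's own default filtering is trusted).

    Raises :class:`VcfFormatError` if a record lacks the required DP or AD
    fields, and propagates I/O errors for unreadable files.
    """
    if caller not in ("G", "S"):
        raise ValueError(f"caller must be 'G' or 'S', got {caller!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    calls: list[CellCall] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            filters = list(rec.filter.keys())
            pass_flag = (not filters) or ("PASS" in filters)
            if caller == "S" and not pass_flag:
                continue
            ref = rec.ref or ""
            alts = rec.alts or ()
            dp = _get_field(rec.info, "DP")
            sample = rec.samples[0] if rec.samples else None
            if dp is None and sample is not None:
                dp = _get_field(sample, "DP")
            if dp is None:
                raise VcfFormatError(f"{path}: record {rec.chrom}:{rec.pos} lacks required field DP")
            ad = _get_field(sample, "AD") if sample is not None else None
            pl = _get_field(sample, "PL") if sample is not None else None
            fs = _get_field(rec.info, "FS")
            qd = _get_field(rec.info, "QD")
            rpb = _get_field(rec.info, "ReadPosRankSum")
            for i, alt in enumerate(alts):
                if len(ref) != 1 or alt is None or len(alt) != 1 or ref not in BASES or alt not in BASES:
                    n_skipped += 1
                    continue
                if ad is None or len(ad) <= i + 1 or ad[0] is None:
                    raise VcfFormatError(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks required field AD"
                    )
                calls.append(
                    CellCall(
                        key=VariantKey(rec.chrom, rec.pos, ref, alt),
                        cell_id=cell_id,
                        caller=caller,
                        dp=int(dp),
                        ad_ref=int(ad[0]),
                        ad_alt=int(ad[i + 1]),
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        pl=_pl_for_alt(pl, i + 1),
                        fs=float(fs) if fs is not None else None,
                        qd=float(qd) if qd is not None else None,
                        read_pos_bias=float(rpb) if rpb is not None else None,
                        pass_flag=pass_flag,
                    )
                )
    if n_skipped:
        log.info("%s: skipped %d non-SNV allele(s)", path, n_skipped)
    return calls


def load_site_list(path: str | Path, kind: str) -> SiteList:
    """Load a site list from a VCF or a TSV with columns chrom,pos[,ref,alt].

    Duplicates collapse to one entry.  ``kind="editing"`` keeps site-level
    (chrom, pos) entries; every other kind requires ref/alt columns and
    keeps full keys.  An empty file yields a valid empty list with a
    warning; a malformed row is fatal with its line number.
    """
    if kind not in SITE_LIST_KINDS:
        raise ValueError(f"unknown site-list kind {kind!r}")
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".vcf", ".vcf.gz", ".bcf")):
        keys, sites = _site_list_from_vcf(path)
    else:
        keys, sites = _site_list_from_tsv(path, kind)
    if not keys and not sites:
        log.warning("%s: empty site list (kind=%s)", path, kind)
    if kind == "editing":
        return SiteList(kind=kind, sites=frozenset(sites))
    if sites and not keys:
        raise VcfFormatError(f"{path}: kind={kind} requires ref/alt columns")
    return SiteList(kind=kind, keys=frozenset(keys))


def _site_list_from_vcf(path: Path):
    keys: set[VariantKey] = set()
    sites: set[tuple[str, int]] = set()
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref = rec.ref or ""
            for alt in rec.alts or ():
                if len(ref) == 1 and alt and len(alt) == 1 and ref in BASES and alt in BASES:
                    keys.add(VariantKey(rec.chrom, rec.pos, ref, alt))
                    sites.add((rec.chrom, rec.pos))
                else:
                    n_skipped += 1
    if n_skipped:
        log.info("%s: skipped %d non-SNV allele(s)", path, n_skipped)
    return keys, sites


def _site_list_from_tsv(path: Path, kind: str):
    keys: set[VariantKey] = set()
    sites: set[tuple[str, int]] = set()
    first_data = True
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise VcfFormatError(f"{path}: malformed row at line {lineno}")
            try:
                pos = int(parts[1])
            except ValueError:
                if first_data:  # header row
                    first_data = False
                    continue
                raise VcfFormatError(f"{path}: malformed row at line {lineno}")
            first_data = False
            sites.add((parts[0], pos))
            if len(parts) >= 4 and parts[2] in BASES and parts[3] in BASES and parts[2] != parts[3]:
                keys.add(VariantKey(parts[0], pos, parts[2], parts[3]))
            elif kind != "editing":
                raise VcfFormatError(
                    f"{path}: line {lineno} lacks valid ref/alt columns required for kind={kind}"
                )
    return keys, sites


# ---------------------------------------------------------------------------
# Trinucleotide context / SBS96
# ---------------------------------------------------------------------------

def sbs96_class_from_context(ref: str, alt: str, trinucleotide: str) -> int | None:
    """Map a substitution plus its 3-mer context to the canonical SBS96 class.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand first.  Returns ``None`` if the context contains N.
    """
    if len(trinucleotide) != 3 or trinucleotide[1] != ref:
        raise ValueError(f"context {trinucleotide!r} does not center on ref {ref!r}")
    if "N" in trinucleotide or alt == "N":
        return None
    five, _, three = trinucleotide
    if ref in ("G", "A"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five, three = COMPLEMENT[three], COMPLEMENT[five]
    mt = MUTATION_TYPES.index(f"{ref}>{alt}")
    return mt * 16 + BASES.index(five) * 4 + BASES.index(three)


def trinucleotide_context(key: VariantKey, reference: Fasta) -> tuple[str, int | None]:
    """Resolve ``key``'s 3-mer reference context and SBS96 class.

    Returns ``(context, sbs96_class)`` where the class is ``None`` when the
    context contains N (such variants are excluded from sequence features).
    Raises :class:`ReferenceMismatchError` if the reference base at
    ``key.pos`` differs from ``key.ref``.
    """
    try:
        contig = reference[key.chrom]
    except KeyError:
        raise VcfFormatError(f"contig {key.chrom!r} absent from reference FASTA")
    if key.pos < 2 or key.pos + 1 > len(contig):
        raise ConsistencyError(
            f"{key}: flanking bases fall off contig {key.chrom} (length {len(contig)})"
        )
    tri = contig[key.pos - 2 : key.pos + 1].seq.upper()
    if tri[1] != key.ref:
        raise ReferenceMismatchError(
            f"{key}: reference has {tri[1]!r} at {key.chrom}:{key.pos}, call has {key.ref!r}"
        )
    return tri, sbs96_class_from_context(key.ref, key.alt, tri)


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------

_INFO_DEFS = (
    ("DP", "1", "Integer", "Total read depth"),
    ("FS", "1", "Float", "Phred-scaled Fisher strand bias"),
    ("QD", "1", "Float", "Quality by depth"),
    ("ReadPosRankSum", "1", "Float", "Read position rank-sum statistic"),
)


def _base_header(contigs: Mapping[str, int | None] | Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if isinstance(contigs, Mapping):
        items = contigs.items()
    else:
        items = ((c, None) for c in contigs)
    for name, length in items:
        if length:
            header.add_line(f"##contig=<ID={name},length={length}>")
        else:
            header.add_line(f"##contig=<ID={name}>")
    return header


def write_cell_vcf(calls: Sequence[CellCall], path: str | Path, contigs: Mapping[str, int]) -> None:
    """Write one cell's calls as a VCF 4.2 file (caller-G field layout).

    All calls must belong to the same cell.  Records are sorted by key so
    output is deterministic; quality-failing calls get FILTER ``q_fail``.
    """
    cells = {c.cell_id for c in calls}
    if len(cells) > 1:
        raise ValueError(f"calls span multiple cells: {sorted(cells)}")
    cell_id = calls[0].cell_id if calls else "sample"
    header = _base_header(contigs)
    for info in _INFO_DEFS:
        header.add_meta(
            "INFO",
            items=[("ID", info[0]), ("Number", info[1]), ("Type", info[2]), ("Description", info[3])],
        )
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"), ("Description", "Allele depths")])
    header.add_meta("FORMAT", items=[("ID", "PL"), ("Number", "G"), ("Type", "Integer"), ("Description", "Phred genotype likelihoods")])
    header.add_meta("FILTER", items=[("ID", "q_fail"), ("Description", "Failed caller quality filters")])
    header.add_sample(cell_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: c.key):
            rec = out.new_record(
                contig=call.key.chrom,
                start=call.key.pos - 1,
                alleles=(call.key.ref, call.key.alt),
                qual=call.qual,
                filter="PASS" if call.pass_flag else "q_fail",
            )
            rec.info["DP"] = call.dp
            if call.fs is not None:
                rec.info["FS"] = call.fs
            if call.qd is not None:
                rec.info["QD"] = call.qd
            if call.read_pos_bias is not None:
                rec.info["ReadPosRankSum"] = call.read_pos_bias
            smp = rec.samples[cell_id]
            smp["GT"] = (0, 1)
            smp["AD"] = (call.ad_ref, call.ad_alt)
            if call.pl is not None:
                smp["PL"] = call.pl
            out.write(rec)


def write_sites_vcf(
    path: str | Path,
    keys: Iterable[VariantKey],
    contigs: Mapping[str, int | None] | Iterable[str],
    annotations: Mapping[VariantKey, Mapping[str, object]] | None = None,
    info_defs: Sequence[tuple[str, str, str, str]] = (),
) -> None:
    """Write a site-level VCF (no samples) for a set of keys, sorted.

    ``annotations`` maps each key to INFO values declared in ``info_defs``
    (id, number, type, description)."""
    header = _base_header(contigs)
    for info in info_defs:
        header.add_meta(
            "INFO",
            items=[("ID", info[0]), ("Number", info[1]), ("Type", info[2]), ("Description", info[3])],
        )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(set(keys)):
            rec = out.new_record(
                contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt), filter="PASS"
            )
            if annotations and key in annotations:
                for k, v in annotations[key].items():
                    rec.info[k] = v
            out.write(rec)


def read_sites_vcf(path: str | Path) -> set[VariantKey]:
    """Read the SNV keys of a site-level VCF (used for truth/positive sets)."""
    keys, _ = _site_list_from_vcf(Path(path))
    return keys
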