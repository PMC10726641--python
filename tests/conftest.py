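from __future__ import annotations

import pytest
from pyfaidx import Fasta

from resa import pipeline, simulate

# Handcrafted contig: pos 3 is C with context ACA (class 0); pos 5 is G with
# context AGT (reverse-complements to A[C>A]T); pos 11 is N so pos 10/12
# contexts are undefined.
CONTEXT_SEQ = "AACAGTCTGANTACGT" + "ACGTTGCAACGGATCA" * 4

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=100000>\n"
    '##FILTER=<ID=q_fail,Description="failed quality filters">\n'
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
    '##INFO=<ID=FS,Number=1,Type=Float,Description="strand bias">\n'
    '##INFO=<ID=QD,Number=1,Type=Float,Description="qual by depth">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allele depths">\n'
    '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="phred GL">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tcell1\n"
)


def write_vcf_text(path, rows):
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in rows))
    return path


@pytest.fixture(scope="session")
def context_fasta(tmp_path_factory):
    d = tmp_path_factory.mktemp("ctxref")
    p = d / "ref.fa"
    p.write_text(f">chr1\n{CONTEXT_SEQ}\n")
    return Fasta(str(p))


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """On-disk tiny synthetic cohort shared across file-level tests."""
    d = tmp_path_factory.mktemp("tiny_cohort")
    paths, cohort = simulate.end_to_end_fixture("tiny", d, seed=11)
    return paths, cohort


@pytest.fixture(scope="session")
def tiny_run(tiny_cohort):
    """The tiny cohort plus its completed filtering/labeling run."""
    paths, cohort = tiny_cohort
    result = pipeline.run_cohort_files(
        paths["manifest"],
        paths["exons_bed"],
        editing=paths["editing_tsv"],
        germline=[paths["germline_tsv"]],
    )
    return paths, cohort, result
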