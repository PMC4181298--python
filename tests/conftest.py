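"""Shared fixtures: a tiny genome, hand-written VCF text and a small
simulated panel reused across modules."""

import numpy as np
import pytest

from sojasweep import GenomeIndex, SimulationConfig, simulate_panel

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##contig=<ID=chr1,length=10000>
##contig=<ID=chr2,length=8000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def make_vcf(tmp_path, name, samples, rows):
    """Write a small VCF; rows are (chrom, pos, ref, alt, [sample fields])."""
    path = tmp_path / name
    lines = [VCF_HEADER.format(samples="\t".join(samples)).rstrip("\n")]
    for chrom, pos, ref, alt, fields in rows:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT:DP:AD\t"
                     + "\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def genome():
    return GenomeIndex(("chr1", "chr2"), {"chr1": 10_000, "chr2": 8_000})


@pytest.fixture(scope="session")
def small_panel():
    """A compact panel exercising all three populations and one sweep."""
    cfg = SimulationConfig(
        n_chromosomes=3, chromosome_length=300_000,
        n_wild=5, n_semiwild=3, n_cultivated=5,
        n_sweeps=1, sweep_length=150_000,
        n_specific_segments=1, specific_segment_length=20_000,
        seed=42)
    return simulate_panel(cfg)
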