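from dataclasses import replace

import numpy as np
import pytest

from repeatenrich import GeneRecord, RepeatInstance
from repeatenrich.neighborhoods import KINDS, NeighborhoodSpec
from repeatenrich.simulate import DEFAULT_CONFIG


def make_gene(gene_id="G1", chrom="chr1", strand="+", start=10_000, end=20_000, symbol=None):
    return GeneRecord(
        gene_id=gene_id,
        symbol=symbol or gene_id.lower(),
        chrom=chrom,
        strand=strand,
        gene_start=start,
        gene_end=end,
        tss=start if strand == "+" else end,
    )


def make_repeat(chrom="chr1", start=0, end=100, name="MER20", cls="DNA", family="", strand="+"):
    return RepeatInstance(
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        repeat_name=name,
        repeat_class=cls,
        repeat_family=family,
        score=500,
        divergence_pct=12.5,
    )


def random_genes(rng, n, chrom="chr1", chrom_len=2_000_000, min_len=500, max_len=5000):
    genes = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len))
        start = int(rng.integers(0, chrom_len - length))
        strand = str(rng.choice(["+", "-"]))
        genes.append(
            make_gene(f"G{i:04d}", chrom, strand, start, start + length)
        )
    return genes


def random_repeats(rng, n, chrom="chr1", chrom_len=2_000_000, n_names=8):
    names = [f"REP{j}" for j in range(n_names)]
    classes = ["LINE", "SINE", "LTR", "DNA"]
    reps = []
    for _ in range(n):
        length = int(rng.integers(50, 1500))
        start = int(rng.integers(0, chrom_len - length))
        j = int(rng.integers(0, n_names))
        reps.append(
            make_repeat(chrom, start, start + length, names[j], classes[j % 4])
        )
    return reps


def random_spec(rng):
    kind = str(rng.choice(KINDS))
    size = int(rng.choice([2_000, 5_000, 10_000, 20_000]))
    return NeighborhoodSpec(kind, size)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down synthetic genome for quick end-to-end tests."""
    return replace(
        DEFAULT_CONFIG,
        chrom_lengths={"chr1": 10_000_000, "chr2": 10_000_000},
        n_genes_per_chrom=100,
        n_query_genes=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    from repeatenrich.simulate import generate_tables

    return generate_tables(small_config)
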