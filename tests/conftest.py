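import numpy as np
import pandas as pd
import pytest

from h3turnover import (
    Gene, Interval, GenomeSpec, TurnoverModel, generate_annotation, track_from_arrays,
)


@pytest.fixture(scope="session")
def small_spec():
    return GenomeSpec(
        n_chromosomes=2,
        chrom_length=60_000,
        n_genes=40,
        gene_length_range=(300, 3000),
        min_intergenic=700,
        n_ars=4,
        probe_spacing=250,
        probe_length=51,
    )


@pytest.fixture(scope="session")
def small_annotation(small_spec):
    return generate_annotation(small_spec, seed=7)


@pytest.fixture(scope="session")
def toy_genes():
    """Three hand-placed genes: +, -, + on two chromosomes."""
    return [
        Gene(id="gA", chrom="chr1", start=2000, end=4000, strand="+"),
        Gene(id="gB", chrom="chr1", start=6000, end=6800, strand="-"),
        Gene(id="gC", chrom="chr2", start=1000, end=2500, strand="+"),
    ]


@pytest.fixture(scope="session")
def toy_probes():
    """51 bp probes every 250 bp over both toy chromosomes."""
    probes = []
    for chrom, length in (("chr1", 10_000), ("chr2", 5_000)):
        for k, s in enumerate(range(0, length, 250)):
            probes.append(Interval(chrom=chrom, start=s, end=min(s + 51, length), id=f"{chrom}_p{k}"))
    return probes
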