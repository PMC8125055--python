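"""Shared synthetic fixtures (generated programmatically, session-scoped)."""

from __future__ import annotations

import pytest

from napregulon import simulate
from napregulon.io import Gene, Genome


@pytest.fixture(scope="session")
def genome_and_islands():
    return simulate.generate_genome(seed=11)


@pytest.fixture(scope="session")
def genome(genome_and_islands):
    return genome_and_islands[0]


@pytest.fixture(scope="session")
def islands(genome_and_islands):
    return genome_and_islands[1].islands


@pytest.fixture(scope="session")
def annotation(genome):
    return simulate.generate_annotation(genome, seed=12)


@pytest.fixture(scope="session")
def peaks_de_truth(genome, annotation, islands):
    return simulate.generate_peaks_and_de(
        genome, annotation, islands=islands, seed=13
    )


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """A full synthetic dataset written to disk once per session."""
    outdir = tmp_path_factory.mktemp("dataset") / "sim"
    simulate.generate_dataset(outdir, master_seed=5)
    return outdir


@pytest.fixture
def toy_genome():
    return Genome({"c1": "ACGT" * 250})  # 1 kb


@pytest.fixture
def toy_genes():
    # two-gene toy annotation with an intergenic gap at [300, 600)
    return [
        Gene(contig="c1", start=100, end=300, gene_id="gA", strand="+"),
        Gene(contig="c1", start=600, end=900, gene_id="gB", strand="-"),
    ]
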