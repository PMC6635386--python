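import warnings

import numpy as np
import pytest

from meiohic.layout import GenomeLayout
from meiohic.sim import (
    ArchitectureSpec,
    GenomeSpec,
    build_genome_layout,
    planted_compartment_labels,
    sample_contact_reads,
    simulate_expected_matrix,
)


@pytest.fixture(autouse=True)
def _no_warning_noise():
    """Keep intentional library warnings out of the test output."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def toy_layout() -> GenomeLayout:
    """3 chromosomes x 10 Mbp at 50-kbp bins (600 bins)."""
    return GenomeLayout(("chr1", "chr2", "chr3"), (10_000_000,) * 3, 50_000)


@pytest.fixture(scope="session")
def default_genome():
    """Default synthetic genome: layout, gene table and planted labels."""
    spec = GenomeSpec()
    layout, genes = build_genome_layout(spec, seed=1)
    labels = planted_compartment_labels(layout)
    return layout, genes, labels


@pytest.fixture(scope="session")
def default_sampled(default_genome):
    """Default architecture sampled at 1e6 reads, seed 1."""
    layout, genes, labels = default_genome
    arch = ArchitectureSpec(seed=1)
    expected = simulate_expected_matrix(layout, arch, labels)
    reads, raw = sample_contact_reads(expected, 1_000_000, seed=1)
    return layout, genes, labels, arch, expected, reads, raw


def gene_density_track(layout, genes) -> np.ndarray:
    dens = np.zeros(layout.n_bins)
    for chrom, tss in zip(genes["chrom"], genes["tss"]):
        dens[layout.bin_index(chrom, int(tss))] += 1
    return dens
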