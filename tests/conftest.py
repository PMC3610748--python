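"""Shared fixtures: small hand-built datasets and simulated cohorts."""

import numpy as np
import pytest

from genemdr.datamodel import Dataset, SampleRecord, SnpAnnotation


def make_dataset(genotypes, statuses, genes=None, zd=None, zmd=None):
    """Convenience constructor for small in-memory datasets.

    ``genotypes``: (n_samples, n_snps) codes; ``statuses``: iterable of
    'case'/'control'; ``genes``: per-SNP gene symbols (default one gene).
    """
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    genes = list(genes) if genes is not None else ["GENE1"] * m
    zd = zd if zd is not None else [None] * n
    zmd = zmd if zmd is not None else [None] * n
    samples = [
        SampleRecord(f"s{i:03d}", status, zd=zd[i], zmd=zmd[i])
        for i, status in enumerate(statuses)
    ]
    positions = {}
    snps = []
    for j in range(m):
        positions[genes[j]] = positions.get(genes[j], 0) + 1
        snps.append(
            SnpAnnotation(
                snp_id=f"snp{j:03d}",
                gene=genes[j],
                chromosome="chr1",
                position=1000 * (j + 1),
                alleles=("A", "G"),
            )
        )
    gene_map = {}
    for j, g in enumerate(genes):
        gene_map.setdefault(g, []).append(j)
    return Dataset(genotypes=genotypes, samples=samples, snps=snps, gene_map=gene_map)


@pytest.fixture
def tiny_dataset():
    """4 samples x 3 SNPs, 2 cases / 2 controls, no missing."""
    return make_dataset(
        [[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 0, 0]],
        ["case", "case", "control", "control"],
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Medium null cohort shared by read-only tests (no planted effects)."""
    from genemdr import simulate as sim

    cfg = sim.SimulationConfig(
        gene_sizes=(3, 3), n_case=200, n_control=200, missing_rate=0.0, seed=424242
    )
    return sim.simulate_dataset(cfg)
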