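"""Shared fixtures: tiny handcrafted cohorts and seeded scenarios."""

import numpy as np
import pytest

from genoconcord import (
    Allele,
    GenotypeDataset,
    SampleRecord,
    SimulationConfig,
    VariantRecord,
    simulate_scenario,
)
from genoconcord.model import MISSING_CODE, encode_pair


def make_dataset(variants, samples, cells):
    """Build a dataset from 'AC'/'NA' string cells (variants x samples)."""
    calls = np.full((len(variants), len(samples)), MISSING_CODE, dtype=np.int8)
    for i, row in enumerate(cells):
        for j, cell in enumerate(row):
            if cell != "NA":
                calls[i, j] = encode_pair(Allele(cell[0]), Allele(cell[1]))
    return GenotypeDataset(variants=list(variants), samples=list(samples),
                           calls=calls)


def var(chrom, pos, rsid, a, b):
    return VariantRecord(chromosome=chrom, position=pos, rsid=rsid,
                         allele_a=Allele(a), allele_b=Allele(b))


@pytest.fixture(scope="session")
def small_scenario():
    """A 5-family, 120-variant scenario exercising every error channel."""
    config = SimulationConfig(
        n_families=5, family_size_range=(6, 12), n_generations=3,
        n_variants=120, n_noseq_families=2, seed=11,
    )
    return simulate_scenario(config)


@pytest.fixture(scope="session")
def two_family_pedigree():
    return [
        SampleRecord("A1", "FA", None, None, sequenced=True),
        SampleRecord("A2", "FA", None, None, sequenced=False),
        SampleRecord("A3", "FA", "A1", "A2", sequenced=True),
        SampleRecord("B1", "FB", None, None, sequenced=False),
        SampleRecord("B2", "FB", None, None, sequenced=False),
    ]
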