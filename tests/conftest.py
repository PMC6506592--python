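"""Shared fixtures: small synthetic systems reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from larvorigin.genio import GenotypeTable
from larvorigin.synthgen import (
    CohortSpec,
    PopulationModel,
    make_allele_freqs,
    simulate_adults,
    simulate_cohorts,
)


def make_table(loci, genotypes_by_pop):
    """Tiny GenotypeTable from {pop: [((a, b), ...), ...]} literals."""
    ids, pops, rows = [], [], []
    for pop, genos in genotypes_by_pop.items():
        for k, geno in enumerate(genos):
            ids.append(f"{pop}-{k + 1:03d}")
            pops.append(pop)
            rows.append(np.array(geno, dtype=np.int32))
    metadata = pd.DataFrame({"pop": pops}, index=pd.Index(ids, name="id"))
    return GenotypeTable(loci=list(loci), ids=ids, calls=np.stack(rows), metadata=metadata)


@pytest.fixture(scope="session")
def small_model():
    return PopulationModel(n_pops=4, n_loci=14, fst_target=0.05, seed=11)


@pytest.fixture(scope="session")
def small_freqs(small_model):
    return make_allele_freqs(small_model)


@pytest.fixture(scope="session")
def small_adults(small_model, small_freqs):
    return simulate_adults(small_freqs, {p: 30 for p in small_model.pop_names}, seed=12)


@pytest.fixture(scope="session")
def small_cohorts(small_model, small_freqs, small_adults):
    spec = CohortSpec(
        sites=("LongKey", "BigMunson"),
        months=("m01", "m02", "m03"),
        n_per_month=20,
        source_mixture={p: 0.25 for p in small_model.pop_names},
        prop_parent_sampled=0.5,
        error_rate=0.01,
        missing_rate=0.02,
    )
    return simulate_cohorts(small_freqs, small_adults, spec, seed=13)
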