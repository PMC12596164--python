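import dataclasses
import logging

import numpy as np
import pandas as pd
import pytest

from clonalpop.conservation import ProteinAlignment, gene_entropy_score, translate_cds
from clonalpop.synthetic_data import (
    GeneModel,
    SimulationConfig,
    clade_recovery_config,
    simulate_population,
)

# internal-stop warnings from highly mutated synthetic genes are expected noise
logging.getLogger("clonalpop.conservation").setLevel(logging.ERROR)


def small_config(seed=1, mu=1e-4, genes=None, n_years=2, **overrides):
    """A fast, small simulation config for unit tests."""
    genes = genes or (
        GeneModel("hi", 300, 0.95),
        GeneModel("mid", 300, 0.5),
        GeneModel("free", 300, 0.0),
    )
    schedule = []
    sample_sizes = {}
    for year in range(n_years):
        summer, winter = f"Y{year + 1}-summer", f"Y{year + 1}-winter"
        schedule.append((summer, 4.0))
        schedule.append((winter, 1.5))
        sample_sizes[summer] = 10
    base = SimulationConfig(
        genes=genes,
        n_clades=4,
        founder_divergence_nt=30,
        mu=mu,
        generations_per_interval=5,
        seasonal_log10_peaks=tuple(schedule),
        trough_log10=1.5,
        sample_sizes=sample_sizes,
        effective_size_cap=500,
        lod=1.0,
        seed=seed,
    )
    return dataclasses.replace(base, **overrides) if overrides else base


def score_genes(config, isolates):
    """Per-gene entropy score of translated isolate sequences."""
    scores = {}
    for g in config.genes:
        aln = ProteinAlignment(
            gene=g.name,
            ids=tuple(i.isolate_id for i in isolates),
            rows=tuple(translate_cds(i.sequences[g.name], record_id=g.name) for i in isolates),
        )
        scores[g.name] = gene_entropy_score(aln).score
    return scores


@pytest.fixture(scope="session")
def clade_run():
    """One seeded clade-recovery simulation shared across tests."""
    config = clade_recovery_config(seed=1)
    isolates, truth = simulate_population(config)
    return config, isolates, truth


@pytest.fixture()
def metadata_frame():
    def build(isolates):
        return pd.DataFrame(
            {
                "isolate_id": [i.isolate_id for i in isolates],
                "time_point": [i.time_point for i in isolates],
                "source": [i.source for i in isolates],
                "clade": [i.clade for i in isolates],
            }
        )

    return build


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
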