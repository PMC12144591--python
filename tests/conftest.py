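"""Shared fixtures: small synthetic datasets reused across the suite.

Heavy objects (parental pools, a fitted generation-bin set) are session
scoped so the admixture fits behind them run once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from duckmix import genofilter, hybridclass, synthio
from duckmix.synthio import AlleleFrequencyPool, PoolSpec, simulate_parental_pools


def hudson_fst(p1: np.ndarray, p2: np.ndarray) -> float:
    """Independent Hudson-style FST oracle from two frequency vectors."""
    num = ((p1 - p2) ** 2).sum()
    den = (p1 * (1 - p2) + p2 * (1 - p1)).sum()
    return float(num / den)


@pytest.fixture(scope="session")
def pools_011():
    """Two parental pools at differentiation 0.11 over 1000 loci."""
    return simulate_parental_pools(PoolSpec(n_loci=1000, fst_target=0.11,
                                            seed=11))


@pytest.fixture(scope="session")
def fixed_difference_pools():
    """Pools fixed for opposite alleles at every one of 200 loci."""
    return (AlleleFrequencyPool("A", np.zeros(200)),
            AlleleFrequencyPool("B", np.ones(200)))


@pytest.fixture(scope="session")
def two_pool_matrix(pools_011):
    """30 + 30 diploids sampled from the two pools, with truth labels."""
    pa, pb = pools_011
    ga = synthio.sample_genotypes(pa, 30, seed=21, id_prefix="A")
    gb = synthio.sample_genotypes(pb, 30, seed=22, id_prefix="B")
    geno = np.vstack([ga.genotypes, gb.genotypes])
    ids = ga.individual_ids + gb.individual_ids
    meta = pd.DataFrame({"taxon": ["A"] * 30 + ["B"] * 30}, index=ids)
    return genofilter.GenotypeMatrix(geno, ids, ga.locus_ids, metadata=meta)


@pytest.fixture(scope="session")
def generation_bins(pools_011):
    """Generation bins from a reduced replicate design (2 sims x 2 runs).

    Uses the full nine-generation pedigree over the session pools; the
    admixture fits behind it dominate the fixture's cost, so it is built
    once per session.
    """
    spec = hybridclass.PedigreeSpec(n_f1=10, n_backcross_lineages_per_side=5,
                                    max_backcross_generations=9,
                                    n_replicate_simulations=2)
    bins, fits = hybridclass.build_generation_bins(
        pools_011[0], pools_011[1], spec, K=2, runs_per_sim=2, n_ref=40,
        seed=51)
    return bins, fits


@pytest.fixture(scope="session")
def env_dataset():
    """Planted-signal genotype-environment dataset (env1 causal)."""
    scenario = synthio.EnvScenario(n_sites=25, n_variables=5, n_loci=60,
                                   n_adaptive_loci=15,
                                   n_individuals_per_site=12,
                                   effect_slope=2.5, noise_sd=0.2,
                                   grid_dims=(6, 6))
    return synthio.simulate_env_dataset(scenario, seed=77)
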