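import numpy as np
import pandas as pd
import pytest

from ctenopop.core import GenotypeMatrix, PopulationMap, make_locus_table
from ctenopop import synthetic as syn


def small_matrix(dosage, pops=None, tag_ids=None, positions=None, scaffolds=None):
    """Build a GenotypeMatrix (+ optional PopulationMap) from a plain array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    inds = [f"i{k:03d}" for k in range(n)]
    loci = make_locus_table(
        [f"L{j:03d}" for j in range(L)],
        tag_ids=tag_ids,
        positions=positions or list(range(1, L + 1)),
        scaffolds=scaffolds,
    )
    g = GenotypeMatrix(inds, loci, dosage)
    if pops is None:
        return g
    pm = PopulationMap(
        population_of=pd.Series(dict(zip(inds, pops))),
        group_of=pd.Series({p: p for p in dict.fromkeys(pops)}),
        native=pd.Series({p: True for p in dict.fromkeys(pops)}),
    )
    return g, pm


@pytest.fixture(scope="session")
def study_design():
    return syn.default_design(seed=0)


@pytest.fixture(scope="session")
def study_cohort(study_design):
    """One simulated 9-population cohort with planted selected loci,
    shared across tests that only read it."""
    g, truth = syn.simulate_metapopulation(study_design, 1500, seed=11)
    plan = syn.SelectionPlan(n_clinal=40, n_divergent=40, n_balanced=40)
    g, truth = syn.plant_selected_loci(g, plan, study_design, seed=12, truth=truth)
    return g, truth


@pytest.fixture(scope="session")
def study_popmap(study_design):
    return study_design.population_map()
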