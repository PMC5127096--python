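import numpy as np
import pandas as pd
import pytest

from guttype.abundance import AbundanceTable, to_relative
from guttype.clustering import jsd_distance
from guttype.simulate import (
    EnterotypeArchetype,
    SyntheticCohortConfig,
    archetype_composition,
    generate_cohort,
    study_families,
)


def two_archetype_config(
    n_samples=200,
    concentration=200.0,
    dominant_a=("Prevotellaceae", 0.60),
    dominant_b=("Bacteroidaceae", 0.60),
    depth=10000.0,
    depth_sd=0.0,
    seed=7,
    n_taxa=66,
):
    taxa = study_families(n_taxa)
    comp_a = archetype_composition({dominant_a[0]: dominant_a[1]}, taxa)
    comp_b = archetype_composition({dominant_b[0]: dominant_b[1]}, taxa)
    return SyntheticCohortConfig(
        n_samples=n_samples,
        archetypes=[
            EnterotypeArchetype("A", comp_a, concentration),
            EnterotypeArchetype("B", comp_b, concentration),
        ],
        depth_mean=depth,
        depth_sd=depth_sd,
        n_taxa=n_taxa,
        seed=seed,
        questionnaire_couplings=[],
    )


def single_archetype_config(n_samples=200, concentration=200.0, seed=3, n_taxa=66):
    taxa = study_families(n_taxa)
    comp = archetype_composition({"Bacteroidaceae": 0.35, "Lachnospiraceae": 0.18}, taxa)
    return SyntheticCohortConfig(
        n_samples=n_samples,
        archetypes=[EnterotypeArchetype("only", comp, concentration)],
        depth_mean=10000.0,
        depth_sd=0.0,
        n_taxa=n_taxa,
        seed=seed,
        questionnaire_couplings=[],
    )


@pytest.fixture(scope="session")
def two_archetype_cohort():
    return generate_cohort(two_archetype_config())


@pytest.fixture(scope="session")
def two_archetype_distance(two_archetype_cohort):
    return jsd_distance(to_relative(two_archetype_cohort.counts))


def relative_table(rows, sample_ids=None, taxon_ids=None):
    arr = np.asarray(rows, dtype=float)
    arr = arr / arr.sum(axis=1, keepdims=True)
    sample_ids = sample_ids or [f"s{i}" for i in range(arr.shape[0])]
    taxon_ids = taxon_ids or [f"t{j}" for j in range(arr.shape[1])]
    return AbundanceTable(
        pd.DataFrame(arr, index=sample_ids, columns=taxon_ids), kind="relative"
    )


def counts_table(rows, sample_ids=None, taxon_ids=None, level="otu"):
    arr = np.asarray(rows, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(arr.shape[0])]
    taxon_ids = taxon_ids or [f"t{j}" for j in range(arr.shape[1])]
    return AbundanceTable(
        pd.DataFrame(arr, index=sample_ids, columns=taxon_ids), kind="counts", level=level
    )
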