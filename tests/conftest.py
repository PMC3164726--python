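import numpy as np
import pandas as pd
import pytest

from docktriage import (KnownInteractions, SimulationConfig, aggregate_best,
                        compute_ranks, generate_cross_docking)


@pytest.fixture(scope="session")
def small_dataset():
    """A 10-protein x 40-drug synthetic landscape with planted binders."""
    cfg = SimulationConfig(n_proteins=10, n_drugs=40,
                           known_per_protein_mean=3.0,
                           dockable_fraction=1.0, binder_shift_icm=-25.0,
                           binder_shift_pmf=-120.0, seed=11)
    return generate_cross_docking(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return aggregate_best(small_dataset.records)


@pytest.fixture(scope="session")
def small_ranks(small_matrix):
    return compute_ranks(small_matrix)


@pytest.fixture(scope="session")
def small_known(small_dataset):
    status = dict(zip(small_dataset.drug_properties["drug_id"],
                      small_dataset.drug_properties["status"]))
    return KnownInteractions(pairs=small_dataset.known_interactions,
                             drug_status=status)


def random_matrix(rng, n_proteins, n_drugs):
    """Dense random score matrix for rank/threshold property tests."""
    from docktriage import ScoreMatrix
    proteins = [f"P{i:03d}" for i in range(n_proteins)]
    drugs = [f"D{j:03d}" for j in range(n_drugs)]
    icm = pd.DataFrame(-rng.uniform(0, 60, (n_proteins, n_drugs)),
                       index=proteins, columns=drugs)
    pmf = pd.DataFrame(-rng.uniform(0, 300, (n_proteins, n_drugs)),
                       index=proteins, columns=drugs)
    prov = pd.DataFrame({"protein_id": np.repeat(proteins, n_drugs),
                         "drug_id": drugs * n_proteins,
                         "structure_id": "s1", "pocket_id": "pk1",
                         "replicate": 1})
    return ScoreMatrix(icm=icm, pmf=pmf, provenance=prov)
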