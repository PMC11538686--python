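import numpy as np
import pandas as pd
import pytest

import modulon as md
from modulon.preprocess import preprocess_counts

#: study conditions for the end-to-end recovery experiment
RECOVERY = dict(n_genes=2000, k_true=12, n_conditions=20, replicates_per_condition=3,
                noise_sd=0.25, seed=1)


def membership_f1(truth_set, called_set) -> float:
    a, b = set(truth_set), set(called_set)
    if not a or not b:
        return 0.0
    p = len(a & b) / len(b)
    r = len(a & b) / len(a)
    return 2 * p * r / (p + r) if p + r else 0.0


@pytest.fixture(scope="session")
def recovery_pipeline():
    """Full pipeline on the default synthetic compendium: 2000 genes, 12
    planted modules, 20 conditions x 3 replicates, noise sd 0.25."""
    sim = md.simulate_compendium(**RECOVERY)
    X, report = preprocess_counts(sim.counts, sim.genes, sim.design)
    est = md.RobustICA(n_components=12, n_runs=20, random_state=1).fit(X)
    imodulons = md.build_imodulons(est.to_component_set(), X, seed=0)
    return {"sim": sim, "X": X, "qc": report, "est": est, "imodulons": imodulons}


@pytest.fixture(scope="session")
def small_sim():
    """Small compendium for cheap structural tests."""
    return md.simulate_compendium(
        n_genes=400, k_true=4, n_conditions=8, module_size_range=(6, 15), seed=3
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_gene_table():
    return pd.DataFrame(
        {"length_nt": [200, 300], "start": [1, 1001], "end": [200, 1300],
         "strand": ["+", "-"]},
        index=pd.Index(["g1", "g2"], name="gene_id"),
    )
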