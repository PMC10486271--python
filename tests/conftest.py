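import numpy as np
import pandas as pd
import pytest

from mdgpipe.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def two_group_cohort():
    """Default-condition cohort restricted to NT vs stage I, 24 vs 24."""
    cfg = SimulationConfig(group_sizes={"NT": 24, "I": 24}, seed=42)
    beta, counts, cpg_map, samples, truth = simulate_cohort(cfg)
    return {"config": cfg, "beta": beta, "counts": counts, "cpg_map": cpg_map,
            "samples": samples, "truth": truth}


@pytest.fixture(scope="session")
def null_cohort():
    """No planted signal: every gene identically distributed across groups."""
    cfg = SimulationConfig(group_sizes={"NT": 24, "I": 24}, n_genes=300,
                           n_hypo_planted=0, n_hyper_planted=0, seed=7)
    beta, counts, cpg_map, samples, truth = simulate_cohort(cfg)
    return {"config": cfg, "beta": beta, "counts": counts, "cpg_map": cpg_map,
            "samples": samples, "truth": truth}


@pytest.fixture()
def toy_samples():
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(8)],
        "phenotype": ["NT"] * 4 + ["I"] * 4,
    })


def make_beta(values, samples=None, prefix="cg"):
    values = np.asarray(values, dtype=float)
    cols = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, columns=cols,
                        index=pd.Index([f"{prefix}{i}" for i in range(values.shape[0])],
                                       name="cpg_id"))
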