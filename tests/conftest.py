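import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from angiocompendium.knowledge import REQUIRED_PATHWAYS, PathwayCompendium
from angiocompendium.synthetic import SimulationConfig

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_de(up=(), down=(), other=(), p_sig=1e-4, p_ns=0.5, treatment="T"):
    """Build a DE table directly: `up`/`down` significant, `other` not."""
    genes, rows = [], []
    for g in up:
        genes.append(g)
        rows.append((p_sig, 1.0, "up", True))
    for g in down:
        genes.append(g)
        rows.append((p_sig, -1.0, "down", True))
    for g in other:
        genes.append(g)
        rows.append((p_ns, 0.1, "up", False))
    table = pd.DataFrame(
        rows,
        columns=["p_value", "log2_fold_change", "direction", "significant"],
        index=pd.Index([str(g).upper() for g in genes], name="gene"),
    )
    table.attrs["treatment"] = treatment
    table.attrs["threshold"] = 0.003
    return table


@pytest.fixture
def small_kb():
    """Nine required pathways with 3 upstream / 4 downstream genes each."""
    pathways = {}
    for i, name in enumerate(REQUIRED_PATHWAYS):
        pathways[name] = {
            "upstream": {f"{name.upper()}U{j}" for j in range(3)},
            "downstream": {f"{name.upper()}D{j}" for j in range(4)},
        }
    return PathwayCompendium.from_dict(pathways)


@pytest.fixture
def tiny_sim_config():
    """A reduced but structurally faithful simulation for fast tests."""
    return SimulationConfig(
        n_genes=1500,
        n_replicates=12,
        pathway_sizes={p: (5, 10) for p in REQUIRED_PATHWAYS},
        de_background_rate=0.05,
        noise_sd=0.25,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
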