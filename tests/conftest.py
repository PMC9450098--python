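import itertools

import numpy as np
import pytest

from peakconcord import SampleInfo, SimulationConfig, generate_dataset
from peakconcord.types import CountMatrix


CONTROL_PAIRS = list(itertools.combinations(["EtOH-1", "EtOH-2", "EtOH-3"], 2))


@pytest.fixture(scope="session")
def small_dataset():
    """One mid-size synthetic dataset shared across read-only tests."""
    config = SimulationConfig(
        seed=42, n_genes=300, frac_de_genes=0.2, frac_concordant=0.5,
        accessibility_effect=4.0,
    )
    return generate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_matrix(values, conditions, units="fragments"):
    """CountMatrix from a dense array and per-column condition labels."""
    values = np.asarray(values, dtype=float)
    reps: dict[str, int] = {}
    samples = []
    for cond in conditions:
        reps[cond] = reps.get(cond, 0) + 1
        role = "control" if cond.startswith(("EtOH", "ctrl")) else "experimental"
        samples.append(SampleInfo(f"{cond}_r{reps[cond]}", cond, reps[cond], role))
    rows = [f"peak_{i + 1:06d}" for i in range(values.shape[0])]
    return CountMatrix(rows, samples, values, units)
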