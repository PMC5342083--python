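import numpy as np
import pandas as pd
import pytest

from agecurve import CohortSpec, ExpressionDataset, simulate_dataset


def write_tsv_fixture(tmp_path, name, frame, index=True):
    path = tmp_path / name
    frame.to_csv(path, sep="\t", index=index)
    return path


@pytest.fixture
def small_dataset():
    """3 probes x 6 samples, deterministic values, ages spanning 46-89."""
    rng = np.random.default_rng(7)
    ages = np.array([46.0, 52.0, 60.0, 68.0, 75.0, 89.0])
    values = rng.normal(7.0, 1.0, (3, 6))
    return ExpressionDataset(
        probe_ids=np.array([f"P{i}" for i in range(3)], dtype=object),
        sample_ids=np.array([f"S{j}" for j in range(6)], dtype=object),
        ages=ages,
        values=values,
    )


@pytest.fixture
def hinge_cohort():
    """Noisy cohort of opposite hinge trends at 65 plus null probes."""
    spec = CohortSpec(
        n_samples=300,
        age_range=(46.0, 89.0),
        n_probes=200,
        frac_signal=0.4,
        archetype_mix={"hinge-up": 0.5, "hinge-down": 0.5},
        seed=11,
    )
    dataset, truth = simulate_dataset(spec, change_point=65.0, delta=1.0, noise_sd=0.3)
    return dataset, truth
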