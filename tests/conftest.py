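import numpy as np
import pandas as pd
import pytest

from mtxdiff import GeneratorConfig, generate_paired_dataset, make_null_assignment
from mtxdiff.transforms import FeatureView


@pytest.fixture(scope="session")
def small_dataset():
    """A small paired dataset with group labels (30 samples, 40 features)."""
    cfg = GeneratorConfig(
        n_subjects=15,
        timepoints_per_subject=2,
        n_taxa=8,
        n_features=40,
        dropout_rate=0.05,
        seed=123,
    )
    data, truth = generate_paired_dataset(cfg)
    groups = make_null_assignment(data.meta, seed=7)
    return data.with_groups(groups), truth


@pytest.fixture(scope="session")
def medium_dataset():
    """Default-sized dataset (100 samples, 200 features) with group labels."""
    cfg = GeneratorConfig(seed=42)
    data, truth = generate_paired_dataset(cfg)
    groups = make_null_assignment(data.meta, seed=9)
    return data.with_groups(groups), truth


def make_view(y, dna, taxa, subjects, groups, **extra):
    """Assemble a FeatureView from raw vectors (test helper)."""
    n = len(y)
    meta = pd.DataFrame(
        {"subject_id": list(subjects), "group": list(groups), **extra},
        index=[f"s{i}" for i in range(n)],
    )
    return FeatureView(
        "feat", np.asarray(y, float), np.asarray(dna, float), np.asarray(taxa, float), meta
    )
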