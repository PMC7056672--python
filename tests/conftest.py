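import numpy as np
import pandas as pd
import pytest

from microgdm.io_formats import OtuTable, SampleMetadata, TaxonomyMap
from microgdm.synthetic_cohort import CohortSimConfig, null_config


@pytest.fixture
def tiny_table():
    return OtuTable(
        ["s1", "s2", "s3"],
        ["otuA", "otuB"],
        np.array([[3, 1], [0, 5], [2, 2]]),
    )


@pytest.fixture
def tiny_metadata():
    frame = pd.DataFrame(
        {
            "group": ["case", "control", "case", "control"],
            "pair_id": ["p1", "p1", "p2", "p2"],
            "set": ["discovery"] * 4,
            "FGB": [5.1, 4.6, 4.9, 4.4],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="#SampleID"),
    )
    return SampleMetadata(frame, ("FGB",))


@pytest.fixture
def tiny_taxonomy():
    return TaxonomyMap({
        "otuA": ("Bacteria", "Firmicutes", "c", "o", "f", "GenusX", ""),
        "otuB": ("Bacteria", "Firmicutes", "c", "o", "f", "GenusX", ""),
    })


def small_config(seed=0, **overrides):
    """A fast cohort for tests: 12 pairs discovery + 5 validation, 40 genera,
    shallow depth."""
    base = dict(
        n_pairs_discovery=12,
        n_pairs_validation=5,
        n_genera=40,
        depth_mean=5000.0,
        seed=seed,
    )
    base.update(overrides)
    return CohortSimConfig(**base)


def small_null_config(seed=0, **overrides):
    base = dict(
        n_pairs_discovery=12,
        n_pairs_validation=5,
        n_genera=40,
        depth_mean=5000.0,
    )
    base.update(overrides)
    return null_config(seed=seed, **base)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
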