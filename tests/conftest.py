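import numpy as np
import pandas as pd
import pytest

from phyllo.tables import FeatureTable, SampleMetadata


@pytest.fixture
def toy_table() -> FeatureTable:
    """3 taxa x 4 samples with easy hand-checkable counts."""
    counts = pd.DataFrame(
        {
            "s1": [1, 1, 2],
            "s2": [10, 0, 0],
            "s3": [5, 5, 0],
            "s4": [0, 2, 2],
        },
        index=["ASV1", "ASV2", "ASV3"],
    )
    kingdom = pd.Series(["bacteria", "bacteria", "fungi"], index=counts.index)
    return FeatureTable(counts, kingdom)


@pytest.fixture
def paired_metadata() -> SampleMetadata:
    frame = pd.DataFrame(
        {
            "site": ["QH", "QH", "WC", "WC"],
            "genotype": ["wild", "cultivated", "wild", "cultivated"],
            "replicate": [1, 1, 1, 1],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SampleMetadata(frame)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_table(counts: np.ndarray, prefix: str = "ASV", kingdom: str = "bacteria") -> FeatureTable:
    """Wrap a raw taxon x sample array into a FeatureTable."""
    counts = np.asarray(counts)
    ids = [f"{prefix}{i + 1}" for i in range(counts.shape[0])]
    samples = [f"s{j + 1}" for j in range(counts.shape[1])]
    return FeatureTable(
        pd.DataFrame(counts, index=ids, columns=samples),
        pd.Series(kingdom, index=ids),
    )
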