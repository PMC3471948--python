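import numpy as np
import pandas as pd
import pytest

import crossexpr as cx


@pytest.fixture(scope="session")
def sim_bundle():
    """A small default-noise synthetic bundle shared by read-only tests."""
    cfg = cx.SimulationConfig(n_pairs=300, seed=42)
    return cx.simulate(cfg)


@pytest.fixture()
def tiny_dataset():
    """3 genes x 6 samples, 2 replicates per stage, hand-chosen values."""
    samples = pd.DataFrame(
        {
            "sample_id": ["M1", "M2", "B1", "B2", "I1", "I2"],
            "species": ["mouse"] * 6,
            "stage": ["morula", "morula", "blastocyst", "blastocyst", "ICM", "ICM"],
            "replicate": [1, 2, 1, 2, 1, 2],
        }
    )
    values = pd.DataFrame(
        [
            [5.0, 5.4, 6.0, 6.4, 8.0, 8.0],   # means 5.2 / 6.2 / 8.0
            [7.0, 7.0, 7.0, 7.0, 7.0, 7.0],   # flat
            [4.0, 4.0, 6.0, 6.0, 3.0, 3.0],   # up then down
        ],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=samples["sample_id"],
    )
    return cx.ExpressionDataset(species_label="mouse", values=values, samples=samples)


def random_dataset(rng: np.random.Generator, n_genes: int = 50, species: str = "sp") -> "cx.ExpressionDataset":
    """Random but valid dataset with 2 replicates per stage."""
    samples = pd.DataFrame(
        {
            "sample_id": [f"{species}_s{i}" for i in range(6)],
            "species": [species] * 6,
            "stage": ["morula", "morula", "blastocyst", "blastocyst", "ICM", "ICM"],
            "replicate": [1, 2, 1, 2, 1, 2],
        }
    )
    values = pd.DataFrame(
        rng.normal(8, 2, size=(n_genes, 6)),
        index=pd.Index([f"{species}_g{i:04d}" for i in range(n_genes)], name="gene_id"),
        columns=samples["sample_id"],
    )
    return cx.ExpressionDataset(species_label=species, values=values, samples=samples)
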