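"""Shared fixtures: seeded RNG and small random-object factories."""

import numpy as np
import pandas as pd
import pytest

from phagepanel import (
    DistanceMatrix,
    FeatureSpec,
    InfectionMatrix,
    Partition,
    PhenotypeTable,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_distance_matrix(rng, n, max_d=1.0):
    m = rng.uniform(0, max_d, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix([f"i{k}" for k in range(n)], m)


def random_partition(rng, items, n_groups):
    labels = [str(rng.integers(n_groups)) for _ in items]
    return Partition(list(items), labels)


def random_infection_matrix(rng, n_phages, n_strains):
    vals = rng.integers(0, 2, size=(n_phages, n_strains))
    return InfectionMatrix(
        [f"p{i}" for i in range(n_phages)],
        [f"s{j}" for j in range(n_strains)],
        vals,
    )


def random_phenotype_table(rng, n, n_binary=3, n_quant=2, p_missing=0.0):
    cols, feats = {}, []
    for j in range(n_binary):
        name = f"b{j}"
        cols[name] = rng.integers(0, 2, size=n).astype(float)
        feats.append(FeatureSpec(name, "binary"))
    for j in range(n_quant):
        name = f"q{j}"
        cols[name] = rng.normal(size=n)
        feats.append(FeatureSpec(name, "quantitative"))
    df = pd.DataFrame(cols, index=[f"i{k}" for k in range(n)])
    if p_missing > 0:
        mask = rng.random(df.shape) < p_missing
        # never blank an entire row: every pair must share a feature
        mask[:, 0] = False
        df = df.mask(mask)
    return PhenotypeTable(list(df.index), feats, df)
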