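import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from halocca.datamodel import AbundanceMatrix, EnvTable, LineageTable, ModuleMap

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_env() -> EnvTable:
    frame = pd.DataFrame(
        {
            "station": ["TT", "BB", "BP", "BW"],
            "depth": [5.0, 5.0, 10.0, 5.0],
            "size_fraction": ["combined"] * 4,
            "salinity": [0.5, 5.0, 12.0, 30.0],
            "temperature": [8.0, 9.5, 11.0, 14.0],
            "oxygen": [11.0, 10.5, 10.0, 9.0],
        },
        index=pd.Index(["GS1", "GS2", "GS3", "GS4"], name="sample_id"),
    )
    return EnvTable(frame)


@pytest.fixture
def counts_2x2() -> AbundanceMatrix:
    frame = pd.DataFrame(
        {"K00001": [100.0, 300.0], "K00002": [0.0, 100.0]},
        index=pd.Index(["GS1", "GS2"], name="sample_id"),
    )
    return AbundanceMatrix(frame, "ko", "raw_counts")


@pytest.fixture
def small_lineage() -> LineageTable:
    frame = pd.DataFrame(
        {
            "superkingdom": ["Bacteria"] * 4,
            "phylum": ["Proteobacteria", "Proteobacteria", "Actinobacteria", "Actinobacteria"],
            "class": ["Alphaproteobacteria", "Gammaproteobacteria", "Actinomycetia", "Actinomycetia"],
            "order": ["Pelagibacterales", "Alteromonadales", "Micrococcales", "Nanopelagicales"],
            "genus": ["Pelagibacter", "Alteromonas", "Limnoluna", "Nanopelagicus"],
        },
        index=pd.Index(
            ["Pelagibacter", "Alteromonas", "Limnoluna", "Nanopelagicus"], name="taxon"
        ),
    )
    return LineageTable(frame)


@pytest.fixture
def small_module_map() -> ModuleMap:
    return ModuleMap.from_pairs(
        [
            ("K00001", "M1"),
            ("K00002", "M1"),
            ("K00003", "M2"),
            ("K00002", "M2"),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
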