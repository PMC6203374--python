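import numpy as np
import pandas as pd
import pytest

import trussmorph as tm
from trussmorph.size_correction import CorrectedTable, SizeCorrectionModel
from trussmorph.synthetic import default_n_per_species


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def barbinae_dataset():
    """Default five-species synthetic dataset at the published sample sizes."""
    models = tm.default_barbinae_models()
    cfg = tm.GeneratorConfig(
        species=models, n_per_species=default_n_per_species(), seed=42
    )
    return tm.generate(cfg)


@pytest.fixture(scope="session")
def separated_dataset():
    """Well-separated five-species benchmark (separation 10, tight noise)."""
    models = tm.default_barbinae_models(separation=10.0, shape_sd=0.002)
    cfg = tm.GeneratorConfig(
        species=models, n_per_species=[20, 20, 20, 20, 20], seed=7
    )
    return tm.generate(cfg)


def make_corrected(values: np.ndarray, species, columns=None, index=None) -> CorrectedTable:
    """Wrap a raw matrix + labels as a CorrectedTable for multivariate stages."""
    values = np.asarray(values, dtype=float)
    columns = columns or [f"v{i}" for i in range(values.shape[1])]
    index = pd.Index(
        index if index is not None else [f"s{i}" for i in range(values.shape[0])],
        name="specimen_id",
    )
    return CorrectedTable(
        values=pd.DataFrame(values, columns=columns, index=index),
        species=pd.Series(list(species), index=index, name="species"),
        provenance=SizeCorrectionModel(method="m_transform"),
    )
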