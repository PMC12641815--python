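import numpy as np
import pytest

from spectraqsar import (
    Dataset,
    GeneratorConfig,
    SpectrumRecord,
    generate_dataset,
    generate_homolog_ladder,
)


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """120 mixed-scaffold compounds, enough for embedding/cluster tests."""
    return generate_dataset(GeneratorConfig(n_compounds=120, seed=11))


@pytest.fixture(scope="session")
def qsar_dataset() -> Dataset:
    """The default-size corpus used for model-benchmark tests."""
    return generate_dataset(GeneratorConfig(n_compounds=1000, seed=1))


@pytest.fixture(scope="session")
def ladder() -> Dataset:
    """PCB-like chlorination ladder, k=1..10, 5 replicates, low noise."""
    return generate_homolog_ladder(1, 10, 5, intensity_noise_cv=0.05, seed=1)


@pytest.fixture()
def toy_record() -> SpectrumRecord:
    return SpectrumRecord(
        compound_id="TOY-1",
        name="toy",
        peaks=[(77.0, 500.0), (152.0, 999.0)],
        ri=1200.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
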