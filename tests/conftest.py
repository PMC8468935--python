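import numpy as np
import pandas as pd
import pytest

from meatspec import GeneratorConfig, SpectraSet, generate_dataset

#: Coarser grid (201 instead of 1001 wavelengths) used by the heavier
#: tests; every checked property is grid-resolution independent.
FAST_STEP = 3.0


@pytest.fixture(scope="session")
def fast_dataset():
    """Default-parameter synthetic dataset on the coarse grid."""
    return generate_dataset(GeneratorConfig(wavelength_step=FAST_STEP, seed=42))


@pytest.fixture()
def toy_spectra():
    """Tiny hand-built spectra set with metadata."""
    wavelengths = np.linspace(400.0, 700.0, 31)
    rng = np.random.default_rng(7)
    base = 0.5 + 0.3 * np.sin(wavelengths / 60.0)
    reflectance = base + 0.05 * rng.normal(size=(6, wavelengths.size))
    ids = [f"s{i}" for i in range(6)]
    metadata = pd.DataFrame(
        {
            "cut_type": ["oyster", "fillet"] * 3,
            "carcass_id": ["D1C1", "D1C1", "D1C2", "D1C2", "D2C1", "D2C1"],
            "day": [1, 1, 1, 1, 2, 2],
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return SpectraSet(
        wavelengths=wavelengths, reflectance=reflectance, sample_ids=ids,
        metadata=metadata,
    )
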