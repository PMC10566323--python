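import numpy as np
import pytest

from thermoseq.io import Dataset, ProteinRecord
from thermoseq.synthetic import GeneratorConfig, generate, make_golden_fixtures


@pytest.fixture(scope="session")
def golden_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("golden")
    make_golden_fixtures(out)
    return out


@pytest.fixture(scope="session")
def separable_ds():
    """~150-record dataset with a strong composition signal, short sequences."""
    return generate(
        GeneratorConfig(
            n_species_thermo=8, n_species_meso=12, proteins_per_species=(5, 10),
            length_range=(82, 140), effect_size=2.0, seed=3,
        )
    )


@pytest.fixture(scope="session")
def small_labeled_ds():
    """30 records, 3 species per class, deterministic."""
    rng = np.random.RandomState(11)
    records = []
    for s in range(6):
        thermo = s < 3
        for p in range(5):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
            records.append(
                ProteinRecord(
                    id=f"sp{s}_p{p}",
                    sequence=seq,
                    species=f"species_{s}",
                    ogt=75.0 if thermo else 25.0,
                    label=int(thermo),
                )
            )
    return Dataset(records, provenance="unit fixture")


@pytest.fixture
def rng():
    return np.random.RandomState(0)
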