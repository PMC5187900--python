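import numpy as np
import pandas as pd
import pytest

from pigbv import (
    Pedigree,
    PedigreeRecord,
    ScenarioConfig,
    UNKNOWN,
    make_field_scenario,
)
from pigbv.io import BayesBSettings
from pigbv.simulate import GenotypeMatrix


def random_pedigree(n: int, seed: int, p_unknown: float = 0.25) -> Pedigree:
    """Messy random pedigree: arbitrary parent choice from earlier animals,
    unknown-parent gaps, and (through repeated ancestors) inbreeding."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        sire = dam = UNKNOWN
        if i > 1 and rng.random() > p_unknown:
            sire = f"R{rng.integers(0, i):04d}"
        if i > 1 and rng.random() > p_unknown:
            dam = f"R{rng.integers(0, i):04d}"
            if dam == sire:
                dam = UNKNOWN
        recs.append(PedigreeRecord(f"R{i:04d}", sire, dam, cohort=i // 50))
    return Pedigree(recs)


def toy_genotypes(n: int, m: int, seed: int, freqs=None) -> GenotypeMatrix:
    rng = np.random.default_rng(seed)
    p = np.asarray(freqs) if freqs is not None else rng.uniform(0.2, 0.8, m)
    D = rng.binomial(2, p, (n, m)).astype(float)
    ids = [f"M{j:03d}" for j in range(m)]
    meta = pd.DataFrame(
        {"allele_freq": p, "is_major": False, "label": "chip"},
        index=pd.Index(ids, name="marker_id"),
    )
    return GenotypeMatrix([f"A{i:04d}" for i in range(n)], ids, D, meta)


@pytest.fixture(scope="session")
def small_scenario_config() -> ScenarioConfig:
    """Down-scaled field design for fast structural tests."""
    return ScenarioConfig(
        n_founders=40,
        n_cohorts=6,
        litters_per_cohort=10,
        litter_size=5,
        n_markers=30,
        n_training=20,
        n_testing=15,
        n_background=80,
        n_littermates=30,
        background_cohorts=4,
    )


@pytest.fixture(scope="session")
def small_bundle(small_scenario_config):
    return make_field_scenario(small_scenario_config, seed=123)


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size synthetic study (65/70/936/196 design)."""
    return make_field_scenario(seed=2024)


@pytest.fixture(scope="session")
def fast_bayes_settings() -> BayesBSettings:
    return BayesBSettings(chain_length=2000, burn_in=500, thinning=5)
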