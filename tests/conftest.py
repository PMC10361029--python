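import numpy as np
import pytest

from erpmkl.synth import EffectSpec, SynthConfig, synth_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    """Small, fast cohort: 2+3 subjects, one block, 125 Hz, no artifacts."""
    return SynthConfig(
        n_pos=2, n_neg=3, fs=125.0, n_blocks=1, stimuli_per_valence=4,
        artifact_rate=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return synth_cohort(tiny_config)


@pytest.fixture(scope="session")
def planted_config() -> SynthConfig:
    """Cohort with one strong planted source, sized for CV unit tests."""
    return SynthConfig(
        n_pos=6, n_neg=8, fs=125.0, n_blocks=1, stimuli_per_valence=20,
        artifact_rate=0.0, seed=5,
        effects=(EffectSpec(roi=8, band="gamma", valence="positive", effect_size=3.0),),
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_config):
    return synth_cohort(planted_config)


@pytest.fixture(scope="session")
def planted_table(planted_cohort):
    from erpmkl.features import build_feature_table

    return build_feature_table(planted_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
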