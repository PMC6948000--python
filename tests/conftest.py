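import numpy as np
import pytest

from ewasrep.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with planted signal, confounding and batch structure."""
    cfg = SyntheticConfig(
        n_samples=100,
        n_probes=500,
        n_causal=30,
        effect_scale=1e-3,
        noise_sd=0.01,
        confounder_strength=1.0,
        confounder_loading_sd=0.008,
        slide_sd=0.004,
        cell_effect_sd=0.01,
        seed=42,
    )
    meth, pheno, truth = generate_cohort(cfg)
    return cfg, meth, pheno, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def noise_free_config(**overrides) -> SyntheticConfig:
    base = dict(
        n_samples=60,
        n_probes=20,
        n_causal=1,
        effect_scale=1e-4,
        effect_jitter=0.0,
        noise_sd=1e-12,
        confounder_strength=0.0,
        slide_sd=0.0,
        cell_effect_sd=0.0,
        seed=5,
    )
    base.update(overrides)
    return SyntheticConfig(**base)
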