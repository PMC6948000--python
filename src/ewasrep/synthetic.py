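"""Synthetic methylation cohorts with planted association structure.

Generates beta-valued methylation matrices with probe-specific baselines,
planted linear trait effects, cell-mixture and slide-batch structure, a
hidden confounding factor, and a paired "reference cohort" summary table
with scaled effects, sampling noise and a configurable fraction of
sign-discordant probes.  Every downstream stage of the pipeline is testable
against the ground truth recorded here.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

Z95 = float(stats.norm.ppf(0.975))

CELL_TYPES = ("Bcell", "CD4T", "CD8T", "Gran", "Mono", "NK")
# Mean whole-blood fractions used for the Dirichlet trait model.
CELL_MEANS = (0.04, 0.11, 0.11, 0.47, 0.09, 0.11)

SMOKING_LEVELS = ("never", "former", "current")
EDUCATION_LEVELS = ("none", "primary", "secondary")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``se_profile`` describes the reference-study standard errors; supported
    kinds are ``{"kind": "lognormal", "median": m, "sigma": s}`` and
    ``{"kind": "constant", "value": v}``.
    """

    n_samples: int = 120
    n_probes: int = 5000
    n_causal: int = 50
    effect_scale: float = 1e-3
    se_profile: dict = field(
        default_factory=lambda: {"kind": "lognormal", "median": 1e-4, "sigma": 0.4}
    )
    discordant_fraction: float = 0.0
    reference_effect_multiplier: float = 1.0
    reference_noise_scale: float = 1.0
    confounder_strength: float = 0.0
    confounder_fraction: float = 0.5
    confounder_loading_sd: float = 0.01
    n_slides: int = 4
    slide_sd: float = 0.0
    cell_effect_sd: float = 0.0
    noise_sd: float = 0.01
    seed: int = 0
    trait: str = "alcohol"
    effect_jitter: float = 0.0
    logit_scale: bool = False
    embed_cell_reference: bool = False
    n_reference: int = 5000
    reference_ancestry: str = "EUR"

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if not math.isfinite(v):
                    raise ValueError(f"non-finite value for config field {f.name!r}: {v}")
        if not 0.0 <= self.discordant_fraction <= 1.0:
            raise ValueError("discordant_fraction must lie in [0, 1]")
        if self.n_causal > self.n_probes:
            raise ValueError("n_causal must not exceed n_probes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be strictly positive")
        if self.n_samples < 2 or self.n_probes < 1:
            raise ValueError("n_samples must be >= 2 and n_probes >= 1")
        if self.n_slides < 1:
            raise ValueError("n_slides must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        return cls.from_dict(json.loads(text))


def _probe_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")


def _sample_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")


def _generate_phenotypes(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    age = rng.uniform(45.0, 88.0, n)
    # Zero-inflated alcohol intake: ~47% never-users, gamma tail for users.
    drinks = rng.random(n) >= 0.47
    alcohol = np.where(drinks, rng.gamma(1.2, 26.0, n), 0.0)
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=[0.47, 0.02, 0.51])
    bmi = np.clip(rng.normal(22.5, 4.9, n), 15.0, 45.0)
    wc = np.clip(rng.normal(83.8, 12.8, n), 55.0, 140.0)
    physical_activity = np.clip(rng.normal(2.41, 0.94, n), 0.1, None)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=[0.22, 0.55, 0.23])
    crp = np.exp(rng.normal(np.log(4.0), 1.0, n))
    tc = np.clip(rng.normal(171.0, 41.6, n), 60.0, None)
    ldl = np.clip(rng.normal(96.5, 35.7, n), 20.0, None)
    hdl = np.clip(rng.normal(54.1, 22.7, n), 10.0, None)
    tg = np.clip(rng.normal(48.5, 30.5, n), 10.0, None)
    cellfrac = rng.dirichlet(np.asarray(CELL_MEANS) * 80.0, size=n)
    slide = np.array([f"slide{j:02d}" for j in rng.integers(0, config.n_slides, n)])
    hidden = rng.standard_normal(n)

    pheno = pd.DataFrame(
        {
            "age": age,
            "bmi": bmi,
            "wc": wc,
            "alcohol": alcohol,
            "smoking": smoking,
            "physical_activity": physical_activity,
            "education": education,
            "crp": crp,
            "tc": tc,
            "ldl": ldl,
            "hdl": hdl,
            "tg": tg,
            "slide": slide,
            "hidden_factor": hidden,
        },
        index=_sample_ids(n),
    )
    for j, ct in enumerate(CELL_TYPES):
        pheno[ct] = cellfrac[:, j]
    return pheno


def _generate_truth(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.n_probes
    baseline = rng.uniform(0.15, 0.85, m)
    true_effect = np.zeros(m)
    causal = rng.choice(m, size=config.n_causal, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_causal)
    magnitude = config.effect_scale * (
        1.0 + config.effect_jitter * rng.uniform(-1.0, 1.0, config.n_causal)
    )
    true_effect[causal] = signs * magnitude

    discordant = np.zeros(m, dtype=bool)
    discordant[causal] = rng.random(config.n_causal) < config.discordant_fraction

    loading = np.zeros(m)
    loaded = rng.random(m) < config.confounder_fraction
    loading[loaded] = config.confounder_strength * rng.normal(
        0.0, config.confounder_loading_sd, int(loaded.sum())
    )

    return pd.DataFrame(
        {
            "true_effect": true_effect,
            "confounder_loading": loading,
            "discordant": discordant,
            "baseline": baseline,
        },
        index=_probe_ids(m),
    )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns ``(meth, pheno, truth)`` where ``meth`` is a probes x samples
    beta-value matrix in [0, 1], ``pheno`` a per-sample phenotype table (the
    ``hidden_factor`` and ``slide`` columns record the planted structure for
    test oracles), and ``truth`` the per-probe ground truth.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    pheno = _generate_phenotypes(config, rng)
    truth = _generate_truth(config, rng)

    t = pheno[config.trait].to_numpy(dtype=float)
    hidden = pheno["hidden_factor"].to_numpy()
    cellfrac = pheno[list(CELL_TYPES)].to_numpy()

    signal = truth["baseline"].to_numpy()[:, None] + np.outer(
        truth["true_effect"].to_numpy(), t
    )
    signal += np.outer(truth["confounder_loading"].to_numpy(), hidden)

    if config.cell_effect_sd > 0:
        cell_load = rng.normal(0.0, config.cell_effect_sd, (config.n_probes, len(CELL_TYPES)))
        centred = cellfrac - np.asarray(CELL_MEANS)
        signal += cell_load @ centred.T

    if config.slide_sd > 0:
        slide_codes = pd.Categorical(pheno["slide"]).codes
        slide_eff = rng.normal(0.0, config.slide_sd, (config.n_probes, config.n_slides))
        signal += slide_eff[:, slide_codes]

    signal += rng.normal(0.0, config.noise_sd, signal.shape)

    if config.logit_scale:
        base = truth["baseline"].to_numpy()[:, None]
        logit = np.log(base / (1.0 - base)) + (signal - base) / (base * (1.0 - base))
        beta = 1.0 / (1.0 + np.exp(-logit))
    else:
        beta = np.clip(signal, 0.0, 1.0)

    meth = pd.DataFrame(beta, index=truth.index, columns=pheno.index)

    if config.embed_cell_reference:
        from ewasrep.cells import default_cell_reference

        ref = default_cell_reference()
        mixed = ref.to_numpy() @ cellfrac.T
        mixed += rng.normal(0.0, config.noise_sd, mixed.shape)
        extra = pd.DataFrame(np.clip(mixed, 0.0, 1.0), index=ref.index, columns=pheno.index)
        meth = pd.concat([meth, extra])
        meth.index.name = "probe_id"

    return meth, pheno, truth


def _draw_reference_se(
    profile: dict, n: int, rng: np.random.Generator
) -> np.ndarray:
    kind = profile.get("kind", "lognormal")
    if kind == "lognormal":
        median = float(profile.get("median", 1e-4))
        sigma = float(profile.get("sigma", 0.4))
        if median <= 0:
            raise ValueError("se_profile median must be positive")
        se = np.exp(rng.normal(np.log(median), sigma, n))
    elif kind == "constant":
        value = float(profile.get("value", 1e-4))
        se = np.full(n, value)
    else:
        raise ValueError(f"unknown se_profile kind {kind!r}")
    if np.any(se <= 0):
        raise ValueError("se_profile produced non-positive standard errors")
    return se


def generate_reference_summary(truth: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Emulate a reference-study summary-statistics table for the truth probes.

    Reference effect = ``reference_effect_multiplier * true_effect`` with the
    sign flipped where the truth marks the probe discordant, plus Gaussian
    sampling noise scaled by the drawn SE.  p-values come from the two-sided
    normal statistic effect/SE; 95% CIs use the normal quantile.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    m = len(truth)
    se = _draw_reference_se(config.se_profile, m, rng)
    sign = np.where(truth["discordant"].to_numpy(), -1.0, 1.0)
    effect = config.reference_effect_multiplier * truth["true_effect"].to_numpy() * sign
    effect = effect + rng.normal(0.0, se * config.reference_noise_scale, m)

    z = effect / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0.0, 1.0), 1.0)
    table = pd.DataFrame(
        {
            "probe_id": truth.index.to_numpy(),
            "trait": config.trait,
            "cohort": "reference",
            "ancestry": config.reference_ancestry,
            "n": config.n_reference,
            "effect": effect,
            "se": se,
            "p": p,
            "ci_low": effect - Z95 * se,
            "ci_high": effect + Z95 * se,
            "model_id": "reference_summary",
        }
    )
    return table


def generate_detection_matrix(
    config: SyntheticConfig,
    planted_bad_samples: int = 0,
    planted_bad_probes: int = 0,
) -> pd.DataFrame:
    """Detection p-value matrix with planted QC failures.

    Background p-values are drawn uniform on (0, 0.001), far below the 0.01
    detection threshold.  The first ``planted_bad_samples`` samples and the
    first ``planted_bad_probes`` probes get 10% of their entries pushed above
    the threshold, so the QC stage should exclude exactly those.
    """
    config.validate()
    if planted_bad_samples > config.n_samples:
        raise ValueError("planted_bad_samples exceeds n_samples")
    if planted_bad_probes > config.n_probes:
        raise ValueError("planted_bad_probes exceeds n_probes")
    rng = np.random.default_rng([config.seed, 3])
    m, n = config.n_probes, config.n_samples
    det = rng.uniform(0.0, 0.001, (m, n))

    # plants are staggered so no un-planted row or column accumulates enough
    # failing entries to cross the 5% exclusion threshold itself
    k_rows = max(1, math.ceil(0.10 * m))
    for j in range(planted_bad_samples):
        idx = (j * k_rows + np.arange(k_rows)) % m
        det[idx, j] = rng.uniform(0.02, 0.5, k_rows)
    k_cols = max(1, math.ceil(0.10 * n))
    for i in range(planted_bad_probes):
        idx = (i * k_cols + np.arange(k_cols)) % n
        det[i, idx] = rng.uniform(0.02, 0.5, k_cols)

    return pd.DataFrame(det, index=_probe_ids(m), columns=_sample_ids(n))
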