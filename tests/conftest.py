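"""Shared fixtures: synthetic cohorts at several scales and template factories."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from egmloc.cohort import CohortConfig, generate_cohort
from egmloc.pipeline import build_feature_table, site_templates
from egmloc.preprocess import N_TEMPLATE, TEMPLATE_MS, BeatTemplate
from egmloc.regionalize import OCTANT_CODES

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

TPL_DT = TEMPLATE_MS / N_TEMPLATE


def make_template(
    bumps: list[tuple[float, float, float]],
    lead: str = "far_field",
    time_origin_ms: float = -120.0,
    n: int = N_TEMPLATE,
    dt: float = TPL_DT,
) -> BeatTemplate:
    """Noise-free template from Gaussian bumps ``(amp, center_ms, width_ms)``.

    Centers are snapped to the sample grid so that extrema fall exactly on
    samples.
    """
    t = np.arange(n) * dt
    v = np.zeros(n)
    for amp, center, width in bumps:
        c = round(center / dt) * dt
        v += amp * np.exp(-0.5 * ((t - c) / width) ** 2)
    return BeatTemplate(
        lead=lead,
        samples=v,
        sampling_interval_ms=dt,
        anchor_index=int(np.argmax(v)),
        time_origin_ms=time_origin_ms,
        with_stimulus=False,
    )


@pytest.fixture(scope="session")
def template_factory():
    return make_template


def _small_config(**overrides) -> CohortConfig:
    base = dict(
        octant_counts={c: 3 for c in OCTANT_CODES},
        n_patients=8,
        seed=7,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return _small_config()


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_templates(small_cohort):
    return {s.site_id: site_templates(s) for s in small_cohort}


@pytest.fixture(scope="session")
def small_table(small_cohort, small_templates):
    return build_feature_table(small_cohort, small_templates)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale cohort: 23 patients, published per-octant counts."""
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def recovery_cohort():
    """High-effect-size, low-noise cohort for the parameter-recovery check."""
    cfg = CohortConfig(effect_size=1.5, noise_sd=0.02, seed=11)
    sites = generate_cohort(cfg)
    templates = {s.site_id: site_templates(s) for s in sites}
    table = build_feature_table(sites, templates)
    return cfg, sites, templates, table
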