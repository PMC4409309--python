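"""Synthetic paced-EGM cohort generator.

Clinical ICD electrograms of the study type are not publicly distributable,
so this module emulates them: two-lead (far-field can-to-coil, bipolar
tip-to-ring) paced trains whose beat morphology is a sum of three
Gaussian-shaped far-field deflections (initial, peak, final), a bipolar
intrinsic deflection, a narrow pacing-stimulus spike, sinusoidal baseline
drift and additive white noise.

The generated cohort mirrors the study database: 23 patients, the published
per-octant site counts, ≥10-beat trains at a 400/500 ms cycle length, a
scar/normal dichotomy at 1.5 mV bipolar peak-to-peak, and per-patient
coordinate frames with an arbitrary offset so that per-patient recentering
is non-trivial.

Octant identity drives morphology through disjoint parameter subsets per
axis (scaled by ``effect_size``):

* apical/basal shifts the onset-to-intrinsic-deflection lag ``bip_delay``;
* septal/lateral shifts the initial-deflection amplitude ``a_I``;
* superior/inferior shifts the final-deflection amplitude ``a_F`` (and,
  weakly, the peak amplitude ``a_P``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import EgmRecording, N_TEMPLATE, TEMPLATE_MS
from .regionalize import (
    OCTANT_CODES,
    OctantLabel,
    assign_octant,
    recenter,
    tissue_label,
)

__all__ = [
    "DeflectionParams",
    "CohortConfig",
    "SiteRecord",
    "TABLE1_OCTANT_COUNTS",
    "synth_beat",
    "synth_pacing_train",
    "generate_cohort",
    "true_onset_time",
    "true_intrinsic_time",
    "true_bipolar_peak_to_peak",
]

#: Published per-octant site counts of the study database.
TABLE1_OCTANT_COUNTS = {
    "BSS": 37,
    "BSI": 38,
    "BLS": 64,
    "BLI": 94,
    "ASS": 45,
    "ASI": 41,
    "ALS": 50,
    "ALI": 46,
}

# Within-octant jitter scales (1-sigma) applied on top of the octant means.
_JITTER_A_I = 0.05
_JITTER_A_P = 0.10
_JITTER_A_F = 0.05
_JITTER_BIP_DELAY = 2.0  # ms
# Octant-axis effect magnitudes at effect_size = 1.
_EFFECT_BIP_DELAY = 12.0  # ms, basal +, apical -
_EFFECT_A_I = 0.25  # lateral more negative
_EFFECT_A_F = 0.35  # superior more negative
_EFFECT_A_P = 0.15  # superior slightly taller peak


@dataclass(frozen=True)
class DeflectionParams:
    """Morphology parameters of one paced beat (both leads).

    Amplitudes in mV, times and widths in ms. Deflection centers ``tau_*``
    are offsets from the pacing stimulus; widths are Gaussian sigmas.
    """

    a_I: float = -0.8
    a_P: float = 2.0
    a_F: float = -0.8
    tau_I: float = 35.0
    tau_P: float = 65.0
    tau_F: float = 100.0
    w_I: float = 8.0
    w_P: float = 9.0
    w_F: float = 12.0
    bip_delay: float = 40.0
    bip_amp: float = 2.5
    bip_width: float = 6.0
    stim_amp: float = 4.0
    stim_width: float = 4.0
    drift_amp: float = 0.3
    drift_period: float = 2000.0
    noise_sd: float = 0.05

    def validate(self) -> None:
        if min(self.w_I, self.w_P, self.w_F, self.bip_width, self.stim_width) <= 0:
            raise ValueError("all deflection widths must be positive")
        if not (self.tau_I < self.tau_P < self.tau_F):
            raise ValueError("deflection centers must satisfy tau_I < tau_P < tau_F")
        if self.a_I > 0 or self.a_F > 0 or self.a_P < 0:
            raise ValueError("amplitude signs must satisfy a_I <= 0 <= a_P, a_F <= 0")
        if self.tau_F - self.tau_P > 170.0:
            raise ValueError("final deflection must lie within 170 ms of the peak")
        if self.a_P < 3.0 * abs(self.noise_sd):
            raise ValueError("peak amplitude must exceed three noise standard deviations")
        if self.bip_delay < 0:
            raise ValueError("bipolar delay must be non-negative")
        if self.drift_period <= 0:
            raise ValueError("drift period must be positive")


def _gauss(t: np.ndarray, amp: float, center: float, width: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def _far_field_deflections(params: DeflectionParams, t: np.ndarray) -> np.ndarray:
    return (
        _gauss(t, params.a_I, params.tau_I, params.w_I)
        + _gauss(t, params.a_P, params.tau_P, params.w_P)
        + _gauss(t, params.a_F, params.tau_F, params.w_F)
    )


def _stimulus_spike(params: DeflectionParams, t: np.ndarray) -> np.ndarray:
    return _gauss(t, params.stim_amp, 0.0, params.stim_width / 2.0)


def true_onset_time(params: DeflectionParams) -> float:
    """Far-field onset of the noiseless beat (ms after the stimulus).

    The onset convention matches the feature extractor: the earliest time
    at which |v| crosses 10% of the peak voltage, evaluated on the
    stimulus-free closed-form deflection sum (0.01 ms resolution).
    """
    t = np.arange(0.0, params.tau_F + 4 * params.w_F, 0.01)
    v = _far_field_deflections(params, t)
    v_peak = float(v.max())
    if v_peak <= 0:
        raise ValueError("beat has no positive peak deflection")
    above = np.abs(v) >= 0.1 * v_peak
    idx = int(np.argmax(above))
    if not above[idx]:
        raise ValueError("no onset crossing found")
    return float(t[idx])


def true_intrinsic_time(params: DeflectionParams) -> float:
    """Bipolar intrinsic-deflection time (steepest downslope), ms after stimulus."""
    return true_onset_time(params) + params.bip_delay


def _bipolar_deflection(params: DeflectionParams, t: np.ndarray) -> np.ndarray:
    # Gaussian bump whose steepest downslope (center + width) falls at the
    # intrinsic-deflection time: far-field onset + bip_delay.
    center = true_intrinsic_time(params) - params.bip_width
    return _gauss(t, params.bip_amp, center, params.bip_width)


def true_bipolar_peak_to_peak(params: DeflectionParams) -> float:
    """Noiseless, drift- and stimulus-free bipolar peak-to-peak voltage (mV)."""
    t = np.arange(0.0, params.tau_F + 6 * params.w_F + params.bip_delay, 0.01)
    v = _bipolar_deflection(params, t)
    return float(v.max() - v.min())


def synth_beat(
    params: DeflectionParams,
    t_grid: np.ndarray,
    rng: np.random.Generator | None = None,
    lead: str = "far_field",
    include_stimulus: bool = True,
    include_drift: bool = True,
) -> np.ndarray:
    """Evaluate one beat waveform on ``t_grid`` (ms after the stimulus).

    The waveform is the sum of the lead's deflections, the stimulus spike
    at t = 0, sinusoidal baseline drift and (when an ``rng`` is given and
    ``noise_sd > 0``) additive white noise.
    """
    params.validate()
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be non-empty and strictly increasing")
    if lead == "far_field":
        v = _far_field_deflections(params, t)
    elif lead == "bipolar":
        v = _bipolar_deflection(params, t)
    else:
        raise ValueError(f"unknown lead {lead!r}")
    if include_stimulus:
        v = v + _stimulus_spike(params, t)
    if include_drift and params.drift_amp != 0:
        v = v + params.drift_amp * np.sin(2 * np.pi * t / params.drift_period)
    if rng is not None and params.noise_sd > 0:
        v = v + rng.normal(0.0, params.noise_sd, t.size)
    return v


def synth_pacing_train(
    params: DeflectionParams,
    n_beats: int,
    cycle_length_ms: float,
    sampling_interval_ms: float = TEMPLATE_MS / N_TEMPLATE,
    seed: int = 0,
) -> tuple[EgmRecording, EgmRecording]:
    """Generate one paced train on both leads.

    Stimuli are exactly ``cycle_length_ms`` apart; the recording spans
    ``n_beats * cycle_length_ms``. Drift is shared between leads (common
    phase); noise is drawn independently per lead. Identical arguments and
    seed reproduce bitwise-identical sample arrays.
    """
    params.validate()
    if n_beats < 1:
        raise ValueError("a pacing train needs at least one beat")
    if cycle_length_ms <= 0 or sampling_interval_ms <= 0:
        raise ValueError("cycle length and sampling interval must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(n_beats * cycle_length_ms / sampling_interval_ms))
    t = np.arange(n_samples) * sampling_interval_ms
    stim_times = np.arange(n_beats) * cycle_length_ms
    ff = np.zeros(n_samples)
    bip = np.zeros(n_samples)
    for s in stim_times:
        tb = t - s
        ff += _far_field_deflections(params, tb) + _stimulus_spike(params, tb)
        bip += _bipolar_deflection(params, tb) + _stimulus_spike(params, tb)
    if params.drift_amp != 0:
        drift = params.drift_amp * np.sin(2 * np.pi * t / params.drift_period)
        ff += drift
        bip += drift
    if params.noise_sd > 0:
        ff = ff + rng.normal(0.0, params.noise_sd, n_samples)
        bip = bip + rng.normal(0.0, params.noise_sd, n_samples)
    common = dict(sampling_interval_ms=sampling_interval_ms, stimulus_times_ms=stim_times)
    return (
        EgmRecording(lead="far_field", samples=ff, **common),
        EgmRecording(lead="bipolar", samples=bip, **common),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_patients: int = 23
    octant_counts: dict = field(default_factory=lambda: dict(TABLE1_OCTANT_COUNTS))
    n_beats: int = 10
    cycle_length_ms: float = 500.0
    sampling_interval_ms: float = TEMPLATE_MS / N_TEMPLATE
    effect_size: float = 1.0
    scar_fraction: float = 0.5
    coordinate_spread_cm: float = 0.8
    noise_sd: float = 0.05
    param_jitter_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if set(self.octant_counts) != set(OCTANT_CODES):
            raise ValueError("octant_counts must have exactly the eight octant codes")
        if any(c < 0 for c in self.octant_counts.values()):
            raise ValueError("octant counts must be non-negative")
        if sum(self.octant_counts.values()) == 0:
            raise ValueError("octant counts sum to zero")
        if self.cycle_length_ms not in (400.0, 500.0, 400, 500):
            raise ValueError("cycle_length_ms must be 400 or 500")
        if self.n_beats < 1:
            raise ValueError("n_beats must be at least 1")
        if not 0 <= self.scar_fraction <= 1:
            raise ValueError("scar_fraction must lie in [0, 1]")
        if 2 * self.n_patients > sum(self.octant_counts.values()):
            raise ValueError(
                "each patient needs at least two sites (single-site patients "
                "recenter to the origin, losing their octant geometry)"
            )


@dataclass(frozen=True)
class SiteRecord:
    """One pacing site: identifiers, geometry, labels, and both leads."""

    patient_id: str
    site_id: str
    coords: np.ndarray  # raw (x, y, z) in the patient frame, cm
    octant: OctantLabel
    tissue: str
    far_field: EgmRecording
    bipolar: EgmRecording
    truth: DeflectionParams | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if self.tissue not in ("scar", "normal"):
            raise ValueError(f"unknown tissue label {self.tissue!r}")
        if abs(self.far_field.sampling_interval_ms - self.bipolar.sampling_interval_ms) > 1e-12:
            raise ValueError("leads must share the sampling interval")
        if self.far_field.samples.size != self.bipolar.samples.size:
            raise ValueError("leads must share the duration")
        if not np.array_equal(self.far_field.stimulus_times_ms, self.bipolar.stimulus_times_ms):
            raise ValueError("leads must share the stimulus times")
        object.__setattr__(self, "coords", coords)


_AXIS_SIGNS = {  # (ab, sl, si) signs per octant code; + = basal/lateral/superior
    code: (
        +1 if code[0] == "B" else -1,
        +1 if code[1] == "L" else -1,
        +1 if code[2] == "S" else -1,
    )
    for code in OCTANT_CODES
}
def _octant_sign_vector(code: str) -> np.ndarray:
    s = _AXIS_SIGNS[code]
    return np.array([s[1], s[2], s[0]], dtype=float)  # (x=sl, y=si, z=ab)


def _allocate_sites(config: CohortConfig, rng: np.random.Generator) -> list[tuple[int, str]]:
    """Deal octant slots to patients, keeping per-patient loads balanced.

    Recentering forces every patient's sites to straddle each dividing
    plane, so each patient first receives a sign-covering set of octants
    (usually one antipodal pair); remaining slots go to the least-loaded
    patient.
    """
    remaining = {code: int(config.octant_counts[code]) for code in OCTANT_CODES}
    assignment: list[tuple[int, str]] = []
    load = np.zeros(config.n_patients, dtype=int)
    for p in range(config.n_patients):
        needed = {0: {1, -1}, 1: {1, -1}, 2: {1, -1}}  # axis -> missing signs
        while any(needed.values()):
            best, best_gain = [], 0
            for code, left in remaining.items():
                if left <= 0:
                    continue
                gain = sum(
                    1 for ax, s in enumerate(_AXIS_SIGNS[code]) if s in needed[ax]
                )
                if gain > best_gain:
                    best, best_gain = [code], gain
                elif gain == best_gain and gain > 0:
                    best.append(code)
            if not best:
                raise ValueError(
                    "octant counts cannot give every patient sites on both "
                    "sides of every dividing plane"
                )
            code = best[int(rng.integers(len(best)))]
            remaining[code] -= 1
            load[p] += 1
            assignment.append((p, code))
            for ax, s in enumerate(_AXIS_SIGNS[code]):
                needed[ax].discard(s)
    for code in OCTANT_CODES:
        for _ in range(remaining[code]):
            candidates = np.flatnonzero(load == load.min())
            p = int(rng.choice(candidates))
            load[p] += 1
            assignment.append((p, code))
    return assignment


def _patient_centered_coords(
    codes: list[str], spread: float, rng: np.random.Generator, margin: float = 0.3
) -> np.ndarray:
    """Draw one patient's recentered coordinates consistent with its octants.

    Components are drawn around ±1.5 cm per axis with the configured
    spread, then driven to an exactly zero mean by a fixed-point loop that
    alternates mean subtraction with sign clamping, so that
    ``assign_octant(recenter(raw))`` returns the stored octant for every
    site.
    """
    signs = np.stack([_octant_sign_vector(c) for c in codes])
    mag = rng.normal(1.5, spread, signs.shape)
    c = signs * np.maximum(mag, margin + 0.05)
    for _ in range(500):
        m = c.mean(axis=0)
        c = c - m
        viol = signs * c < margin
        c[viol] = (signs * margin)[viol]
        if np.max(np.abs(m)) < 1e-12 and not viol.any():
            break
    c = c - c.mean(axis=0)
    if np.any(signs * c <= 0):
        raise RuntimeError("octant-consistent recentering failed to converge")
    return c


def _site_params(
    code: str, config: CohortConfig, rng: np.random.Generator, scar: bool
) -> DeflectionParams:
    s_ab, s_sl, s_si = _AXIS_SIGNS[code]
    e = config.effect_size
    j = config.param_jitter_scale
    bip_delay = 40.0 + _EFFECT_BIP_DELAY * e * s_ab + rng.normal(0, _JITTER_BIP_DELAY) * j
    a_I = -0.8 - _EFFECT_A_I * e * s_sl + rng.normal(0, _JITTER_A_I) * j
    a_F = -0.8 - _EFFECT_A_F * e * s_si + rng.normal(0, _JITTER_A_F) * j
    a_P = 2.0 + _EFFECT_A_P * e * s_si + rng.normal(0, _JITTER_A_P) * j
    if scar:
        bip_amp = rng.uniform(0.5, 1.3)
    else:
        bip_amp = rng.uniform(1.8, 3.5)
    return DeflectionParams(
        a_I=min(a_I, -0.01),
        a_P=max(a_P, 0.5),
        a_F=min(a_F, -0.05),
        bip_delay=max(bip_delay, 5.0),
        bip_amp=bip_amp,
        noise_sd=config.noise_sd,
    )


def generate_cohort(config: CohortConfig | None = None) -> list[SiteRecord]:
    """Generate the full multi-patient synthetic cohort.

    Per-octant site counts equal ``config.octant_counts`` exactly; octant
    labels are consistent with ``assign_octant(recenter(coords))`` for
    every site; tissue labels follow the 1.5 mV bipolar peak-to-peak rule
    on the realized noiseless bipolar deflection. The run is fully
    reproducible from ``config`` (including its seed).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    assignment = _allocate_sites(config, rng)
    by_patient: dict[int, list[tuple[int, str]]] = {}
    for global_idx, (p, code) in enumerate(assignment):
        by_patient.setdefault(p, []).append((global_idx, code))

    sites: list[SiteRecord] = []
    for p in sorted(by_patient):
        entries = by_patient[p]
        codes = [code for _, code in entries]
        centered = _patient_centered_coords(codes, config.coordinate_spread_cm, rng)
        offset = rng.uniform(-3.0, 3.0, 3)
        for (global_idx, code), c in zip(entries, centered):
            scar_intent = rng.random() < config.scar_fraction
            params = _site_params(code, config, rng, scar_intent)
            tissue = tissue_label(true_bipolar_peak_to_peak(params))
            train_seed = int(rng.integers(0, 2**31 - 1))
            ff, bip = synth_pacing_train(
                params,
                config.n_beats,
                config.cycle_length_ms,
                config.sampling_interval_ms,
                seed=train_seed,
            )
            sites.append(
                SiteRecord(
                    patient_id=f"p{p:02d}",
                    site_id=f"p{p:02d}s{global_idx:03d}",
                    coords=c + offset,
                    octant=OctantLabel.from_code(code),
                    tissue=tissue,
                    far_field=ff,
                    bipolar=bip,
                    truth=params,
                )
            )
    # generator self-check: stored labels match the regionalization round trip
    for p in sorted(by_patient):
        patient_sites = [s for s in sites if s.patient_id == f"p{p:02d}"]
        rec = recenter(np.stack([s.coords for s in patient_sites]))
        for s, c in zip(patient_sites, rec):
            if assign_octant(c).code != s.octant.code:
                raise RuntimeError("generated octant label inconsistent with geometry")
    return sites
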