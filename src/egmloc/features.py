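"""Deflection feature extraction from two-lead beat templates.

From the far-field template: the peak deflection ``v_P`` (highest voltage
above the baseline, which is zero after baseline removal), the initial
deflection ``v_I`` (smallest voltage between the far-field onset and the
peak), and the final deflection ``v_F`` (smallest voltage within 170 ms
after the peak instant). From the bipolar template: the intrinsic
deflection (steepest downslope), giving the onset-to-intrinsic lag
``t_ob``. Feature times are referenced to the mid-time between the
previous and current peak deflections.

Two detection rules are conventions of this package (the feature names are
standard, their operational definitions are not): the far-field onset is
the earliest instant before the peak at which |v| exceeds 10% of v_P for
at least three consecutive samples, and the bipolar intrinsic deflection
is the most negative first difference. Ties in min/max searches resolve to
the earliest sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .preprocess import BeatTemplate, concatenate_far_bip

__all__ = [
    "DeflectionFeatures",
    "FeatureSetId",
    "FEATURE_SET_DIMS",
    "SCALAR_FEATURE_NAMES",
    "V_F_SEARCH_MS",
    "detect_onset",
    "detect_intrinsic_deflection",
    "extract_features",
    "assemble",
    "ZScoreStats",
    "zscore_fit",
    "zscore_apply",
]

#: Post-peak search interval for the final deflection (ms).
V_F_SEARCH_MS = 170.0

#: Column order of the scalar feature table.
SCALAR_FEATURE_NAMES = ("v_I", "v_P", "v_F", "v_IP", "v_FP", "t_I", "t_P", "t_F", "t_ob")


class FeatureSetId(str, Enum):
    """Input spaces: raw-waveform sets (D1) and scalar-feature sets (D2)."""

    D1_FF_STIM = "D1_FF_STIM"
    D1_FF_NOSTIM = "D1_FF_NOSTIM"
    D1_BIP_STIM = "D1_BIP_STIM"
    D1_CONCAT_STIM = "D1_CONCAT_STIM"
    F_3V = "3V"
    F_3V1T = "3V1T"
    F_3V3T = "3V3T"
    F_2VR1T = "2VR1T"


FEATURE_SET_DIMS = {
    FeatureSetId.D1_FF_STIM: 150,
    FeatureSetId.D1_FF_NOSTIM: 150,
    FeatureSetId.D1_BIP_STIM: 150,
    FeatureSetId.D1_CONCAT_STIM: 300,
    FeatureSetId.F_3V: 3,
    FeatureSetId.F_3V1T: 4,
    FeatureSetId.F_3V3T: 6,
    FeatureSetId.F_2VR1T: 3,
}


@dataclass(frozen=True)
class DeflectionFeatures:
    """Scalar deflection features of one pacing site.

    Voltages in mV, times in ms relative to the template's time origin
    (mid-time between previous and current peak deflections); ``t_ob`` is
    origin-free (a lag).
    """

    v_I: float
    v_P: float
    v_F: float
    v_IP: float
    v_FP: float
    t_I: float
    t_P: float
    t_F: float
    t_ob: float
    t_onset: float
    t_id: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SCALAR_FEATURE_NAMES}


def _require_no_stimulus(template: BeatTemplate) -> None:
    if template.with_stimulus:
        raise ValueError("template must be stimulus-removed before feature extraction")


def detect_onset(
    ff: BeatTemplate, fraction: float = 0.1, persistence: int = 3
) -> float:
    """Far-field onset time (ms relative to the window start).

    Earliest sample before the peak at which |v| exceeds ``fraction`` of
    |v_P| and stays above for ``persistence`` consecutive samples. The
    threshold is relative, so the result is invariant to positive
    rescaling of the template.
    """
    _require_no_stimulus(ff)
    v = ff.samples
    i_peak = int(np.argmax(v))
    v_peak = float(v[i_peak])
    if v_peak <= 0:
        raise ValueError("template has no positive peak deflection")
    thr = fraction * abs(v_peak)
    above = np.abs(v) > thr
    for i in range(i_peak + 1):
        window = above[i : min(i + persistence, above.size)]
        if window.size and window.all():
            return i * ff.sampling_interval_ms
    raise ValueError("no onset crossing before the peak deflection")


def detect_intrinsic_deflection(bip: BeatTemplate) -> float:
    """Bipolar intrinsic-deflection time (ms relative to the window start).

    The instant of the most negative first difference (steepest
    downslope), placed at the midpoint of the steepest sample pair.
    """
    _require_no_stimulus(bip)
    d = np.diff(bip.samples)
    if d.size == 0 or float(d.min()) >= 0:
        raise ValueError("bipolar template has no negative slope")
    i = int(np.argmin(d))
    return (i + 0.5) * bip.sampling_interval_ms


def extract_features(
    ff: BeatTemplate, bip: BeatTemplate, search_ms: float = V_F_SEARCH_MS
) -> DeflectionFeatures:
    """Compute the scalar deflection features from both templates.

    Both templates must be baseline- and stimulus-removed and share their
    time base. Raises if the peak voltage is zero (ratios undefined) or if
    the post-peak search interval does not fit inside the template.
    """
    _require_no_stimulus(ff)
    _require_no_stimulus(bip)
    dt = ff.sampling_interval_ms
    v = ff.samples
    i_peak = int(np.argmax(v))
    v_P = float(v[i_peak])
    if v_P == 0:
        raise ValueError("zero peak voltage: deflection ratios undefined")
    t_onset = detect_onset(ff)
    i_onset = int(round(t_onset / dt))
    seg = v[i_onset : i_peak + 1]
    i_I = i_onset + int(np.argmin(seg))
    v_I = float(v[i_I])
    i_end = i_peak + int(np.floor(search_ms / dt + 1e-9))
    if i_end > v.size - 1:
        raise ValueError("post-peak search interval exceeds the template window")
    if i_peak + 1 > i_end:
        raise ValueError("empty post-peak search interval")
    post = v[i_peak + 1 : i_end + 1]
    i_F = i_peak + 1 + int(np.argmin(post))
    v_F = float(v[i_F])
    t_id = detect_intrinsic_deflection(bip)
    origin = ff.time_origin_ms
    return DeflectionFeatures(
        v_I=v_I,
        v_P=v_P,
        v_F=v_F,
        v_IP=v_I / v_P,
        v_FP=v_F / v_P,
        t_I=i_I * dt - origin,
        t_P=i_peak * dt - origin,
        t_F=i_F * dt - origin,
        t_ob=t_id - t_onset,
        t_onset=t_onset - origin,
        t_id=t_id - origin,
    )


def assemble(
    set_id: FeatureSetId | str,
    features: DeflectionFeatures | None = None,
    ff: BeatTemplate | None = None,
    bip: BeatTemplate | None = None,
) -> np.ndarray:
    """Build the input vector for one feature set.

    D1 sets take raw template samples (``ff`` with stimulus for
    D1_FF_STIM, without for D1_FF_NOSTIM; ``bip`` with stimulus for
    D1_BIP_STIM; far-field followed by bipolar for D1_CONCAT_STIM). D2
    sets take the scalar features in their documented order.
    """
    set_id = FeatureSetId(set_id)
    if set_id in (FeatureSetId.D1_FF_STIM, FeatureSetId.D1_FF_NOSTIM):
        if ff is None:
            raise ValueError(f"{set_id.value} requires the far-field template")
        if set_id is FeatureSetId.D1_FF_STIM and not ff.with_stimulus:
            raise ValueError("D1_FF_STIM requires the template with its stimulus")
        if set_id is FeatureSetId.D1_FF_NOSTIM and ff.with_stimulus:
            raise ValueError("D1_FF_NOSTIM requires the stimulus-removed template")
        return np.asarray(ff.samples, dtype=float).copy()
    if set_id is FeatureSetId.D1_BIP_STIM:
        if bip is None:
            raise ValueError("D1_BIP_STIM requires the bipolar template")
        return np.asarray(bip.samples, dtype=float).copy()
    if set_id is FeatureSetId.D1_CONCAT_STIM:
        if ff is None or bip is None:
            raise ValueError("D1_CONCAT_STIM requires both templates")
        return concatenate_far_bip(ff, bip)
    if features is None:
        raise ValueError(f"{set_id.value} requires extracted features")
    f = features
    order = {
        FeatureSetId.F_3V: (f.v_I, f.v_P, f.v_F),
        FeatureSetId.F_3V1T: (f.v_I, f.v_P, f.v_F, f.t_ob),
        FeatureSetId.F_3V3T: (f.v_I, f.v_P, f.v_F, f.t_I, f.t_P, f.t_F),
        FeatureSetId.F_2VR1T: (f.v_FP, f.v_IP, f.t_ob),
    }
    return np.array(order[set_id], dtype=float)


@dataclass(frozen=True)
class ZScoreStats:
    """Per-dimension training mean and standard deviation."""

    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray  # boolean mask of constant training columns


def zscore_fit(train: np.ndarray) -> ZScoreStats:
    """Learn zero-mean/unit-sd normalization statistics from training rows.

    Constant columns are flagged; they map to zero under
    :func:`zscore_apply` (with a warning here, once, at fit time).
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("z-score fitting needs a 2-D matrix with at least two rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)  # population sd: column {1, 3} has sd 1
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature column(s) mapped to 0",
            stacklevel=2,
        )
    return ZScoreStats(mean=mean, sd=np.where(zero, 1.0, sd), zero_variance=zero)


def zscore_apply(stats: ZScoreStats, X: np.ndarray) -> np.ndarray:
    """Apply training normalization statistics to a matrix."""
    X = np.asarray(X, dtype=float)
    one_row = X.ndim == 1
    if one_row:
        X = X[None, :]
    if X.shape[1] != stats.mean.size:
        raise ValueError("feature dimension does not match the fitted statistics")
    Z = (X - stats.mean) / stats.sd
    Z[:, stats.zero_variance] = 0.0
    return Z[0] if one_row else Z
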