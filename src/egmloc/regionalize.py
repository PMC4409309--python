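"""Left-ventricle regionalization: halves, octants, and tissue labels.

The LV is split by three mutually perpendicular planes into two halves per
plane (apical/basal, septal/lateral, superior/inferior); the plane
intersection yields eight octants. Navigation-system coordinates are
patient-relative, so each patient's site cloud is recentered on its mean
before any plane test.

Default axis semantics (configurable through :class:`PlaneDivision`):

* x: septal (-) / lateral (+)
* y: inferior (-) / superior (+)
* z: apical (-) / basal (+)

Points exactly on a plane are assigned to the positive-side half, so the
partition into octants is total and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OCTANT_CODES",
    "OctantLabel",
    "PlaneDivision",
    "recenter",
    "assign_halves",
    "halves_to_octant",
    "assign_octant",
    "tissue_label",
    "SCAR_THRESHOLD_MV",
]

#: Bipolar peak-to-peak voltage below which myocardium is labeled scar (mV).
SCAR_THRESHOLD_MV = 1.5

#: Canonical octant ordering (apical before basal, septal before lateral,
#: superior before inferior within each pair is not imposed; this is the
#: conventional listing order).
OCTANT_CODES = ("ASI", "ASS", "ALI", "ALS", "BSI", "BSS", "BLI", "BLS")

_AB = {"apical": "A", "basal": "B"}
_SL = {"septal": "S", "lateral": "L"}
_SI = {"superior": "S", "inferior": "I"}
_AB_INV = {v: k for k, v in _AB.items()}
_SL_INV = {v: k for k, v in _SL.items()}
_SI_INV = {v: k for k, v in _SI.items()}


@dataclass(frozen=True)
class OctantLabel:
    """One of the eight LV octants, as three half labels plus its code."""

    axis_ab: str
    axis_sl: str
    axis_si: str

    def __post_init__(self) -> None:
        if self.axis_ab not in _AB or self.axis_sl not in _SL or self.axis_si not in _SI:
            raise ValueError(
                f"invalid axis values ({self.axis_ab}, {self.axis_sl}, {self.axis_si})"
            )

    @property
    def code(self) -> str:
        return _AB[self.axis_ab] + _SL[self.axis_sl] + _SI[self.axis_si]

    @classmethod
    def from_code(cls, code: str) -> "OctantLabel":
        if len(code) != 3 or code not in OCTANT_CODES:
            raise ValueError(f"unknown octant code {code!r}")
        return cls(_AB_INV[code[0]], _SL_INV[code[1]], _SI_INV[code[2]])


def _default_normals() -> np.ndarray:
    # rows: apical/basal, septal/lateral, superior/inferior axes
    return np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class PlaneDivision:
    """Three perpendicular planes (point + unit normal each).

    The positive side of each plane carries the labels basal, lateral and
    superior respectively; the default is axis-aligned through the origin
    of the recentered patient frame.
    """

    points: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    normals: np.ndarray = field(default_factory=_default_normals)

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        normals = np.asarray(self.normals, dtype=float)
        if points.shape != (3, 3) or normals.shape != (3, 3):
            raise ValueError("points and normals must each be 3x3 arrays")
        norms = np.linalg.norm(normals, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length plane normal")
        normals = normals / norms[:, None]
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(float(normals[i] @ normals[j])) >= 1e-9:
                    raise ValueError("plane normals must be mutually orthogonal")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "normals", normals)


def recenter(coords: np.ndarray) -> np.ndarray:
    """Subtract the mean vector from one patient's site coordinates.

    Navigation-system frames differ between patients; subtracting each
    patient's mean site sets a common zero reference. Pairwise distances
    are preserved exactly.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[None, :]
    if coords.size == 0:
        raise ValueError("recenter requires at least one site")
    if coords.shape[1] != 3:
        raise ValueError("coordinates must have three columns")
    return coords - coords.mean(axis=0)


def assign_halves(coord, division: PlaneDivision | None = None) -> tuple[str, str, str]:
    """Assign a recentered coordinate to one half per dividing plane.

    Returns ``(axis_ab, axis_sl, axis_si)``; a signed distance of exactly
    zero goes to the positive-side label (basal, lateral, superior).
    """
    division = division or PlaneDivision()
    coord = np.asarray(coord, dtype=float)
    if coord.shape != (3,):
        raise ValueError("coord must be a 3-vector")
    if not np.all(np.isfinite(coord)):
        raise ValueError("non-finite coordinate")
    signed = np.einsum("ij,ij->i", coord[None, :] - division.points, division.normals)
    ab = "basal" if signed[0] >= 0 else "apical"
    sl = "lateral" if signed[1] >= 0 else "septal"
    si = "superior" if signed[2] >= 0 else "inferior"
    return ab, sl, si


def halves_to_octant(axis_ab: str, axis_sl: str, axis_si: str) -> OctantLabel:
    """Combine three half labels into the unique octant label."""
    return OctantLabel(axis_ab, axis_sl, axis_si)


def assign_octant(coord, division: PlaneDivision | None = None) -> OctantLabel:
    """Octant of a recentered coordinate under a plane division."""
    return halves_to_octant(*assign_halves(coord, division))


def tissue_label(bipolar_peak_to_peak_mv: float) -> str:
    """Label pacing-site tissue from bipolar peak-to-peak voltage.

    Scar iff the value is below 1.5 mV; ``normal`` at or above it.
    """
    v = float(bipolar_peak_to_peak_mv)
    if not np.isfinite(v) or v < 0:
        raise ValueError("peak-to-peak voltage must be finite and non-negative")
    return "scar" if v < SCAR_THRESHOLD_MV else "normal"
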