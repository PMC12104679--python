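"""Leaf-temperature stress indices.

Vapor pressures follow the Tetens form (kPa, temperatures in degC); the two
crop-water-stress-index variants normalise the leaf (or leaf-air) temperature
between the session's wet and dry references; LTD is the control-mean leaf
temperature minus an individual seedling's leaf temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SessionReferences",
    "ThermalObservation",
    "lvp",
    "avp",
    "vpd",
    "session_references",
    "cwsi_tl",
    "cwsi_tlta",
    "ltd",
    "tl_from_map",
]

#: Tetens coefficients (kPa / dimensionless / degC).
TETENS_A = 0.61078
TETENS_B = 17.27
TETENS_C = 237.3


class DegenerateReferenceError(ValueError):
    """Raised when session references collapse (zero normalising span)."""


@dataclass(frozen=True)
class SessionReferences:
    """Wet/dry leaf and air temperature anchors for one capture session."""

    Tlw: float  # minimum leaf temperature, degC
    Tld: float  # maximum leaf temperature, degC
    Taw: float  # minimum air temperature, degC
    Tad: float  # maximum air temperature, degC
    scope: str = ""

    def __post_init__(self) -> None:
        if not (self.Tlw <= self.Tld and self.Taw <= self.Tad):
            raise ValueError("references must satisfy Tlw <= Tld and Taw <= Tad")


@dataclass
class ThermalObservation:
    """Per-seedling thermal record with derived indices."""

    seedling_id: str
    session: str
    treatment: str
    Tl: float
    Ta: float
    AH: float
    LVP: float = np.nan
    AVP: float = np.nan
    VPD: float = np.nan
    CWSI_Tl: float = np.nan
    CWSI_TlTa: float = np.nan
    LTD: float = np.nan


def lvp(Tl):
    """Saturation (leaf) vapor pressure in kPa at leaf temperature ``Tl`` degC."""
    Tl = np.asarray(Tl, dtype=float)
    if np.any(Tl <= -TETENS_C):
        raise ValueError(f"leaf temperature must exceed {-TETENS_C} degC")
    out = TETENS_A * np.exp(TETENS_B * Tl / (Tl + TETENS_C))
    return float(out) if out.ndim == 0 else out


def avp(Ta, AH):
    """Actual air vapor pressure in kPa: saturation at ``Ta`` scaled by ``AH``/100."""
    AH = np.asarray(AH, dtype=float)
    if np.any((AH < 0) | (AH > 100)):
        raise ValueError("relative humidity must lie in [0, 100] percent")
    out = lvp(Ta) * (AH / 100.0)
    return float(out) if np.ndim(out) == 0 else out


def vpd(Tl, Ta, AH):
    """Vapor pressure deficit in kPa (leaf saturation minus actual air pressure)."""
    return lvp(Tl) - avp(Ta, AH)


def session_references(
    leaf_temps: Sequence[float], air_temps: Sequence[float], scope: str = ""
) -> SessionReferences:
    """Componentwise min/max anchors over one session's pooled observations.

    Raises
    ------
    DegenerateReferenceError
        If fewer than two leaf observations are available or all leaf
        temperatures coincide (the CWSI denominator would vanish).
    """
    tl = np.asarray(leaf_temps, dtype=float)
    ta = np.asarray(air_temps, dtype=float)
    if tl.size < 2:
        raise DegenerateReferenceError("need at least two leaf observations per session")
    refs = SessionReferences(
        Tlw=float(tl.min()), Tld=float(tl.max()),
        Taw=float(ta.min()), Tad=float(ta.max()),
        scope=scope,
    )
    if refs.Tld == refs.Tlw:
        raise DegenerateReferenceError("constant leaf temperatures: CWSI undefined")
    return refs


def cwsi_tl(Tl, refs: SessionReferences):
    """CWSI from leaf temperature only: (Tl - Tlw) / (Tld - Tlw)."""
    span = refs.Tld - refs.Tlw
    if span == 0:
        raise DegenerateReferenceError("Tld == Tlw: CWSI(Tl) undefined")
    out = (np.asarray(Tl, dtype=float) - refs.Tlw) / span
    return float(out) if out.ndim == 0 else out


def cwsi_tlta(Tl, Ta, refs: SessionReferences):
    """CWSI from the leaf-air difference, normalised between its wet/dry anchors."""
    lo = refs.Tlw - refs.Taw
    hi = refs.Tld - refs.Tad
    span = hi - lo
    if span == 0:
        raise DegenerateReferenceError("(Tld-Tad) == (Tlw-Taw): CWSI(Tl-Ta) undefined")
    d = np.asarray(Tl, dtype=float) - np.asarray(Ta, dtype=float)
    out = (d - lo) / span
    return float(out) if np.ndim(out) == 0 else out


def ltd(control_Tl: Sequence[float], Tl_i):
    """Leaf temperature difference: mean control Tl minus the seedling's Tl.

    Computed for every seedling including controls, so the control-group LTD
    averages to exactly zero within a session.  Negative values mean foliage
    warmer than the control average (stress).
    """
    ctl = np.asarray(control_Tl, dtype=float)
    if ctl.size == 0:
        raise ValueError("LTD requires at least one control observation in the session")
    out = ctl.mean() - np.asarray(Tl_i, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def tl_from_map(thermal_map: np.ndarray, mask: np.ndarray) -> float:
    """Mean leaf temperature over a seedling's labeled region of a thermal map.

    NaN pixels (dead sensor elements) are excluded from the mean.
    """
    thermal_map = np.asarray(thermal_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if thermal_map.shape != mask.shape:
        raise ValueError("thermal map and mask shapes differ")
    vals = thermal_map[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no valid thermal pixels under the region mask")
    return float(vals.mean())
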