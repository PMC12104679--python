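"""Needle-angle measurement, quadrant averaging, binning and vitality tracking.

The needle angle theta is the signed interior angle (in [-90, +90] degrees)
between the horizontal and the base-to-tip vector of a needle, positive when
the tip sits above the base in plant coordinates (smaller image row).  Apical
angles are averaged per quadrant and then across non-empty quadrants.

Difference parameters are oriented so that positive values mean the needles
dropped relative to the reference (wilting) and negative values mean they rose
(recovery).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NeedleAngleObservation",
    "AngleParameterSet",
    "VitalityState",
    "needle_angle",
    "quadrant_mean",
    "stx_bin",
    "derive_parameters",
    "sufficient_sample_sessions",
    "classify_vitality",
    "STX_BINS",
    "SURVIVAL",
    "RECOVERY",
    "DEAD",
]

log = logging.getLogger(__name__)

SURVIVAL = "○"  # open circle: survival
RECOVERY = "△"  # open triangle: recovery the morning after first wilting
DEAD = "X"  # completely died

#: Left-closed 30-degree bins over [-90, +90]; the last bin includes +90.
STX_BINS = {
    "ST1": (-90.0, -60.0),
    "ST2": (-60.0, -30.0),
    "ST3": (-30.0, 0.0),
    "ST4": (0.0, 30.0),
    "ST5": (30.0, 60.0),
    "ST6": (60.0, 90.0),
}


@dataclass
class NeedleAngleObservation:
    seedling_id: str
    day: int
    session: str
    quadrant_angles: dict = field(default_factory=dict)  # quadrant -> mean deg
    theta: float = math.nan
    n_needles_measured: int = 0
    measurable: bool = True


@dataclass
class AngleParameterSet:
    seedling_id: str
    session: str
    stx_bin: str | None = None
    bd_m: float = math.nan
    pm_m: float = math.nan
    pm_m_st: float = math.nan


@dataclass
class VitalityState:
    seedling_id: str
    states: dict = field(default_factory=dict)  # session -> SURVIVAL/RECOVERY/DEAD
    first_wilt_session: str | None = None
    death_session: str | None = None


def needle_angle(base: Sequence[float], tip: Sequence[float]) -> float:
    """Signed needle angle in degrees from base and tip (col, row) coordinates.

    The horizontal run enters unsigned so the result is the interior angle with
    the horizontal regardless of which way the needle points; the sign comes
    from the vertical rise alone (image rows grow downward, so a tip at a
    smaller row than the base is *above* it and yields a positive angle).
    """
    bc, br = float(base[0]), float(base[1])
    tc, tr = float(tip[0]), float(tip[1])
    if bc == tc and br == tr:
        raise ValueError("needle base and tip coincide: angle undefined")
    rise = br - tr
    run = abs(tc - bc)
    theta = math.degrees(math.atan2(rise, run))
    return max(-90.0, min(90.0, theta))


def quadrant_mean(
    needles: Iterable[tuple[int, float]],
    seedling_id: str = "",
    day: int = -1,
    session: str = "",
) -> NeedleAngleObservation:
    """Average needle angles per quadrant, then across non-empty quadrants.

    ``needles`` yields ``(quadrant, angle_deg)`` pairs with quadrant in 1..4.
    Quadrant means are unweighted, as is the final mean over quadrant means.
    """
    per_quadrant: dict[int, list[float]] = {}
    n = 0
    for quadrant, angle in needles:
        if not 1 <= int(quadrant) <= 4:
            raise ValueError(f"quadrant must be 1..4, got {quadrant}")
        per_quadrant.setdefault(int(quadrant), []).append(float(angle))
        n += 1
    obs = NeedleAngleObservation(
        seedling_id=seedling_id, day=day, session=session, n_needles_measured=n
    )
    if n == 0:
        obs.measurable = False
        return obs
    obs.quadrant_angles = {q: float(np.mean(v)) for q, v in sorted(per_quadrant.items())}
    obs.theta = float(np.mean(list(obs.quadrant_angles.values())))
    return obs


def stx_bin(theta: float) -> str:
    """Map an angle to its STx bin; bins are left-closed, ST6 closed at +90."""
    t = float(theta)
    if not -90.0 <= t <= 90.0:
        raise ValueError(f"theta must lie in [-90, 90], got {t}")
    if t == 90.0:
        return "ST6"
    idx = int((t + 90.0) // 30.0)
    return f"ST{idx + 1}"


def sufficient_sample_sessions(
    needle_counts: Mapping[str, int], min_values: int = 30
) -> list[str]:
    """Sessions that keep at least ``min_values`` measurable needle-angle
    values in the drought group (the continuation rule for the daily
    analysis); returns the session labels that satisfy the guard."""
    return [s for s, n in needle_counts.items() if n >= min_values]


def _theta_map(observations: Sequence[NeedleAngleObservation]) -> dict[str, float]:
    return {
        o.session: o.theta
        for o in observations
        if o.measurable and not math.isnan(o.theta)
    }


def derive_parameters(
    observations: Sequence[NeedleAngleObservation],
    session_order: Sequence[str],
    bd_session: str = "BD",
) -> list[AngleParameterSet]:
    """Per-session difference parameters from a seedling's ordered theta series.

    * ``bd_m``: theta at the pre-drought session minus current theta.
    * ``pm_m``: theta at the immediately preceding session minus current theta.
    * ``pm_m_st``: theta at the previous day's same session type minus current.

    Missing or unmeasurable reference sessions leave the parameter NaN (logged).
    """
    theta = _theta_map(observations)
    sid = observations[0].seedling_id if observations else ""
    order = list(session_order)
    out: list[AngleParameterSet] = []
    for i, ses in enumerate(order):
        if ses not in theta:
            continue
        cur = theta[ses]
        ps = AngleParameterSet(seedling_id=sid, session=ses, stx_bin=stx_bin(cur))
        if bd_session in theta:
            ps.bd_m = theta[bd_session] - cur
        else:
            log.debug("bd_m undefined for %s at %s: no %s", sid, ses, bd_session)
        prev = next((s for s in reversed(order[:i]) if s in theta), None)
        if prev is not None:
            ps.pm_m = theta[prev] - cur
        same_type = [
            s for s in order[:i] if s in theta and s[-1:] == ses[-1:] and s != bd_session
        ]
        if same_type:
            ps.pm_m_st = theta[same_type[-1]] - cur
        out.append(ps)
    return out


def classify_vitality(
    theta_series: Mapping[str, Mapping[str, float]],
    discoloration_series: Mapping[str, Mapping[str, float]],
    session_order: Sequence[str],
    bd_session: str = "BD",
    wilt_drop_min: float = 15.0,
    dead_frac: float = 0.8,
) -> tuple[dict[str, VitalityState], pd.DataFrame]:
    """Per-seedling vitality states plus the per-session percentage tally.

    ``theta_series`` maps seedling id -> {session: theta}; sessions with an
    unmeasurable apical part should be absent (they are excluded from the
    tally denominator for that session).  A seedling wilts when its drop from
    the pre-drought angle reaches ``wilt_drop_min`` degrees; it is tagged as a
    recovery only on the morning immediately after its first wilt if the drop
    has receded; death (absorbing) is declared once the discoloration fraction
    reaches ``dead_frac``.
    """
    order = list(session_order)
    states: dict[str, VitalityState] = {}
    for sid, thetas in theta_series.items():
        disc = discoloration_series.get(sid, {})
        vs = VitalityState(seedling_id=sid)
        baseline = thetas.get(bd_session)
        dead = False
        wilted_prev = False
        for ses in order:
            if ses == bd_session:
                continue
            if dead or disc.get(ses, 0.0) >= dead_frac:
                if not dead:
                    vs.death_session = ses
                    dead = True
                vs.states[ses] = DEAD
                continue
            th = thetas.get(ses)
            if th is None:
                wilted_prev = False
                continue  # apical part unmeasurable this session
            wilted_now = baseline is not None and (baseline - th) >= wilt_drop_min
            if wilted_now and vs.first_wilt_session is None:
                vs.first_wilt_session = ses
                vs.states[ses] = SURVIVAL
            elif (
                not wilted_now
                and wilted_prev
                and ses.endswith("M")
                and vs.first_wilt_session is not None
                and order.index(vs.first_wilt_session) == order.index(ses) - 1
            ):
                vs.states[ses] = RECOVERY
            else:
                vs.states[ses] = SURVIVAL
            wilted_prev = wilted_now
        states[sid] = vs

    rows = []
    for ses in order:
        if ses == bd_session:
            continue
        labels = [vs.states[ses] for vs in states.values() if ses in vs.states]
        n = len(labels)
        rows.append(
            {
                "session": ses,
                "n": n,
                SURVIVAL: 100.0 * labels.count(SURVIVAL) / n if n else math.nan,
                RECOVERY: 100.0 * labels.count(RECOVERY) / n if n else math.nan,
                DEAD: 100.0 * labels.count(DEAD) / n if n else math.nan,
            }
        )
    return states, pd.DataFrame(rows)
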