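"""Seeded synthetic drought-stress experiments.

Generates everything the downstream analysis consumes: time-lapse scene
frames (four potted seedlings plus a color chart per frame), matching
single-channel thermal maps, environment and physiology tables, per-needle
apical angle annotations, ground-truth geometry and per-plant ground-truth
pixel masks.

The scenario: two treatments observed over morning/evening sessions; drought
seedlings start wilting in the evenings from a configurable onset session,
a configurable fraction recover the following morning, and wilted seedlings
die within one to two days, discoloring progressively afterwards.  A late
physiological response (quenching rise, leaf-temperature departure) switches
on at a separate configurable session.

Coordinates follow image convention: origin top-left, x = column, y = row,
y increasing downward.  All randomness flows from one seed through
``numpy.random.SeedSequence`` sub-streams (one per seedling, frame and table)
so identical seed + config reproduce bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line

from .colormask import Rect, SceneImage

__all__ = [
    "ExperimentConfig",
    "SeedlingState",
    "SimulationResult",
    "ConfigError",
    "session_labels",
    "session_day",
    "session_period",
    "angle_trajectory",
    "simulate_experiment",
    "REFERENCE_CHART",
    "SURVIVAL",
    "WILTED",
    "RECOVERED",
    "DEAD",
]

SURVIVAL = "survival"
WILTED = "wilted"
RECOVERED = "recovered"
DEAD = "dead"

#: 24 reference chart colors (a coarse tonal/chromatic spread, rows x cols = 4 x 6).
REFERENCE_CHART = np.array(
    [
        [115, 82, 68], [194, 150, 130], [98, 122, 157], [87, 108, 67],
        [133, 128, 177], [103, 189, 170], [214, 126, 44], [80, 91, 166],
        [193, 90, 99], [94, 60, 108], [157, 188, 64], [224, 163, 46],
        [56, 61, 150], [70, 148, 73], [175, 54, 60], [231, 199, 31],
        [187, 86, 149], [8, 133, 161], [243, 243, 242], [200, 200, 200],
        [160, 160, 160], [122, 122, 121], [85, 85, 85], [52, 52, 52],
    ],
    dtype=float,
)

_GREEN_NEEDLE = np.array([40, 170, 60], dtype=float)
_GREEN_STEM = np.array([60, 150, 55], dtype=float)
_BROWN_DEAD = np.array([120, 90, 40], dtype=float)
_BACKGROUND = np.array([8, 8, 8], dtype=float)


class ConfigError(ValueError):
    """Invalid experiment configuration."""


def session_labels(n_days: int) -> list[str]:
    """Session sequence: one pre-drought session, then M/E pairs per day."""
    if n_days < 1:
        raise ConfigError("n_days must be >= 1")
    labels = ["BD"]
    for d in range(1, n_days):
        labels += [f"D{d}M", f"D{d}E"]
    return labels


def session_day(label: str) -> int:
    return 0 if label == "BD" else int(label[1:-1])


def session_period(label: str) -> str:
    return "M" if label == "BD" else label[-1]


@dataclass
class ExperimentConfig:
    """Scenario constants for one synthetic experiment."""

    n_seedlings_per_treatment: int = 10
    n_days: int = 7  # BD plus days 1..n_days-1, two sessions per day
    baseline_angle_mean: float = 30.0
    baseline_angle_sd: float = 8.0
    session_noise_sd: float = 2.0
    wilt_onset_session: str = "D2E"
    wilt_drop_mean: float = 17.0  # degrees, positive = downward
    wilt_drop_sd: float = 4.0
    recovery_fraction: float = 0.7
    days_to_death_after_first_wilt: tuple = (1, 2)
    discoloration_rate: float = 0.5  # fraction per day once death begins
    env_means: dict = field(
        default_factory=lambda: {
            "AH": 79.13, "AT": 30.46, "SR": 194.32, "SM": 29.48, "ST": 29.55,
            "EC": 0.115,
        }
    )
    env_sds: dict = field(
        default_factory=lambda: {
            "AH": 13.88, "AT": 4.72, "SR": 233.92, "SM": 1.22, "ST": 4.06,
            "EC": 0.01,
        }
    )
    drought_sm_final: float = 8.0  # soil moisture floor reached by the last day
    physio_effect_day: str | None = "D6M"
    phi_npq_shift: float = 0.11
    tl_shift: float = 2.0  # degC leaf warming from physio_effect_day
    tl_offset: float = -2.0  # leaf minus air temperature, unstressed
    tl_seedling_sd: float = 0.4
    thermal_noise_sd: float = 0.2  # per-pixel map noise, degC
    image_height: int = 200
    image_width: int = 400
    stem_height_mean: float = 120.0
    stem_height_sd: float = 6.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_seedlings_per_treatment < 1:
            raise ConfigError("n_seedlings_per_treatment must be positive")
        sessions = session_labels(self.n_days)
        if self.wilt_onset_session not in sessions:
            raise ConfigError(
                f"wilt_onset_session {self.wilt_onset_session!r} not in {sessions}"
            )
        if self.physio_effect_day is not None and self.physio_effect_day not in sessions:
            raise ConfigError(f"physio_effect_day {self.physio_effect_day!r} invalid")
        for name in ("baseline_angle_sd", "session_noise_sd", "wilt_drop_sd",
                     "tl_seedling_sd", "thermal_noise_sd", "stem_height_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if any(v < 0 for v in self.env_sds.values()):
            raise ConfigError("environment SDs must be >= 0")
        if not 0.0 <= self.recovery_fraction <= 1.0:
            raise ConfigError("recovery_fraction must lie in [0, 1]")
        lo, hi = self.days_to_death_after_first_wilt
        if not (1 <= lo <= hi):
            raise ConfigError("days_to_death_after_first_wilt must be an increasing range >= 1")

    @property
    def sessions(self) -> list[str]:
        return session_labels(self.n_days)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["days_to_death_after_first_wilt"] = list(self.days_to_death_after_first_wilt)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "days_to_death_after_first_wilt" in d:
            d["days_to_death_after_first_wilt"] = tuple(d["days_to_death_after_first_wilt"])
        return cls(**d)

    @classmethod
    def null_scenario(cls, **overrides) -> "ExperimentConfig":
        """Zero-effect configuration: no wilt, no death, no physiology shift."""
        defaults = dict(
            wilt_drop_mean=0.0, wilt_drop_sd=0.0, physio_effect_day=None,
            phi_npq_shift=0.0, tl_shift=0.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SeedlingState:
    """Mutable per-seedling vitality bookkeeping during simulation."""

    vitality: str = SURVIVAL
    first_wilt_session: str | None = None
    death_session: str | None = None
    will_recover: bool | None = None
    death_delay_days: int | None = None
    discoloration: float = 0.0


def angle_trajectory(
    treatment: str,
    session: str,
    state: SeedlingState,
    config: ExperimentConfig,
    rng: np.random.Generator,
    baseline: float | None = None,
    wilt_drop: float | None = None,
) -> tuple[float, SeedlingState]:
    """One step of the wilt/recover/death state machine.

    Returns the sampled mean apical angle for the session and the advanced
    state.  Control seedlings (and drought seedlings before onset) fluctuate
    around the baseline with session noise only; evening drought samples after
    onset are shifted down by the wilt drop; a recovering seedling returns to
    baseline the morning after its first wilt; dead is absorbing, with
    discoloration accruing at ``config.discoloration_rate`` per day.
    """
    if state.vitality not in {SURVIVAL, WILTED, RECOVERED, DEAD}:
        raise ValueError(f"invalid vitality state {state.vitality!r}")
    cfg = config
    order = cfg.sessions
    if baseline is None:
        baseline = cfg.baseline_angle_mean
    noise = rng.normal(0.0, cfg.session_noise_sd)
    s = SeedlingState(**asdict(state))

    if s.vitality == DEAD:
        s.discoloration = min(1.0, s.discoloration + cfg.discoloration_rate / 2.0)
        return baseline - (wilt_drop if wilt_drop is not None else cfg.wilt_drop_mean), s

    if treatment != "drought" or session == "BD":
        return baseline + noise, s

    idx = order.index(session)
    onset = order.index(cfg.wilt_onset_session)

    # scheduled death: on day first_wilt + delay -- but a recovering seedling
    # still gets its recovery morning before dying (recovered, then died)
    if s.first_wilt_session is not None:
        death_day = session_day(s.first_wilt_session) + (s.death_delay_days or 1)
        day = session_day(session)
        due = day > death_day or (
            day == death_day
            and (session_period(session) == "E" or not s.will_recover)
        )
        if due:
            s.vitality = DEAD
            s.death_session = session
            s.discoloration = min(1.0, s.discoloration + cfg.discoloration_rate / 2.0)
            drop = wilt_drop if wilt_drop is not None else cfg.wilt_drop_mean
            return baseline - drop, s

    is_evening = session_period(session) == "E"
    if s.first_wilt_session is None:
        if is_evening and idx >= onset:
            drop = wilt_drop if wilt_drop is not None else rng.normal(
                cfg.wilt_drop_mean, cfg.wilt_drop_sd
            )
            if drop > 0:
                s.first_wilt_session = session
                s.vitality = WILTED
                if s.will_recover is None:
                    s.will_recover = bool(rng.random() < cfg.recovery_fraction)
                if s.death_delay_days is None:
                    lo, hi = cfg.days_to_death_after_first_wilt
                    s.death_delay_days = int(rng.integers(lo, hi + 1))
                return baseline - drop + noise, s
        return baseline + noise, s

    # after first wilt, before death
    if s.vitality == WILTED and session_period(session) == "M":
        if s.will_recover:
            s.vitality = RECOVERED
            return baseline + noise, s
        return baseline - (wilt_drop if wilt_drop is not None else cfg.wilt_drop_mean) + noise, s
    if is_evening:
        s.vitality = WILTED
        drop = wilt_drop if wilt_drop is not None else rng.normal(
            cfg.wilt_drop_mean, cfg.wilt_drop_sd
        )
        return baseline - drop + noise, s
    return baseline + noise, s


@dataclass
class SimulationResult:
    """All artifacts of one simulated experiment."""

    config: ExperimentConfig
    frames: list  # list[SceneImage], one per (session, frame slot)
    gt_masks: dict  # scene_id -> list of per-ROI boolean ground-truth masks
    thermal_maps: dict  # scene_id -> float32 (rows, cols) degC
    needles: pd.DataFrame  # apical needle endpoint annotations
    env: pd.DataFrame
    physio: pd.DataFrame
    ground_truth: pd.DataFrame


def _draw_marginal(var: str, mu: float, sd: float, size: int, rng) -> np.ndarray:
    """Draw iid values with mean ``mu`` and SD ``sd`` on a physical support.

    Humidity uses a Beta scaled to [0, 100]; radiation a Gamma (positive,
    right-skewed); temperatures a Normal.  Moments are exact, so the series
    mean/SD converge to the configured scenario constants.
    """
    if sd == 0:
        return np.full(size, mu)
    if var == "AH":
        m = mu / 100.0
        v = (sd / 100.0) ** 2
        if v < m * (1 - m):
            nu = m * (1 - m) / v - 1.0
            return 100.0 * rng.beta(m * nu, (1 - m) * nu, size=size)
    if var == "SR":
        k = (mu / sd) ** 2
        return rng.gamma(k, sd**2 / mu, size=size)
    return rng.normal(mu, sd, size=size)


def _apply_diurnal(values: np.ndarray, sessions: list, morning_high: bool) -> np.ndarray:
    """Swap within-day M/E pairs so the larger value lands on the stated period.

    A rank-preserving reordering: the empirical distribution (hence mean/SD)
    is untouched while mornings get the higher humidity/radiation and evenings
    the higher air temperature.
    """
    out = values.copy()
    for i in range(len(sessions) - 1):
        a, b = sessions[i], sessions[i + 1]
        if a.endswith("M") and b.endswith("E") and session_day(a) == session_day(b):
            hi, lo = max(out[i], out[i + 1]), min(out[i], out[i + 1])
            out[i], out[i + 1] = (hi, lo) if morning_high else (lo, hi)
    return out


def _simulate_env(cfg: ExperimentConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    sessions = cfg.sessions
    n_sessions = len(sessions)
    shared_series = {}
    for var in ("AH", "AT", "SR", "ST"):
        vals = _draw_marginal(var, cfg.env_means[var], cfg.env_sds[var], n_sessions, rng)
        if var in ("AH", "SR"):
            vals = _apply_diurnal(vals, sessions, morning_high=True)
        elif var == "AT":
            vals = _apply_diurnal(vals, sessions, morning_high=False)
        shared_series[var] = vals
    for i, ses in enumerate(sessions):
        period = session_period(ses)
        shared = {var: float(shared_series[var][i]) for var in ("AH", "AT", "SR", "ST")}
        for treatment in ("control", "drought"):
            if treatment == "control":
                sm = rng.normal(cfg.env_means["SM"], cfg.env_sds["SM"])
            else:
                frac = i / max(n_sessions - 1, 1)
                sm = cfg.env_means["SM"] + frac * (cfg.drought_sm_final - cfg.env_means["SM"])
                sm += rng.normal(0, cfg.env_sds["SM"])
            ec = rng.normal(cfg.env_means["EC"], cfg.env_sds["EC"])
            rows.append(
                {
                    "session": ses, "day": session_day(ses), "period": period,
                    "treatment": treatment, "AH": shared["AH"], "AT": shared["AT"],
                    "SR": shared["SR"], "SM": float(max(sm, 0.0)),
                    "ST": shared["ST"], "EC": float(max(ec, 1e-4)),
                }
            )
    return pd.DataFrame(rows)


_PHYSIO_DISTS = {
    "SPAD": (17.0, 9.0),
    "Fm_prime": (3900.0, 1100.0),
    "Fo_prime": (1000.0, 270.0),
    "FvFm_prime": (0.73, 0.03),
    "Phi_II": (0.68, 0.03),
    "Phi_NO": (0.18, 0.02),
    "Phi_NPQ": (0.13, 0.04),
    "PSI_act": (2.0, 1.5),
    "PSI_open": (0.6, 0.5),
    "qL": (0.77, 0.07),
}


def _simulate_physio(
    cfg: ExperimentConfig, rng: np.random.Generator, seedlings: pd.DataFrame
) -> pd.DataFrame:
    order = cfg.sessions
    effect_idx = (
        order.index(cfg.physio_effect_day) if cfg.physio_effect_day is not None else None
    )
    # instrument protocol: one midday measurement every second day from day 2
    measured = [
        s for s in order
        if session_day(s) >= 2 and session_day(s) % 2 == 0 and session_period(s) == "M"
    ]
    rows = []
    n_reps = 5  # repeated measurements across different needle bundles
    for _, sdl in seedlings.iterrows():
        for i, ses in enumerate(order):
            if ses not in measured:
                continue
            stressed = (
                effect_idx is not None
                and sdl.treatment == "drought"
                and i >= effect_idx
            )
            # split variance between a seedling-state effect and bundle noise
            state = {
                var: mu + (cfg.phi_npq_shift if stressed and var == "Phi_NPQ" else 0.0)
                - (0.08 if stressed and var == "FvFm_prime" else 0.0)
                + rng.normal(0.0, 0.7 * sd)
                for var, (mu, sd) in _PHYSIO_DISTS.items()
            }
            for rep in range(n_reps):
                row = {
                    "seedling_id": sdl.seedling_id, "treatment": sdl.treatment,
                    "session": ses, "day": session_day(ses),
                    "period": session_period(ses), "replicate": rep + 1,
                }
                for var, (mu, sd) in _PHYSIO_DISTS.items():
                    row[var] = float(state[var] + rng.normal(0.0, 0.7 * sd))
                rows.append(row)
    return pd.DataFrame(rows)


def _draw_segment(img, gt, r0, c0, r1, c1, color, alive, h, w, thick=1):
    """Rasterise a segment with clipping; paint ground truth when alive."""
    rr, cc = draw_line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    for dr in range(thick):
        for dc in range(thick):
            r = np.clip(rr + dr, 0, h - 1)
            c = np.clip(cc + dc, 0, w - 1)
            img[r, c] = color
            if alive:
                gt[r, c] = True


def _render_seedling(
    img: np.ndarray,
    gt: np.ndarray,
    roi: Rect,
    theta: float,
    droop: float,
    wilted: bool,
    stem_height: float,
    discoloration: float,
    dead: bool,
    rng: np.random.Generator,
) -> list[dict]:
    """Draw one seedling inside its ROI; return apical needle annotations.

    Stem: a vertical polyline from the pot line; the apical region is the top
    20% of the stem and bends downward in proportion to ``droop``, the drop of
    the seedling's mean apical angle below its own healthy baseline (degrees).
    Needles are straight segments in whorls; whorl posture sags only once the
    droop clears a small dead zone.  Living tissue is green; dead tissue brown
    (outside the default green mask range).
    """
    h, w = img.shape[:2]
    base_row = roi.r1 - 5
    base_col = (roi.c0 + roi.c1) // 2
    lower_len = 0.6 * stem_height
    mid_len = 0.2 * stem_height
    apical_len = 0.2 * stem_height
    top_row = base_row - lower_len

    needle_len = 12.0
    annotations = []

    def tissue_color(alive_prob_rng):
        if dead or alive_prob_rng.random() < discoloration:
            return _BROWN_DEAD, False
        return _GREEN_NEEDLE + alive_prob_rng.normal(0, 6, size=3), True

    # lower stem (rigid, vertical)
    stem_color = _BROWN_DEAD if dead else _GREEN_STEM
    _draw_segment(img, gt, base_row, base_col, top_row, base_col, stem_color,
                  not dead, h, w, thick=2)

    # lower-canopy needle whorls; posture sags only on wilted/dead seedlings
    # (turgid stems and needles hold their posture against angle noise)
    sag = max(0.0, droop) if wilted else 0.0
    whorl_angle = 40.0 - 0.8 * sag
    whorl_rows = np.arange(base_row - 8, top_row + 4, -7.0)
    for wr in whorl_rows:
        for side in (-1, 1):
            ang = math.radians(whorl_angle + rng.normal(0, 4.0))
            tip_c = base_col + side * needle_len * math.cos(ang)
            tip_r = wr - needle_len * math.sin(ang)
            color, alive = tissue_color(rng)
            _draw_segment(img, gt, wr, base_col, tip_r, tip_c, color, alive, h, w)

    # upper stem bends downward when wilted: the mid segment at half rate,
    # the apical (top 20%) fully -- a wilting leader flops over sideways
    side_sign = 1 if rng.random() < 0.5 else -1
    mid_angle = math.radians(max(-60.0, min(90.0, 90.0 - 3.0 * sag)))
    mid_col = base_col + mid_len * math.cos(mid_angle) * side_sign
    mid_row = top_row - mid_len * math.sin(mid_angle)
    _draw_segment(img, gt, top_row, base_col, mid_row, mid_col, stem_color,
                  not dead, h, w, thick=2)
    apical_angle = math.radians(max(-70.0, min(90.0, 90.0 - 6.0 * sag)))
    tip_col = mid_col + apical_len * math.cos(apical_angle) * side_sign
    tip_row = mid_row - apical_len * math.sin(apical_angle)
    _draw_segment(img, gt, mid_row, mid_col, tip_row, tip_col, stem_color,
                  not dead, h, w, thick=2)

    # apical needles: 2 per quadrant at the requested angle + small jitter,
    # based on the apical segment itself so they stay 8-connected to the stem.
    # Quadrants split at the apical bounding-box center: 1=UL, 2=UR, 3=LL, 4=LR.
    for quadrant in (1, 2, 3, 4):
        upper = quadrant in (1, 2)
        side = -1 if quadrant in (1, 3) else 1
        for k in range(2):
            t = (0.65 if upper else 0.15) + 0.2 * k + rng.uniform(-0.05, 0.05)
            nb_r = mid_row + t * (tip_row - mid_row)
            nb_c = mid_col + t * (tip_col - mid_col)
            ang = math.radians(theta + rng.normal(0, 2.0))
            nt_c = nb_c + side * needle_len * math.cos(ang)
            nt_r = nb_r - needle_len * math.sin(ang)
            color, alive = tissue_color(rng)
            _draw_segment(img, gt, nb_r, nb_c, nt_r, nt_c, color, alive, h, w)
            annotations.append(
                {
                    "quadrant": quadrant,
                    "base_col": float(nb_c), "base_row": float(nb_r),
                    "tip_col": float(nt_c), "tip_row": float(nt_r),
                }
            )
    return annotations


def _frame_geometry(cfg: ExperimentConfig) -> tuple[Rect, list[Rect]]:
    chart = Rect(0, 0, 40, 60)
    w = cfg.image_width
    roi_w = (w - 80) // 4
    rois = [
        Rect(45, 80 + i * roi_w, cfg.image_height - 2, 80 + (i + 1) * roi_w - 4)
        for i in range(4)
    ]
    return chart, rois


def _render_chart(img: np.ndarray, chart: Rect) -> None:
    nr, nc = 4, 6
    h = chart.r1 - chart.r0
    w = chart.c1 - chart.c0
    for i in range(nr):
        for j in range(nc):
            r0 = chart.r0 + round(i * h / nr)
            r1 = chart.r0 + round((i + 1) * h / nr)
            c0 = chart.c0 + round(j * w / nc)
            c1 = chart.c0 + round((j + 1) * w / nc)
            img[r0:r1, c0:c1] = REFERENCE_CHART[i * nc + j]


def simulate_experiment(config: ExperimentConfig) -> SimulationResult:
    """Run the full generator; see the module docstring for the scenario."""
    cfg = config
    cfg.validate()
    root = np.random.SeedSequence(cfg.rng_seed)
    ss_env, ss_physio, ss_seedlings, ss_frames = root.spawn(4)

    n = cfg.n_seedlings_per_treatment
    seedlings = pd.DataFrame(
        [
            {"seedling_id": f"{t[0].upper()}{i + 1:02d}", "treatment": t, "index": i}
            for t in ("control", "drought")
            for i in range(n)
        ]
    )

    env = _simulate_env(cfg, np.random.default_rng(ss_env))
    physio = _simulate_physio(cfg, np.random.default_rng(ss_physio), seedlings)

    # per-seedling trajectories
    seedling_rngs = {
        sid: np.random.default_rng(ss)
        for sid, ss in zip(seedlings.seedling_id, ss_seedlings.spawn(len(seedlings)))
    }
    order = cfg.sessions
    at_by_session = env.drop_duplicates("session").set_index("session")["AT"]
    gt_rows = []
    per_seedling_session: dict[tuple[str, str], dict] = {}
    for _, sdl in seedlings.iterrows():
        rng = seedling_rngs[sdl.seedling_id]
        baseline = rng.normal(cfg.baseline_angle_mean, cfg.baseline_angle_sd)
        stem_h = max(40.0, rng.normal(cfg.stem_height_mean, cfg.stem_height_sd))
        tl_bias = rng.normal(0.0, cfg.tl_seedling_sd)
        state = SeedlingState()
        effect_idx = (
            order.index(cfg.physio_effect_day)
            if cfg.physio_effect_day is not None else None
        )
        for i, ses in enumerate(order):
            theta, state = angle_trajectory(
                sdl.treatment, ses, state, cfg, rng, baseline=baseline
            )
            theta = float(np.clip(theta, -90.0, 90.0))
            tl = float(at_by_session[ses]) + cfg.tl_offset + tl_bias + rng.normal(0, 0.2)
            if (
                effect_idx is not None
                and sdl.treatment == "drought"
                and i >= effect_idx
            ):
                tl += cfg.tl_shift
            rec = {
                "seedling_id": sdl.seedling_id, "treatment": sdl.treatment,
                "session": ses, "day": session_day(ses),
                "period": session_period(ses),
                "theta_true": theta, "baseline_theta": float(baseline),
                "vitality": state.vitality,
                "first_wilt_session": state.first_wilt_session,
                "death_session": state.death_session,
                "discoloration": state.discoloration,
                "stem_height_px": stem_h,
                "tl_true": tl,
                "measurable": state.vitality != DEAD,
            }
            gt_rows.append(rec)
            per_seedling_session[(sdl.seedling_id, ses)] = rec

    # frames: pair control[2k:2k+2] with drought[2k:2k+2] per session
    chart, rois = _frame_geometry(cfg)
    n_frames_per_session = (n + 1) // 2
    frames: list[SceneImage] = []
    gt_masks: dict[str, list] = {}
    thermal_maps: dict[str, np.ndarray] = {}
    needle_rows = []
    frame_sss = iter(ss_frames.spawn(len(order) * n_frames_per_session))
    ctl_ids = list(seedlings[seedlings.treatment == "control"].seedling_id)
    dro_ids = list(seedlings[seedlings.treatment == "drought"].seedling_id)
    for ses in order:
        at = float(at_by_session[ses])
        for k in range(n_frames_per_session):
            rng = np.random.default_rng(next(frame_sss))
            ids = ctl_ids[2 * k : 2 * k + 2] + dro_ids[2 * k : 2 * k + 2]
            treatments = ["control"] * len(ctl_ids[2 * k : 2 * k + 2]) + [
                "drought"
            ] * len(dro_ids[2 * k : 2 * k + 2])
            scene_id = f"{ses}_f{k}"
            h, w = cfg.image_height, cfg.image_width
            img = np.empty((h, w, 3), dtype=float)
            img[:] = _BACKGROUND
            masks = [np.zeros((h, w), dtype=bool) for _ in rois]
            thermal = at + rng.normal(0.0, 0.1, size=(h, w))
            for slot, (sid, _treat) in enumerate(zip(ids, treatments)):
                rec = per_seedling_session[(sid, ses)]
                ann = _render_seedling(
                    img, masks[slot], rois[slot],
                    theta=rec["theta_true"],
                    droop=rec["baseline_theta"] - rec["theta_true"],
                    wilted=rec["vitality"] in (WILTED, DEAD),
                    stem_height=rec["stem_height_px"],
                    discoloration=rec["discoloration"],
                    dead=rec["vitality"] == DEAD,
                    rng=rng,
                )
                # thermal pixels over the whole rendered plant (incl. dead tissue)
                plant_px = np.abs(img[..., 1] - _BACKGROUND[1]) > 20
                region = np.zeros((h, w), dtype=bool)
                region[rois[slot].slices] = True
                sel = plant_px & region | masks[slot]
                thermal[sel] = rec["tl_true"] + rng.normal(
                    0.0, cfg.thermal_noise_sd, size=int(sel.sum())
                )
                if rec["measurable"]:
                    for a in ann:
                        needle_rows.append(
                            {"seedling_id": sid, "session": ses,
                             "day": session_day(ses), **a}
                        )
            _render_chart(img, chart)
            # capture distortion: per-channel affine + sensor noise
            gain = rng.uniform(0.85, 1.1, size=3)
            offs = rng.uniform(-10.0, 10.0, size=3)
            noisy = img * gain + offs + rng.normal(0.0, 2.0, size=img.shape)
            frame = SceneImage(
                image=np.clip(np.round(noisy), 0, 255).astype(np.uint8),
                session=ses, scene_id=scene_id, chart_region=chart,
                plant_rois=list(rois[: len(ids)]), treatments=treatments,
                seedling_ids=ids,
            )
            frames.append(frame)
            gt_masks[scene_id] = masks[: len(ids)]
            thermal_maps[scene_id] = thermal.astype(np.float32)

    ground_truth = pd.DataFrame(gt_rows)
    # canopy extent from the rendered ground-truth masks (living pixels)
    extent = {}
    for scene_id, masks in gt_masks.items():
        ses = scene_id.rsplit("_", 1)[0]
        frame = next(f for f in frames if f.scene_id == scene_id)
        for sid, m in zip(frame.seedling_ids, masks):
            rows = np.nonzero(m)[0]
            extent[(sid, ses)] = float(rows.max() - rows.min() + 1) if rows.size else 0.0
    ground_truth["canopy_extent_px"] = [
        extent.get((r.seedling_id, r.session), np.nan) for r in ground_truth.itertuples()
    ]

    return SimulationResult(
        config=cfg,
        frames=frames,
        gt_masks=gt_masks,
        thermal_maps=thermal_maps,
        needles=pd.DataFrame(needle_rows),
        env=env,
        physio=physio,
        ground_truth=ground_truth,
    )
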