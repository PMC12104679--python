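"""End-to-end pipeline and earliest-detection report.

Composes the synthetic generator with the image front end, morphometrics,
needle-angle derivation, thermal indices and the per-session statistical
battery, then reports for every parameter the earliest session at which the
drought and control groups diverge.

Per-session group comparisons use the sample-size rule: groups of at most 10
per treatment are compared with a Mann-Whitney U test, larger groups with a
two-sample t-test.  Each parameter's post-hoc tests run only after a
significant Kruskal-Wallis omnibus over its treatment x session cells
(Bonferroni-corrected across parameter families), and per-session p-values
are Bonferroni-adjusted over the total number of tests in the report, so the
family-wise error of the full screen stays below alpha.  The earliest session
requires adjusted p strictly below alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import angles as ang
from . import colormask as cm
from . import morpho, thermal
from .synth import (
    DEAD,
    ExperimentConfig,
    SimulationResult,
    REFERENCE_CHART,
    session_day,
    session_period,
    simulate_experiment,
)

__all__ = [
    "DetectionReport",
    "PipelineResult",
    "run_pipeline",
    "analyze_simulation",
    "earliest_session",
    "detection_battery",
    "PARAMETER_FAMILIES",
]

log = logging.getLogger(__name__)

#: parameter -> family used for report grouping and ordering claims
PARAMETER_FAMILIES = {
    "theta": "needle_angle",
    "bd_m": "needle_angle",
    "pm_m": "needle_angle",
    "pm_m_st": "needle_angle",
    "area_px": "seedling_level",
    "height_px": "seedling_level",
    "width_px": "seedling_level",
    "longest_path_px": "seedling_level",
    "hull_area_px2": "seedling_level",
    "solidity": "seedling_level",
    "perimeter_px": "seedling_level",
    "com_y": "seedling_level",
    "Phi_NPQ": "physiological",
    "FvFm_prime": "physiological",
    "Tl": "thermal",
    "VPD": "thermal",
    "CWSI_Tl": "thermal",
    "LTD": "thermal",
}


@dataclass
class DetectionReport:
    """Per-parameter earliest significant session and supporting p-values."""

    table: pd.DataFrame  # parameter, family, test, earliest_session, direction
    per_session_p: pd.DataFrame  # parameter x session adjusted p (long format)
    alpha: float = 0.05

    def earliest(self, parameter: str):
        row = self.table[self.table.parameter == parameter]
        if row.empty:
            return None
        v = row.iloc[0].earliest_session
        return None if pd.isna(v) else v

    def to_markdown(self) -> str:
        lines = [
            "# Drought-stress detection report",
            "",
            f"alpha = {self.alpha} (Bonferroni over sessions per parameter)",
            "",
            "| parameter | family | test | earliest session | direction |",
            "|---|---|---|---|---|",
        ]
        for r in self.table.itertuples():
            ses = r.earliest_session if isinstance(r.earliest_session, str) else "-"
            direction = r.direction if isinstance(r.direction, str) else "-"
            lines.append(
                f"| {r.parameter} | {r.family} | {r.test} | {ses} | {direction} |"
            )
        return "\n".join(lines) + "\n"


@dataclass
class PipelineResult:
    simulation: SimulationResult
    masks: pd.DataFrame  # per seedling x session mask pixel counts (QC)
    morphometrics: pd.DataFrame
    angle_observations: pd.DataFrame
    angle_parameters: pd.DataFrame
    vitality_tally: pd.DataFrame
    thermal_table: pd.DataFrame
    long_table: pd.DataFrame  # tidy parameter values for the battery
    regressions: dict = None  # morning/evening stepwise models
    rm_anova: object = None  # 3-way repeated-measures table (or None)
    report: DetectionReport = None


def earliest_session(p_by_session: dict, alpha: float = 0.05):
    """First session (in supplied order) with adjusted p strictly below alpha."""
    for ses, p in p_by_session.items():
        if np.isfinite(p) and p < alpha:
            return ses
    return None


def _front_end(result: SimulationResult) -> tuple[pd.DataFrame, dict, dict]:
    """Color-correct, segment, clean and split every frame into plant masks.

    Returns the per-plant *green* masks (living tissue, the morphometrics
    substrate) and separate *thermal labeling* regions obtained by a
    non-background brightness threshold: the IR workflow labels clustered
    needle areas whether or not the tissue is still green, so dead foliage
    remains measurable thermally.
    """
    per_plant_masks: dict[tuple[str, str], np.ndarray] = {}
    thermal_regions: dict[tuple[str, str], np.ndarray] = {}
    rows = []
    import warnings as _warnings

    for frame in result.frames:
        observed = cm.chart_patch_means(frame.image, frame.chart_region)
        transform = cm.fit_color_correction(observed, REFERENCE_CHART)
        corrected = transform.apply(frame.image)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # dead frames legitimately empty
            mask = cm.threshold_mask(
                corrected, "auto", provenance={"scene_id": frame.scene_id}
            )
        # keep the chart out of the plant mask
        mask.data[frame.chart_region.slices] = False
        cleaned = cm.clean_mask(mask, min_component_px=20, fill_holes=True)
        plants = cm.split_plants(cleaned, frame.plant_rois)

        nonbg = cm.BinaryMask(data=corrected.max(axis=2) > 40)
        nonbg.data[frame.chart_region.slices] = False
        nonbg = cm.clean_mask(nonbg, min_component_px=20, fill_holes=True)
        regions = cm.split_plants(nonbg, frame.plant_rois)

        for sid, pm, reg in zip(frame.seedling_ids, plants, regions):
            per_plant_masks[(sid, frame.session)] = pm.data
            thermal_regions[(sid, frame.session)] = reg.data
            rows.append(
                {"seedling_id": sid, "session": frame.session,
                 "scene_id": frame.scene_id, "mask_px": pm.pixel_count}
            )
    return pd.DataFrame(rows), per_plant_masks, thermal_regions


def _angle_stage(
    result: SimulationResult, min_drought_angle_values: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list]:
    cfg = result.config
    order = cfg.sessions
    obs_rows = []
    obs_by_seedling: dict[str, list] = {}
    for (sid, ses), grp in result.needles.groupby(["seedling_id", "session"], sort=False):
        pairs = [
            (int(r.quadrant),
             ang.needle_angle((r.base_col, r.base_row), (r.tip_col, r.tip_row)))
            for r in grp.itertuples()
        ]
        o = ang.quadrant_mean(pairs, seedling_id=sid, day=session_day(ses), session=ses)
        obs_by_seedling.setdefault(sid, []).append(o)
        obs_rows.append(
            {"seedling_id": sid, "session": ses, "day": o.day,
             "theta": o.theta, "n_needles": o.n_needles_measured,
             "measurable": o.measurable}
        )
    obs_df = pd.DataFrame(obs_rows)

    param_rows = []
    for sid, obs in obs_by_seedling.items():
        obs.sort(key=lambda o: order.index(o.session))
        for ps in ang.derive_parameters(obs, order):
            param_rows.append(
                {"seedling_id": sid, "session": ps.session, "stx_bin": ps.stx_bin,
                 "bd_m": ps.bd_m, "pm_m": ps.pm_m, "pm_m_st": ps.pm_m_st}
            )
    params_df = pd.DataFrame(param_rows)

    theta_series = {
        sid: {o.session: o.theta for o in obs if o.measurable}
        for sid, obs in obs_by_seedling.items()
    }
    gt = result.ground_truth
    disc = {
        sid: dict(zip(sub.session, sub.discoloration))
        for sid, sub in gt.groupby("seedling_id")
    }
    _, tally = ang.classify_vitality(theta_series, disc, order)

    # continuation rule: the daily angle analysis proceeds only while enough
    # measurable needle-angle values remain in the drought group
    treat = gt.drop_duplicates("seedling_id").set_index("seedling_id")["treatment"]
    needles = result.needles
    drought_counts = (
        needles[needles.seedling_id.map(treat) == "drought"]
        .groupby("session").size().reindex(order, fill_value=0).to_dict()
    )
    eligible = set(ang.sufficient_sample_sessions(drought_counts, min_drought_angle_values))
    eligible.add("BD")  # the pre-drought reference is always retained
    if not obs_df.empty:
        obs_df["in_guard"] = obs_df.session.isin(eligible)
    return obs_df, params_df, tally, sorted(eligible, key=order.index)


def _thermal_stage(
    result: SimulationResult, thermal_regions: dict
) -> pd.DataFrame:
    env = result.env.drop_duplicates("session").set_index("session")
    gt = result.ground_truth
    rows = []
    # leaf temperature from the thermal maps under each plant's mask
    tl_by = {}
    for frame in result.frames:
        tmap = result.thermal_maps[frame.scene_id]
        for sid in frame.seedling_ids:
            m = thermal_regions.get((sid, frame.session))
            if m is None or not m.any():
                continue
            tl_by[(sid, frame.session)] = thermal.tl_from_map(tmap, m)
    for ses, sub in gt.groupby("session", sort=False):
        obs = [
            (r.seedling_id, r.treatment, tl_by.get((r.seedling_id, ses)))
            for r in sub.itertuples()
        ]
        obs = [(s, t, v) for s, t, v in obs if v is not None]
        if len(obs) < 2:
            continue
        tls = [v for *_, v in obs]
        ta = float(env.loc[ses, "AT"])
        ah = float(env.loc[ses, "AH"])
        try:
            refs = thermal.session_references(tls, [ta] * len(tls), scope=ses)
        except thermal.DegenerateReferenceError:
            refs = None
        control_tl = [v for _, t, v in obs if t == "control"]
        for sid, treat, tl in obs:
            row = {
                "seedling_id": sid, "treatment": treat, "session": ses,
                "day": session_day(ses), "period": session_period(ses),
                "Tl": tl, "Ta": ta, "AH": ah,
                "VPD": thermal.vpd(tl, ta, ah),
            }
            row["CWSI_Tl"] = thermal.cwsi_tl(tl, refs) if refs else np.nan
            row["LTD"] = thermal.ltd(control_tl, tl) if control_tl else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def _long_table(
    result: SimulationResult,
    morpho_df: pd.DataFrame,
    obs_df: pd.DataFrame,
    params_df: pd.DataFrame,
    thermal_df: pd.DataFrame,
    eligible_sessions=None,
) -> pd.DataFrame:
    """Tidy (seedling, treatment, session, parameter, value) table."""
    treat = result.ground_truth.drop_duplicates("seedling_id").set_index(
        "seedling_id"
    )["treatment"]
    pieces = []

    def melt(df, cols):
        if df.empty:
            return
        d = df.melt(
            id_vars=["seedling_id", "session"], value_vars=cols,
            var_name="parameter", value_name="value",
        ).dropna(subset=["value"])
        pieces.append(d)

    melt(obs_df[obs_df.measurable & obs_df.get("in_guard", True)], ["theta"])
    if not params_df.empty and eligible_sessions is not None:
        params_df = params_df[params_df.session.isin(eligible_sessions)]
    melt(params_df, ["bd_m", "pm_m", "pm_m_st"])
    # Seedling-level features enter the battery as within-seedling differences
    # from the pre-drought session, removing between-plant size variation
    # (the seedling-level tables are built on such difference parameters).
    morpho_cols = [
        "area_px", "height_px", "width_px", "longest_path_px", "hull_area_px2",
        "solidity", "perimeter_px", "com_y",
    ]
    morpho_cols = [c for c in morpho_cols if c in morpho_df.columns]
    if not morpho_df.empty:
        bd = morpho_df[morpho_df.session == "BD"].set_index("seedling_id")
        diffed = morpho_df[morpho_df.seedling_id.isin(bd.index)].copy()
        for c in morpho_cols:
            diffed[c] = diffed[c] - diffed.seedling_id.map(bd[c])
        melt(diffed[diffed.session != "BD"], morpho_cols)
    # replicate bundle measurements are averaged per seedling first: the
    # seedling, not the needle bundle, is the experimental unit
    physio_means = (
        result.physio.groupby(["seedling_id", "session"], as_index=False)[
            ["Phi_NPQ", "FvFm_prime"]
        ].mean()
    )
    melt(physio_means, ["Phi_NPQ", "FvFm_prime"])
    melt(thermal_df, ["Tl", "VPD", "CWSI_Tl", "LTD"])
    long = pd.concat(pieces, ignore_index=True)
    long["treatment"] = long.seedling_id.map(treat)
    long["day"] = long.session.map(session_day)
    return long


_STX_CODE = {f"ST{i}": i for i in range(1, 7)}


def _regression_stage(
    result: SimulationResult,
    params_df: pd.DataFrame,
    thermal_df: pd.DataFrame,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> dict:
    """Stepwise models of the apical-bin code on physiological/thermal and
    environment covariates, fitted separately for morning and evening sessions
    (mirroring the published morning/evening model structure).

    Physiology is measured on alternate days only; angle sessions are joined
    to the same day's physiological measurement, so the regression rows cover
    the measured days.
    """
    from .stats import stepwise_regression

    if params_df.empty:
        return {}
    physio = (
        result.physio.groupby(["seedling_id", "day"], as_index=False)[
            ["Phi_NPQ", "FvFm_prime"]
        ].mean()
    )
    env = result.env.drop_duplicates(["session", "treatment"]).set_index(
        ["session", "treatment"]
    )
    treat = result.ground_truth.drop_duplicates("seedling_id").set_index(
        "seedling_id"
    )["treatment"]
    rows = params_df.copy()
    rows["day"] = rows.session.map(session_day)
    rows["period"] = rows.session.map(session_period)
    rows["y"] = rows.stx_bin.map(_STX_CODE).astype(float)
    rows = rows.merge(physio, on=["seedling_id", "day"], how="inner")
    if not thermal_df.empty:
        rows = rows.merge(
            thermal_df[["seedling_id", "session", "LTD"]],
            on=["seedling_id", "session"], how="left",
        )
    else:
        rows["LTD"] = np.nan
    rows["treatment"] = rows.seedling_id.map(treat)
    for var in ("AH", "SR", "SM", "EC"):
        rows[var] = [
            float(env.loc[(r.session, r.treatment), var])
            for r in rows.itertuples()
        ]
    candidates = ["Phi_NPQ", "LTD", "AH", "SR", "SM", "EC"]
    models = {}
    for period, label in (("M", "STx_M"), ("E", "STx_E")):
        sub = rows[(rows.period == period) & (rows.session != "BD")].dropna(
            subset=["y", *candidates]
        )
        usable = [c for c in candidates if sub[c].nunique() > 1] if not sub.empty else []
        if len(sub) <= len(usable) + 2 or not usable:
            log.info("regression %s skipped: %d usable rows", label, len(sub))
            continue
        models[label] = stepwise_regression(
            sub["y"].to_numpy(), sub[usable], entry_p=entry_p, removal_p=removal_p
        )
    return models


def _rm_anova_stage(
    result: SimulationResult,
    params_df: pd.DataFrame,
    gg_correction: bool = False,
):
    """Three-way repeated-measures ANOVA (treatment x day x time) of the
    pre-drought-difference angle parameter over the pre-mortality window.

    Only complete days on which every seedling is still measurable enter, so
    the design stays balanced; returns None when fewer than two such days
    remain.
    """
    from .stats import UnbalancedDesignError, rm_anova

    if params_df.empty:
        return None
    treat = result.ground_truth.drop_duplicates("seedling_id").set_index(
        "seedling_id"
    )["treatment"]
    df = params_df.dropna(subset=["bd_m"]).copy()
    df["day"] = df.session.map(session_day)
    df["time"] = df.session.map(session_period)
    df = df[df.session != "BD"]
    n_subjects = result.ground_truth.seedling_id.nunique()
    complete = [
        d for d, sub in df.groupby("day")
        if set(sub.time) == {"M", "E"}
        and (sub.groupby("time").seedling_id.nunique() == n_subjects).all()
    ]
    if len(complete) < 2:
        return None
    df = df[df.day.isin(complete)]
    df["treatment"] = df.seedling_id.map(treat)
    try:
        return rm_anova(
            df.rename(columns={"bd_m": "value", "seedling_id": "subject"}),
            within=["day", "time"], gg_correction=gg_correction,
        )
    except UnbalancedDesignError as exc:
        log.warning("3-way repeated-measures ANOVA skipped: %s", exc)
        return None


def detection_battery(
    long_table: pd.DataFrame,
    session_order,
    alpha: float = 0.05,
    nonparametric_max_n: int = 10,
) -> DetectionReport:
    """Per-parameter per-session control/drought comparison with Bonferroni."""
    sessions = [s for s in session_order if s != "BD"]
    table_rows = []
    p_rows = []
    # The omnibus gate is Bonferroni-corrected across parameter *families*
    # (parameters within a family are derived from the same measurements and
    # are strongly correlated, so families are the effective screening units).
    n_families = len(
        {PARAMETER_FAMILIES.get(p, "other") for p in long_table.parameter.unique()}
    )
    gate_alpha = alpha / max(n_families, 1)
    for param, sub in long_table.groupby("parameter", sort=True):
        # omnibus gate (post-hocs only follow a significant omnibus test):
        # Kruskal-Wallis over all treatment x session cells of this parameter,
        # Bonferroni-corrected for the number of parameters screened
        cells = [
            grp.value.to_numpy(dtype=float)
            for _, grp in sub.groupby(["session", "treatment"])
            if len(grp) >= 2
        ]
        gate_p = 1.0
        if len(cells) >= 2 and not np.all(
            np.concatenate(cells) == np.concatenate(cells)[0]
        ):
            try:
                _, gate_p = sps.kruskal(*cells)
            except ValueError:
                gate_p = 1.0
        p_raw = {}
        direction = {}
        test_used = None
        for ses in sessions if gate_p < gate_alpha else []:
            cell = sub[sub.session == ses]
            ctl = cell[cell.treatment == "control"].value.to_numpy(dtype=float)
            dro = cell[cell.treatment == "drought"].value.to_numpy(dtype=float)
            if len(ctl) < 2 or len(dro) < 2:
                continue
            if max(len(ctl), len(dro)) <= nonparametric_max_n:
                test_used = "Mann-Whitney U (Bonferroni)"
                ties = len(np.unique(np.concatenate([ctl, dro]))) < len(ctl) + len(dro)
                method = "exact" if (len(ctl) + len(dro) <= 25 and not ties) else "asymptotic"
                try:
                    _, p = sps.mannwhitneyu(ctl, dro, alternative="two-sided", method=method)
                except ValueError:
                    p = 1.0
            else:
                test_used = "t-test (Bonferroni)"
                _, p = sps.ttest_ind(ctl, dro)
            if np.isnan(p):
                p = 1.0
            p_raw[ses] = float(p)
            direction[ses] = "drought_higher" if dro.mean() > ctl.mean() else "drought_lower"
        m = len(p_raw)
        p_adj = {s: min(1.0, p * m) for s, p in p_raw.items()}
        first = earliest_session(p_adj, alpha)
        if test_used is None:
            test_used = (
                "Kruskal-Wallis omnibus not significant"
                if gate_p >= gate_alpha else "insufficient data"
            )
        table_rows.append(
            {
                "parameter": param,
                "family": PARAMETER_FAMILIES.get(param, "other"),
                "test": test_used,
                "omnibus_p": gate_p,
                "p_raw": p_raw,
                "direction_by_session": direction,
            }
        )
    # report-wide Bonferroni: m = number of tests computed across the whole
    # report, so the family-wise error of the full screen is bounded by alpha
    m = sum(len(r["p_raw"]) for r in table_rows)
    for r in table_rows:
        p_adj = {s: min(1.0, p * m) for s, p in r["p_raw"].items()}
        first = earliest_session(p_adj, alpha)
        direction = r.pop("direction_by_session")
        r["earliest_session"] = first if first is not None else np.nan
        r["direction"] = direction.get(first, np.nan) if first else np.nan
        for s, p in p_adj.items():
            p_rows.append({"parameter": r["parameter"], "session": s, "p_adj": p,
                           "p_raw": r["p_raw"][s], "m": m})
        del r["p_raw"]
    table = pd.DataFrame(table_rows)
    per_session = pd.DataFrame(p_rows)
    # rank parameters by earliest detection (undetected last)
    pos = {s: i for i, s in enumerate(sessions)}
    table["rank_key"] = table.earliest_session.map(
        lambda s: pos.get(s, len(sessions))
    )
    table = table.sort_values(["rank_key", "parameter"]).drop(columns="rank_key")
    table = table.reset_index(drop=True)
    return DetectionReport(table=table, per_session_p=per_session, alpha=alpha)


def analyze_simulation(
    result: SimulationResult,
    alpha: float = 0.05,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    gg_correction: bool = False,
    min_drought_angle_values: int = 30,
) -> PipelineResult:
    """Run every analysis stage on an existing simulation."""
    mask_df, per_plant_masks, thermal_regions = _front_end(result)
    morpho_rows = []
    for (sid, ses), m in per_plant_masks.items():
        rec = morpho.extract_all(m, seedling_id=sid, day=session_day(ses), session=ses)
        row = {"seedling_id": sid, "session": ses, "day": rec.day,
               "flags": ";".join(rec.flags)}
        for c in morpho.FEATURE_COLUMNS:
            row[c] = getattr(rec, c)
        morpho_rows.append(row)
    morpho_df = pd.DataFrame(morpho_rows).dropna(subset=["area_px"])
    obs_df, params_df, tally, eligible = _angle_stage(
        result, min_drought_angle_values=min_drought_angle_values
    )
    thermal_df = _thermal_stage(result, thermal_regions)
    long = _long_table(result, morpho_df, obs_df, params_df, thermal_df,
                       eligible_sessions=eligible)
    report = detection_battery(long, result.config.sessions, alpha=alpha)
    regressions = _regression_stage(result, params_df, thermal_df,
                                    entry_p=entry_p, removal_p=removal_p)
    anova = _rm_anova_stage(result, params_df, gg_correction=gg_correction)
    return PipelineResult(
        simulation=result,
        masks=mask_df,
        morphometrics=morpho_df,
        angle_observations=obs_df,
        angle_parameters=params_df,
        vitality_tally=tally,
        thermal_table=thermal_df,
        long_table=long,
        regressions=regressions,
        rm_anova=anova,
        report=report,
    )


def run_pipeline(
    config: ExperimentConfig | None = None,
    alpha: float = 0.05,
    out_dir=None,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    gg_correction: bool = False,
) -> PipelineResult:
    """Simulate (or accept) an experiment and produce the detection report.

    When ``out_dir`` is given, all intermediate CSVs, the report CSV and a
    markdown summary are written there.
    """
    cfg = config or ExperimentConfig()
    result = simulate_experiment(cfg)
    pipe = analyze_simulation(result, alpha=alpha, entry_p=entry_p,
                              removal_p=removal_p, gg_correction=gg_correction)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pipe.masks.to_csv(out / "masks.csv", index=False)
        pipe.morphometrics.to_csv(out / "morphometrics.csv", index=False)
        pipe.angle_observations.to_csv(out / "angle_observations.csv", index=False)
        pipe.angle_parameters.to_csv(out / "angle_parameters.csv", index=False)
        pipe.vitality_tally.to_csv(out / "vitality_tally.csv", index=False)
        pipe.thermal_table.to_csv(out / "thermal.csv", index=False)
        pipe.long_table.to_csv(out / "long_table.csv", index=False)
        pipe.report.table.to_csv(out / "detection_report.csv", index=False)
        pipe.report.per_session_p.to_csv(out / "detection_pvalues.csv", index=False)
        (out / "detection_report.md").write_text(pipe.report.to_markdown())
        if pipe.rm_anova is not None:
            pipe.rm_anova.table.to_csv(out / "rm_anova.csv", index=False)
        if pipe.regressions:
            reg_rows = []
            for label, model in pipe.regressions.items():
                for p in model.predictors:
                    reg_rows.append(
                        {"model": label, "predictor": p,
                         "beta": model.coefficients[p],
                         "std_beta": model.std_beta.get(p),
                         "p": model.pvalues.get(p),
                         "tolerance": model.tolerance.get(p),
                         "vif": model.vif.get(p),
                         "r2": model.r2, "adj_r2": model.adj_r2,
                         "intercept": model.intercept,
                         "durbin_watson": model.durbin_watson}
                    )
            pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False)
    return pipe
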