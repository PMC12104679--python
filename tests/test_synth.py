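import hashlib
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from needledyn import colormask, morpho
from needledyn.angles import needle_angle, quadrant_mean
from needledyn.synth import (
    DEAD,
    ConfigError,
    ExperimentConfig,
    SeedlingState,
    angle_trajectory,
    session_day,
    session_labels,
    session_period,
    simulate_experiment,
)


class TestConfig:
    def test_session_labels_default(self):
        labels = session_labels(7)
        assert labels[0] == "BD"
        assert labels[1:3] == ["D1M", "D1E"]
        assert labels[-1] == "D6E"
        assert len(labels) == 13

    def test_session_helpers(self):
        assert session_day("BD") == 0
        assert session_day("D4E") == 4
        assert session_period("D4E") == "E"
        assert session_period("BD") == "M"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_seedlings_per_treatment": 0},
            {"wilt_onset_session": "D9E"},
            {"recovery_fraction": 1.5},
            {"baseline_angle_sd": -1.0},
            {"days_to_death_after_first_wilt": (0, 2)},
            {"physio_effect_day": "nonsense"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ExperimentConfig(**kwargs).validate()


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = ExperimentConfig(
            n_seedlings_per_treatment=2, n_days=3, physio_effect_day="D2M",
            rng_seed=11,
        )
        a = simulate_experiment(cfg)
        b = simulate_experiment(
            ExperimentConfig(
                n_seedlings_per_treatment=2, n_days=3, physio_effect_day="D2M",
                rng_seed=11,
            )
        )
        for fa, fb in zip(a.frames, b.frames):
            ha = hashlib.sha256(fa.image.tobytes()).hexdigest()
            hb = hashlib.sha256(fb.image.tobytes()).hexdigest()
            assert ha == hb
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)
        pd.testing.assert_frame_equal(a.env, b.env)
        pd.testing.assert_frame_equal(a.physio, b.physio)

    def test_different_seed_differs(self):
        kw = dict(n_seedlings_per_treatment=2, n_days=3, physio_effect_day="D2M")
        a = simulate_experiment(ExperimentConfig(rng_seed=1, **kw))
        b = simulate_experiment(ExperimentConfig(rng_seed=2, **kw))
        assert not np.array_equal(a.frames[0].image, b.frames[0].image)


class TestAngleTrajectory:
    def test_dead_is_absorbing_and_discolors(self):
        cfg = ExperimentConfig()
        rng = np.random.default_rng(0)
        state = SeedlingState(vitality=DEAD, discoloration=0.5,
                              first_wilt_session="D2E", death_session="D3M")
        _, new = angle_trajectory("drought", "D4M", state, cfg, rng)
        assert new.vitality == DEAD
        assert new.discoloration > 0.5

    def test_control_draws_baseline(self):
        cfg = ExperimentConfig(session_noise_sd=0.0)
        rng = np.random.default_rng(0)
        theta, state = angle_trajectory(
            "control", "D6E", SeedlingState(), cfg, rng, baseline=33.0
        )
        assert theta == pytest.approx(33.0)
        assert state.vitality == "survival"

    def test_drop_mean_monte_carlo(self):
        # 10,000 draws at onset: mean drop from baseline within 3 SE of 17
        cfg = ExperimentConfig(wilt_drop_mean=17.0)
        rng = np.random.default_rng(99)
        baseline = 30.0
        drops = []
        for _ in range(10_000):
            theta, _ = angle_trajectory(
                "drought", "D2E", SeedlingState(), cfg, rng, baseline=baseline
            )
            drops.append(baseline - theta)
        se = np.std(drops, ddof=1) / math.sqrt(len(drops))
        assert np.mean(drops) == pytest.approx(17.0, abs=3 * se)

    def test_pre_onset_drought_no_drop(self):
        cfg = ExperimentConfig(session_noise_sd=0.0)
        rng = np.random.default_rng(0)
        theta, state = angle_trajectory(
            "drought", "D1E", SeedlingState(), cfg, rng, baseline=28.0
        )
        assert theta == pytest.approx(28.0)
        assert state.first_wilt_session is None


class TestZeroEffectNull:
    def test_theta_distributions_identical_in_law(self):
        cfg = ExperimentConfig.null_scenario(
            n_seedlings_per_treatment=120, n_days=4, rng_seed=5
        )
        gt = simulate_experiment(cfg).ground_truth
        assert (gt.vitality == "survival").all()
        for ses in ("D2E", "D3E"):
            ctl = gt[(gt.treatment == "control") & (gt.session == ses)].theta_true
            dro = gt[(gt.treatment == "drought") & (gt.session == ses)].theta_true
            _, p = sps.ks_2samp(ctl, dro)
            assert p > 0.01


class TestGroundTruthInvariants:
    def test_theta_in_range(self, default_simulation):
        gt = default_simulation.ground_truth
        assert gt.theta_true.between(-90, 90).all()

    def test_dead_never_revive(self, default_simulation):
        gt = default_simulation.ground_truth
        order = default_simulation.config.sessions
        pos = {s: i for i, s in enumerate(order)}
        for sid, sub in gt.groupby("seedling_id"):
            sub = sub.sort_values("session", key=lambda s: s.map(pos))
            seen_dead = False
            for v in sub.vitality:
                if seen_dead:
                    assert v == DEAD
                seen_dead = seen_dead or v == DEAD

    def test_living_masks_nonempty(self, default_simulation):
        res = default_simulation
        gt = res.ground_truth.set_index(["seedling_id", "session"])
        for frame in res.frames:
            for sid, m in zip(frame.seedling_ids, res.gt_masks[frame.scene_id]):
                if gt.loc[(sid, frame.session), "vitality"] != DEAD:
                    assert m.any()

    def test_dead_tissue_outside_green_range(self, default_simulation):
        res = default_simulation
        gt = res.ground_truth
        dead = gt[gt.vitality == DEAD]
        assert not dead.empty
        row = dead.iloc[-1]
        frame = next(
            f for f in res.frames
            if f.session == row.session and row.seedling_id in f.seedling_ids
        )
        slot = frame.seedling_ids.index(row.seedling_id)
        roi = frame.plant_rois[slot]
        sub = frame.image[roi.slices].astype(float)
        exg = 2 * sub[..., 1] - sub[..., 0] - sub[..., 2]
        # dead plant: no strongly green pixels left in its ROI
        assert (exg > 150).sum() < 5


class TestRenderedAngles:
    def test_requested_angle_rendered_within_2_degrees(self):
        cfg = ExperimentConfig(
            n_seedlings_per_treatment=2, n_days=2, wilt_onset_session="D1E",
            physio_effect_day=None, session_noise_sd=0.0, baseline_angle_sd=0.0,
            baseline_angle_mean=30.0, rng_seed=3,
        )
        res = simulate_experiment(cfg)
        sub = res.needles[res.needles.session == "BD"]
        for sid, grp in sub.groupby("seedling_id"):
            pairs = [
                (int(r.quadrant),
                 needle_angle((r.base_col, r.base_row), (r.tip_col, r.tip_row)))
                for r in grp.itertuples()
            ]
            obs = quadrant_mean(pairs)
            assert obs.theta == pytest.approx(30.0, abs=2.0)


class TestEnvironment:
    def test_means_and_sds_converge(self):
        cfg = ExperimentConfig(
            n_seedlings_per_treatment=2, n_days=300, wilt_onset_session="D2E",
            physio_effect_day=None, rng_seed=21,
        )
        from needledyn.synth import _simulate_env

        env = _simulate_env(cfg, np.random.default_rng(21))
        shared = env.drop_duplicates("session")
        for var in ("AH", "AT", "SR", "ST"):
            mu, sd = cfg.env_means[var], cfg.env_sds[var]
            n = len(shared)
            assert shared[var].mean() == pytest.approx(mu, abs=4 * sd / math.sqrt(n))
            assert shared[var].std(ddof=1) == pytest.approx(sd, rel=0.15)

    def test_humidity_within_physical_bounds(self, default_simulation):
        env = default_simulation.env
        assert env.AH.between(0, 100).all()
        assert (env.SR >= 0).all()

    def test_diurnal_structure(self):
        cfg = ExperimentConfig(n_days=200, physio_effect_day=None, rng_seed=2)
        from needledyn.synth import _simulate_env

        env = _simulate_env(cfg, np.random.default_rng(2)).drop_duplicates("session")
        env = env[env.session != "BD"]
        m = env[env.period == "M"]
        e = env[env.period == "E"]
        assert m.AH.mean() > e.AH.mean()
        assert m.SR.mean() > e.SR.mean()
        assert m.AT.mean() < e.AT.mean()

    def test_drought_soil_moisture_declines(self, default_simulation):
        env = default_simulation.env
        dro = env[env.treatment == "drought"]
        first = dro[dro.session == "BD"].SM.iloc[0]
        last = dro[dro.session == "D6E"].SM.iloc[0]
        assert last < first


class TestSceneGeometry:
    def test_chart_disjoint_from_rois(self, default_simulation):
        for frame in default_simulation.frames:
            for roi in frame.plant_rois:
                assert frame.chart_region.disjoint(roi)

    def test_frames_per_session(self, default_simulation):
        cfg = default_simulation.config
        per_session = {}
        for f in default_simulation.frames:
            per_session[f.session] = per_session.get(f.session, 0) + 1
        expected = (cfg.n_seedlings_per_treatment + 1) // 2
        assert all(v == expected for v in per_session.values())

    def test_thermal_map_shape_and_background(self, default_simulation):
        res = default_simulation
        frame = res.frames[0]
        tmap = res.thermal_maps[frame.scene_id]
        assert tmap.shape == frame.image.shape[:2]
        assert tmap.dtype == np.float32
        at = res.env[res.env.session == frame.session].AT.iloc[0]
        corner = tmap[:20, -30:]
        assert corner.mean() == pytest.approx(at, abs=0.2)
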