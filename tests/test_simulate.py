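import dataclasses

import numpy as np
import pandas as pd
import pytest

from barnspace.geometry import BarnGeometry, ConfigurationError, Rect
from barnspace.simulate import (
    CowMetadata,
    SimulationParams,
    effect_profile,
    generate_herd,
    generate_metadata,
    nominal_sample_slots,
    read_metadata,
    write_metadata,
)


class TestParams:
    def test_defaults_valid(self):
        SimulationParams()

    def test_rate_positive(self):
        with pytest.raises(ValueError):
            SimulationParams(sample_rate=0.0)

    def test_needs_two_days(self):
        with pytest.raises(ValueError):
            SimulationParams(n_days=1)

    def test_probs_simplex(self):
        bad = {
            "FEED": 0.9,
            "CUBICLE_1": 0.9,
            "CUBICLE_2": 0.0,
            "CUBICLE_3": 0.0,
            "PASSAGE": 0.0,
        }
        with pytest.raises(ValueError):
            SimulationParams(base_probs=bad)

    def test_dwells_positive(self):
        bad = dict(SimulationParams().dwell_min)
        bad["FEED"] = 0.0
        with pytest.raises(ValueError):
            SimulationParams(dwell_min=bad)

    def test_null_effects_copy(self):
        p = SimulationParams().with_null_effects()
        assert p.lame_feed_shift == 0.0
        assert p.lame_radius_mult == 1.0
        assert p.parity_x_shift == 0.0


class TestMetadata:
    def test_invariants(self):
        with pytest.raises(ValueError):
            CowMetadata("c", lame=2, parity=1, dim=10)
        with pytest.raises(ValueError):
            CowMetadata("c", lame=0, parity=0, dim=10)
        with pytest.raises(ValueError):
            CowMetadata("c", lame=0, parity=1, dim=-1)

    def test_split_and_ranges(self):
        params = SimulationParams(n_cows=20, seed=3)
        metas = generate_metadata(params)
        assert sum(m.lame for m in metas) == 10
        assert all(1 <= m.parity <= 6 for m in metas)
        assert all(44 <= m.dim <= 220 for m in metas)

    def test_round_trip(self, tmp_path):
        metas = generate_metadata(SimulationParams(n_cows=5, seed=4))
        path = tmp_path / "meta.csv"
        write_metadata(metas, path)
        df = read_metadata(path)
        assert list(df["cow_id"]) == [m.cow_id for m in metas]
        assert list(df["lame"]) == [m.lame for m in metas]

    def test_read_requires_columns(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("cow_id,lame\n1,0\n")
        with pytest.raises(ValueError, match="parity"):
            read_metadata(p)


class TestEffectProfile:
    def test_feed_probability_drops_with_lameness(self):
        params = SimulationParams()
        sound = CowMetadata("a", 0, 3, 100)
        lame = CowMetadata("b", 1, 3, 100)
        p0 = effect_profile(sound, params)
        p1 = effect_profile(lame, params)
        assert p1.state_probs["FEED"] < p0.state_probs["FEED"]
        assert p1.wander_radius < p0.wander_radius

    def test_parity_x_shift_arithmetic(self):
        params = dataclasses.replace(SimulationParams(), parity_x_shift=3.0)
        a = effect_profile(CowMetadata("a", 0, 1, 100), params)
        b = effect_profile(CowMetadata("b", 0, 4, 100), params)
        assert b.mean_x_target - a.mean_x_target == pytest.approx(9.0)

    def test_null_effects_identical_profiles(self):
        params = SimulationParams().with_null_effects()
        a = effect_profile(CowMetadata("a", 0, 1, 44), params)
        b = effect_profile(CowMetadata("b", 1, 6, 220), params)
        assert a.state_probs == b.state_probs
        assert a.wander_radius == pytest.approx(b.wander_radius)
        assert a.mean_x_target == pytest.approx(b.mean_x_target)

    def test_dim_trend_sign_flips_with_lameness(self):
        params = SimulationParams()
        lo, hi = 44, 220
        s_lo = effect_profile(CowMetadata("a", 0, 3, lo), params).wander_radius
        s_hi = effect_profile(CowMetadata("a", 0, 3, hi), params).wander_radius
        l_lo = effect_profile(CowMetadata("b", 1, 3, lo), params).wander_radius
        l_hi = effect_profile(CowMetadata("b", 1, 3, hi), params).wander_radius
        assert (s_hi - s_lo) > 0 > (l_hi - l_lo)

    def test_probs_sum_to_one(self):
        params = dataclasses.replace(SimulationParams(), lame_feed_shift=-0.9)
        p = effect_profile(CowMetadata("a", 1, 3, 100), params)
        assert sum(p.state_probs.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in p.state_probs.values())


class TestGenerateHerd:
    def test_nominal_slot_arithmetic(self):
        params = SimulationParams(n_cows=1, n_days=5, sample_rate=0.125)
        assert nominal_sample_slots(params) == 54_000

    def test_milking_slots_absent(self, geometry):
        params = SimulationParams(n_cows=1, n_days=2, sample_rate=0.0625, seed=9)
        (traj,), _ = generate_herd(params, geometry)
        # 3 windows x 90 min x 0.0625 Hz = 337.5 -> 338 slots per window pair
        slots = nominal_sample_slots(params)
        milking = 0
        for w in geometry.milking:
            start = int(np.ceil(w.start_s * params.sample_rate))
            stop = int(np.ceil(w.end_s * params.sample_rate))
            milking += stop - start
        assert len(traj) == slots - params.n_days * milking

    def test_timestamps_strictly_increasing_outside_milking(self, geometry):
        params = SimulationParams(n_cows=1, n_days=2, sample_rate=0.0625, seed=10)
        (traj,), _ = generate_herd(params, geometry)
        dt = traj.df["timestamp"].diff().dropna().dt.total_seconds()
        assert (dt > 0).all()
        sod = (
            traj.df["timestamp"].dt.hour * 3600
            + traj.df["timestamp"].dt.minute * 60
            + traj.df["timestamp"].dt.second
        )
        for w in geometry.milking:
            assert not ((sod >= w.start_s) & (sod < w.end_s)).any()

    def test_degenerate_single_state_in_F(self, geometry):
        probs = {
            "FEED": 1.0,
            "CUBICLE_1": 0.0,
            "CUBICLE_2": 0.0,
            "CUBICLE_3": 0.0,
            "PASSAGE": 0.0,
        }
        params = SimulationParams(
            n_cows=1,
            n_days=2,
            sample_rate=0.0625,
            base_probs=probs,
            noise_sd=0.0,
            prob_jitter_sd=0.0,
            day_jitter_sd=0.0,
            passage_jitter_sd=0.0,
            seed=12,
        )
        (traj,), _ = generate_herd(params, geometry)
        f = geometry.zones["F"]
        assert traj.df["x"].between(f.xmin, f.xmax).all()
        assert traj.df["y"].between(f.ymin, f.ymax).all()

    def test_noise_free_positions_inside_zones(self, geometry):
        params = SimulationParams(
            n_cows=2, n_days=2, sample_rate=0.0625, noise_sd=0.0, seed=13
        )
        trajs, _ = generate_herd(params, geometry, add_noise=False)
        for t in trajs:
            for _, row in t.df.sample(200, random_state=0).iterrows():
                assert geometry.zone_of(row.x, row.y) is not None

    def test_seed_determinism(self, geometry, tmp_path):
        from barnspace.prep import write_locations

        params = SimulationParams(n_cows=2, n_days=2, sample_rate=0.0625, seed=14)
        out1, out2 = tmp_path / "a.csv", tmp_path / "b.csv"
        t1, _ = generate_herd(params, geometry)
        t2, _ = generate_herd(params, geometry)
        write_locations(t1, out1)
        write_locations(t2, out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_different_seeds_differ(self, geometry):
        p1 = SimulationParams(n_cows=1, n_days=2, sample_rate=0.0625, seed=15)
        p2 = dataclasses.replace(p1, seed=16)
        (a,), _ = generate_herd(p1, geometry)
        (b,), _ = generate_herd(p2, geometry)
        assert not np.allclose(a.df["x"], b.df["x"])

    def test_missing_zone_is_config_error(self):
        geom = BarnGeometry()
        zones = dict(geom.zones)
        zones["X"] = zones.pop("P")
        zones["P"] = Rect(53, 60, 10, 20)  # keep required tiling zone names
        # remove a state's zone by renaming C1 out of existence is not
        # possible through BarnGeometry validation, so check via geometry
        # missing from the STATE_ZONE map instead
        with pytest.raises(ConfigurationError):
            BarnGeometry(zones={k: v for k, v in geom.zones.items() if k != "C1"})


class TestStatisticalStructure:
    def test_null_effects_group_parity(self, geometry, grid):
        # with all effects off, lame vs non-lame S4 differs < 3 MC SE
        from barnspace.metrics import daily_uds_for_cow, summarize_cow
        from barnspace.prep import prepare

        params = SimulationParams(
            n_cows=24, n_days=2, sample_rate=0.0625, seed=17
        ).with_null_effects()
        trajs, metas = generate_herd(params, geometry)
        s4 = {}
        for t, m in zip(trajs, metas):
            parts = prepare(t, geometry, window=7)
            uds = daily_uds_for_cow(parts, grid)
            s4[m.cow_id] = summarize_cow(parts, uds, geometry, grid).S4
        lame = [s4[m.cow_id] for m in metas if m.lame]
        sound = [s4[m.cow_id] for m in metas if not m.lame]
        diff = abs(np.mean(lame) - np.mean(sound))
        se = np.sqrt(np.var(lame, ddof=1) / len(lame) + np.var(sound, ddof=1) / len(sound))
        assert diff < 3 * se

    def test_default_effects_lower_lame_s4_and_s9(self, geometry, grid):
        from barnspace.metrics import daily_uds_for_cow, summarize_cow
        from barnspace.prep import prepare

        wins = 0
        seeds = range(30, 36)
        for seed in seeds:
            params = SimulationParams(
                n_cows=12, n_days=2, sample_rate=0.0625, seed=seed
            )
            trajs, metas = generate_herd(params, geometry)
            rows = []
            for t, m in zip(trajs, metas):
                parts = prepare(t, geometry, window=7)
                uds = daily_uds_for_cow(parts, grid)
                s = summarize_cow(parts, uds, geometry, grid)
                rows.append((m.lame, s.S4, s.S9))
            df = pd.DataFrame(rows, columns=["lame", "S4", "S9"])
            g = df.groupby("lame").mean()
            if g.loc[1, "S4"] < g.loc[0, "S4"] and g.loc[1, "S9"] < g.loc[0, "S9"]:
                wins += 1
        assert wins >= len(list(seeds)) - 1
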