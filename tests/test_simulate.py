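"""Kinetic Monte-Carlo simulator: ramps, clamps, kinetics, reproducibility."""

import numpy as np
import pytest
from scipy.stats import kstest

from cuproforce.polymer import PolymerModel, wlc_extension
from cuproforce.schemes import (
    InstrumentConfig,
    ModuleScheme,
    TransitionRule,
    cupredoxin_module,
    default_polyprotein,
    two_state_module,
)
from cuproforce.simulate import simulate_constant_velocity, simulate_force_clamp

KT = 0.0138064852 * 298.0


def inert_module(name="inert", dLc=30.0):
    # k0 so small the module never fires on experimental timescales
    return two_state_module(name, dLc, 1e-30, 0.01)


class TestConstantVelocity:
    def test_same_seed_gives_identical_trace(self):
        poly = default_polyprotein("wt-azurin")
        cfg = InstrumentConfig(rng_seed=7)
        t1, g1 = simulate_constant_velocity(poly, cfg)
        t2, g2 = simulate_constant_velocity(default_polyprotein("wt-azurin"), cfg)
        np.testing.assert_array_equal(t1.force, t2.force)
        np.testing.assert_array_equal(t1.extension, t2.extension)
        assert g1["events"] == g2["events"]

    def test_inert_modules_give_monotone_ramp_without_ruptures(self):
        trace, truth = simulate_constant_velocity(
            [inert_module()], InstrumentConfig(rng_seed=0, force_noise_sd=0.0),
            max_force=150.0,
        )
        assert truth["events"] == []
        assert np.all(np.diff(trace.extension) >= 0)
        assert np.all(np.diff(trace.force[10:]) >= -1e-9)

    def test_empty_polyprotein_rejected(self):
        with pytest.raises(ValueError):
            simulate_constant_velocity([], InstrumentConfig())

    def test_threshold_limit_gives_sharp_rupture_force(self):
        """A rate with huge Δx acts as a force threshold: rupture at F*."""
        # k(F) crosses ~1e3/s (the sub-step hazard scale) at
        # F* = kT ln(1e3/k0) / Δx; with Δx = 20 nm the transition from
        # negligible to overwhelming hazard spans < 1 pN.
        dx = 20.0
        k0 = 1e-38
        forces = []
        for seed in range(40):
            mod = two_state_module("step", 30.0, k0, dx)
            _, truth = simulate_constant_velocity(
                [mod], InstrumentConfig(rng_seed=seed, force_noise_sd=0.0),
            )
            assert len(truth["events"]) == 1
            forces.append(truth["events"][0]["force"])
        forces = np.array(forces)
        assert forces.std() < 1.0
        # threshold location: hazard k(F)*dwell-per-pN ~ 1
        f_star = KT * np.log(1e3 / k0) / dx
        assert abs(forces.mean() - f_star) < 2.0

    def test_equal_clamps_partition_evenly_across_many_units(self):
        mod = cupredoxin_module("sym", 6.2, 9.4, 38.6, (0.05, 0.45),
                                (0.05, 0.45), (1.6, 0.4), holo_probability=1.0)
        n_c = n_n = 0
        for seed in range(60):
            _, truth = simulate_constant_velocity(
                [mod] * 4, InstrumentConfig(rng_seed=100 + seed),
            )
            for m in truth["modules"]:
                first = m["states_visited"][1]
                if first == "int_C":
                    n_c += 1
                elif first == "int_N":
                    n_n += 1
        total = n_c + n_n
        se = np.sqrt(0.25 * total)
        assert abs(n_c - total / 2) < 3 * se

    def test_total_released_contour_is_path_independent(self):
        poly = default_polyprotein("wt-azurin")
        expected = sum(m.total_delta_Lc for m in poly)
        for seed in (1, 2, 3):
            _, truth = simulate_constant_velocity(
                poly, InstrumentConfig(rng_seed=seed),
            )
            assert all(m["states_visited"][-1] == "unfolded"
                       for m in truth["modules"])
            released = sum(e["delta_Lc"] for e in truth["events"])
            assert released == pytest.approx(expected, abs=1e-9)

    def test_rupture_forces_increase_with_pulling_velocity(self):
        means = []
        for v in (40.0, 400.0, 4000.0):
            forces = []
            for seed in range(8):
                _, truth = simulate_constant_velocity(
                    [two_state_module("u", 30.0, 1e-4, 0.25)] * 2,
                    InstrumentConfig(rng_seed=seed, pulling_velocity=v,
                                     force_noise_sd=0.0),
                )
                forces += [e["force"] for e in truth["events"]]
            means.append(np.mean(forces))
        assert means[0] < means[1] < means[2]

    def test_modal_force_matches_evans_ritchie_at_constant_loading(self):
        """Single-barrier rupture matches (kT/Δx) ln(r Δx /(k0 kT)) to 10%."""
        k0, dx = 1e-4, 0.25
        forces, rates = [], []
        for seed in range(25):
            trace, truth = simulate_constant_velocity(
                [two_state_module("u", 28.0, k0, dx)],
                InstrumentConfig(rng_seed=seed, force_noise_sd=0.0),
            )
            e = truth["events"][0]
            forces.append(e["force"])
            # loading rate just before rupture, measured from the trace
            t, f = trace.time, trace.force
            sel = (t < e["time"]) & (t > e["time"] - 0.02)
            if sel.sum() > 3:
                rates.append(np.polyfit(t[sel], f[sel], 1)[0])
        r = np.median(rates)
        predicted = (KT / dx) * np.log(r * dx / (k0 * KT))
        assert np.mean(forces) == pytest.approx(predicted, rel=0.10)

    def test_noise_is_confined_to_the_force_channel(self):
        cfg_clean = InstrumentConfig(rng_seed=3, force_noise_sd=0.0)
        cfg_noisy = InstrumentConfig(rng_seed=3, force_noise_sd=5.0)
        t_clean, _ = simulate_constant_velocity([inert_module()], cfg_clean,
                                                max_force=100.0)
        t_noisy, _ = simulate_constant_velocity([inert_module()], cfg_noisy,
                                                max_force=100.0)
        np.testing.assert_array_equal(t_clean.extension, t_noisy.extension)
        assert np.std(t_noisy.force - t_clean.force) == pytest.approx(5.0, rel=0.1)


class TestForceClamp:
    def test_same_seed_gives_identical_trace(self):
        poly = default_polyprotein("wt-azurin")
        cfg = InstrumentConfig(rng_seed=5)
        t1, _ = simulate_force_clamp(poly, 20.0, 3.0, cfg)
        t2, _ = simulate_force_clamp(default_polyprotein("wt-azurin"), 20.0, 3.0, cfg)
        np.testing.assert_array_equal(t1.extension, t2.extension)

    def test_nonpositive_clamp_force_rejected(self):
        with pytest.raises(ValueError):
            simulate_force_clamp([inert_module()], 0.0, 1.0, InstrumentConfig())

    def test_dwell_times_are_exponential(self):
        """First-rupture dwells of a constant-rate unit pass a KS test."""
        # at 20 pN this rule has k ~ 5/s (force-independent: tiny Δx)
        k = 5.0
        rule_k0 = k / np.exp(20.0 * 1e-6 / KT)
        dwells = []
        for seed in range(1000):
            mod = two_state_module("u", 30.0, rule_k0, 1e-6)
            _, truth = simulate_force_clamp(
                [mod], 20.0, 10.0,
                InstrumentConfig(rng_seed=seed, sampling_rate=100.0,
                                 force_noise_sd=0.0),
            )
            if truth["events"]:
                dwells.append(truth["events"][0]["time"])
        assert len(dwells) > 990  # censoring at 10 s is negligible for k=5
        res = kstest(dwells, "expon", args=(0, 1 / k))
        assert res.pvalue > 0.01

    def test_step_size_follows_wlc_fraction_at_clamp_force(self):
        """A 38.6 nm release at 20 pN steps by 38.6 * (x/Lc at 20 pN)."""
        mod = two_state_module("u", 38.6, 5.0, 1e-6)
        _, truth = simulate_force_clamp(
            [mod], 20.0, 50.0, InstrumentConfig(rng_seed=1, force_noise_sd=0.0),
        )
        u = wlc_extension(20.0, PolymerModel(1.0, 0.4, 298.0))
        assert truth["events"], "unit should unfold well within 50 s"
        step = truth["events"][0]["step_extension"]
        assert step == pytest.approx(38.6 * u, rel=1e-9)
        assert truth["extension_ratio"] == pytest.approx(u, rel=1e-9)

    def test_staircase_levels_match_event_log(self):
        poly = default_polyprotein("wt-azurin")
        trace, truth = simulate_force_clamp(
            poly, 25.0, 5.0, InstrumentConfig(rng_seed=9, force_noise_sd=0.0),
        )
        final = trace.extension[-1]
        u = truth["extension_ratio"]
        lc_final = truth["tether_contour_nm"] + sum(
            e["delta_Lc"] for e in truth["events"]
        )
        assert final == pytest.approx(u * lc_final, rel=1e-9)
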