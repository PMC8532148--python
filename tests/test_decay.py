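"""Decay-curve fitting: recovery, model selection, oracles, invariants."""

import numpy as np
import pytest
from scipy.optimize import minimize

import oliverelax as ox
from oliverelax.decay import FitError


def _curve(comps, kind, schedule, noise_level=0.0, seed=0, mhz=2.0):
    return ox.simulate_decay(
        tuple(ox.ExponentialComponent(a, t) for a, t in comps),
        kind,
        schedule,
        ox.NoiseSpec("relative_gaussian", noise_level, seed),
        larmor_mhz=mhz,
    )


class TestFitDecay:
    def test_noiseless_mono_cpmg_56ms(self):
        curve = _curve([(1.0, 0.056)], "cpmg", ox.SCHEDULES["cpmg_2mhz"])
        fit = ox.fit_decay(curve, 1)
        assert fit.converged and fit.model_kind == "mono"
        assert fit.components[0].time_constant == pytest.approx(0.056, rel=1e-4)
        assert fit.components[0].amplitude == pytest.approx(1.0, rel=1e-4)

    def test_noiseless_bi_cpmg_43_147ms(self):
        curve = _curve(
            [(1.0, 0.043), (1.0, 0.147)], "cpmg", ox.SCHEDULES["cpmg_2mhz"]
        )
        fit = ox.fit_decay(curve, 2)
        assert fit.converged
        t_a, t_b = (c.time_constant for c in fit.components)
        assert t_a == pytest.approx(0.043, rel=1e-4)
        assert t_b == pytest.approx(0.147, rel=1e-4)

    def test_noiseless_bi_inversion_recovery(self):
        curve = _curve(
            [(2.0, 0.05), (1.0, 0.2)], "inversion_recovery", ox.SCHEDULES["ir_2mhz"]
        )
        fit = ox.fit_decay(curve, 2)
        assert fit.converged
        assert fit.components[0].time_constant == pytest.approx(0.05, rel=1e-4)
        assert fit.components[1].time_constant == pytest.approx(0.2, rel=1e-4)
        assert ox.amplitude_ratio(fit) == pytest.approx(2.0, rel=1e-4)

    def test_constant_signal_fails_explicitly(self):
        curve = ox.DecayCurve(
            delays=np.linspace(0.01, 1.0, 12),
            magnetization=np.zeros(12),
            sequence_kind="cpmg",
            larmor_mhz=2.0,
        )
        fit = ox.fit_decay(curve, 1)
        assert not fit.converged
        assert "constant" in fit.message

    def test_too_few_points_fails(self):
        curve = ox.DecayCurve(
            delays=np.linspace(0.01, 1.0, 8),
            magnetization=np.exp(-np.linspace(0.01, 1.0, 8)),
            sequence_kind="cpmg",
            larmor_mhz=2.0,
        )
        fit = ox.fit_decay(curve, 2)
        assert not fit.converged and "points" in fit.message

    def test_invalid_component_count(self):
        curve = _curve([(1.0, 0.1)], "cpmg", ox.SCHEDULES["cpmg_2mhz"])
        with pytest.raises(FitError):
            ox.fit_decay(curve, 3)

    @pytest.mark.parametrize(
        "t_true, a_true",
        [(0.001, 0.1), (0.01, 1.0), (0.3, 5.0), (5.0, 10.0)],
    )
    def test_parameter_recovery_under_noise(self, t_true, a_true):
        """Median recovered T over 50 seeded replicates within 5 % of truth
        at 2 % relative noise, across the plausible (T, a) box."""
        sched = ox.log_schedule(t_true / 20, t_true * 8, 20)
        recovered = []
        for seed in range(50):
            curve = _curve(
                [(a_true, t_true)], "cpmg", sched, noise_level=0.02, seed=seed
            )
            fit = ox.fit_decay(curve, 1)
            if fit.converged:
                recovered.append(fit.components[0].time_constant)
        assert len(recovered) >= 45
        assert np.median(recovered) == pytest.approx(t_true, rel=0.05)

    def test_bi_rss_never_exceeds_mono_rss(self):
        for seed in range(5):
            curve = _curve(
                [(1.0, 0.04), (1.0, 0.15)],
                "cpmg",
                ox.SCHEDULES["cpmg_2mhz"],
                noise_level=0.02,
                seed=seed,
            )
            mono = ox.fit_decay(curve, 1)
            bi = ox.fit_decay(curve, 2)
            assert bi.residual_ss <= mono.residual_ss * (1 + 1e-9)

    def test_sorting_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t1 = rng.uniform(0.01, 0.1)
            t2 = t1 * rng.uniform(2, 8)
            curve = _curve(
                [(1.0, t1), (1.0, t2)],
                "cpmg",
                ox.SCHEDULES["cpmg_2mhz"],
                noise_level=0.01,
                seed=int(rng.integers(1e6)),
            )
            fit = ox.fit_decay(curve, 2)
            if fit.converged and len(fit.components) == 2:
                assert (
                    fit.components[0].time_constant
                    <= fit.components[1].time_constant
                )
                assert fit.component_labels == ("a", "b")

    def test_mono_fit_agrees_with_grid_search_oracle(self):
        """Dense (T, a) grid search plus local polish must agree with the
        production fitter within 0.1 % on random mono fixtures."""
        rng = np.random.default_rng(2021)
        for _ in range(20):
            t_true = rng.uniform(0.01, 0.5)
            a_true = rng.uniform(0.5, 5.0)
            sched = ox.log_schedule(t_true / 30, t_true * 10, 25)
            curve = _curve(
                [(a_true, t_true)],
                "cpmg",
                sched,
                noise_level=0.01,
                seed=int(rng.integers(1e6)),
            )
            fit = ox.fit_decay(curve, 1)
            assert fit.converged

            y, x = curve.magnetization, curve.delays
            w = 1.0 / curve.sigma

            def rss_at(t_const):
                basis = np.exp(-x / t_const)
                a = np.sum(w**2 * basis * y) / np.sum(w**2 * basis**2)
                return float(np.sum((w * (y - a * basis)) ** 2)), a

            grid = np.geomspace(t_true / 100, t_true * 100, 4000)
            best_t = min(grid, key=lambda t: rss_at(t)[0])
            res = minimize(
                lambda lg: rss_at(10.0 ** lg[0])[0],
                [np.log10(best_t)],
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14},
            )
            t_oracle = 10.0 ** res.x[0]
            assert fit.components[0].time_constant == pytest.approx(
                t_oracle, rel=1e-3
            )


class TestSelectModel:
    def test_mono_curve_selected_mono(self):
        curve = _curve([(1.0, 0.056)], "cpmg", ox.SCHEDULES["cpmg_2mhz"])
        assert ox.select_model(curve).model_kind == "mono"

    def test_bi_curve_with_separation_selected_bi(self):
        # time constants 3x apart, SNR 100 (1 % additive noise)
        comps = (
            ox.ExponentialComponent(1.0, 0.05),
            ox.ExponentialComponent(1.0, 0.15),
        )
        curve = ox.simulate_decay(
            comps,
            "cpmg",
            ox.SCHEDULES["cpmg_2mhz"],
            ox.NoiseSpec("additive_gaussian", 0.01, 3),
        )
        sel = ox.select_model(curve)
        assert sel.model_kind == "bi"
        # residual oracle: the bi model must actually fit better
        assert sel.residual_ss < ox.fit_decay(curve, 1).residual_ss

    def test_degenerate_equal_time_constants_selected_mono(self):
        curve = _curve(
            [(1.0, 0.08), (1.0, 0.08)], "cpmg", ox.SCHEDULES["cpmg_2mhz"]
        )
        assert ox.select_model(curve).model_kind == "mono"

    def test_deterministic(self):
        curve = _curve(
            [(1.0, 0.04), (1.0, 0.15)],
            "cpmg",
            ox.SCHEDULES["cpmg_2mhz"],
            noise_level=0.02,
            seed=5,
        )
        f1, f2 = ox.select_model(curve), ox.select_model(curve)
        assert f1.model_kind == f2.model_kind
        assert f1.components[0].time_constant == f2.components[0].time_constant


class TestAmplitudeRatio:
    @pytest.mark.parametrize(
        "a_short, a_long, expected", [(2.0, 1.0, 2.0), (1.0, 1.0, 1.0), (3.0, 2.0, 1.5)]
    )
    def test_examples(self, a_short, a_long, expected):
        fit = ox.RelaxationFit(
            components=(
                ox.ExponentialComponent(a_short, 0.05),
                ox.ExponentialComponent(a_long, 0.2),
            ),
            model_kind="bi",
            sequence_kind="inversion_recovery",
            larmor_mhz=2.0,
            converged=True,
        )
        assert ox.amplitude_ratio(fit) == pytest.approx(expected)

    def test_mono_fit_rejected(self):
        fit = ox.RelaxationFit(
            components=(ox.ExponentialComponent(1.0, 0.05),),
            model_kind="mono",
            sequence_kind="cpmg",
            larmor_mhz=2.0,
            converged=True,
        )
        with pytest.raises(FitError):
            ox.amplitude_ratio(fit)
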