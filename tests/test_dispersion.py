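"""Dispersion-profile assembly and composite-model fitting."""

import numpy as np
import pytest

import oliverelax as ox
from oliverelax.dispersion import DispersionError


def _fit(components, mhz, kind="inversion_recovery", sample_id="s"):
    return ox.RelaxationFit(
        components=tuple(ox.ExponentialComponent(a, t) for a, t in components),
        model_kind="bi" if len(components) == 2 else "mono",
        sequence_kind=kind,
        larmor_mhz=mhz,
        sample_id=sample_id,
        converged=True,
    )


class TestBuildDispersion:
    def test_single_ffc_point_is_reciprocal_t1(self):
        profile = ox.build_dispersion([_fit([(2.0, 0.1), (1.0, 0.3)], 1.0)])
        assert profile.freqs_mhz.tolist() == [1.0]
        assert profile.r1.tolist() == [10.0]

    def test_highfield_supplement_averages_ch_and_ch2(self):
        hf = [
            ("CH", _fit([(1.0, 0.873)], 400.0)),
            ("CH2", _fit([(1.0, 0.493)], 400.0)),
            ("CH3", _fit([(1.0, 0.740)], 400.0)),  # excluded from the mean
        ]
        profile = ox.build_dispersion(
            [_fit([(2.0, 0.1), (1.0, 0.3)], 1.0)], hf
        )
        assert profile.freqs_mhz.tolist() == [1.0, 400.0]
        assert profile.r1[-1] == pytest.approx((1 / 0.873 + 1 / 0.493) / 2)

    def test_empty_inputs_rejected(self):
        with pytest.raises(DispersionError):
            ox.build_dispersion([], [])

    def test_duplicate_frequencies_rejected(self):
        fits = [_fit([(1.0, 0.1)], 1.0), _fit([(1.0, 0.2)], 1.0)]
        with pytest.raises(DispersionError):
            ox.build_dispersion(fits, component="a")

    def test_missing_component_goes_to_gap_report(self):
        fits = [
            _fit([(2.0, 0.1), (1.0, 0.3)], 1.0),
            _fit([(1.0, 0.1)], 2.0),  # mono: no component "b"
        ]
        profile = ox.build_dispersion(fits, component="b")
        assert len(profile) == 1
        assert len(profile.meta["gaps"]) == 1
        assert "2.0 MHz" in profile.meta["gaps"][0]

    def test_points_sorted_by_frequency(self):
        fits = [
            _fit([(1.0, 0.1)], 5.0),
            _fit([(1.0, 0.2)], 0.5),
            _fit([(1.0, 0.15)], 2.0),
        ]
        profile = ox.build_dispersion(fits)
        assert np.all(np.diff(profile.freqs_mhz) > 0)


class TestFitDispersion:
    def test_recovers_reference_parameters_noiseless(self, at28_profile_30pt):
        res = ox.fit_dispersion(at28_profile_30pt, d_const=7.7e-12, seed=1)
        assert res.converged and not res.weakly_identified
        p = res.params
        assert p.bpp1.a_rot == pytest.approx(1.08e8, rel=0.01)
        assert p.bpp1.tau_rot == pytest.approx(1.5e-8, rel=0.01)
        assert p.bpp2.a_rot == pytest.approx(3.15e9, rel=0.01)
        assert p.bpp2.tau_rot == pytest.approx(2.15e-10, rel=0.01)

    def test_single_bpp_profile_drives_second_amplitude_to_zero(self):
        m = ox.DispersionModelParams(
            bpp1=ox.BPPParams(1.08e8, 1.5e-8),
            bpp2=ox.BPPParams(1e-12, 1.5e-10),
            sd=ox.SDParams(d_const=7.7e-12, a_sd=0.0),
        )
        profile = ox.simulate_dispersion(
            m,
            np.geomspace(0.01, 400, 30),
            ox.NoiseSpec("relative_gaussian", 0.0, 0),
        )
        res = ox.fit_dispersion(profile, d_const=7.7e-12, seed=4)
        assert res.converged
        a_big = res.params.bpp1.a_rot
        extras = sorted([res.params.bpp2.a_rot, a_big])
        assert extras[0] < 1e-3 * extras[1]

    def test_three_point_profile_rejected(self):
        profile = ox.DispersionProfile(
            freqs_mhz=np.array([0.01, 1.0, 100.0]), r1=np.array([10.0, 9.0, 1.0])
        )
        with pytest.raises(DispersionError):
            ox.fit_dispersion(profile, d_const=7.7e-12)

    def test_narrow_band_rejected(self):
        profile = ox.DispersionProfile(
            freqs_mhz=np.geomspace(1.0, 10.0, 12),
            r1=np.linspace(10.0, 9.0, 12),
        )
        with pytest.raises(DispersionError):
            ox.fit_dispersion(profile, d_const=7.7e-12)

    def test_weak_identification_flagged_for_close_correlation_times(self):
        m = ox.DispersionModelParams(
            bpp1=ox.BPPParams(1e8, 2e-9),
            bpp2=ox.BPPParams(1e8, 1e-9),  # tau ratio 2 < 3
            sd=ox.SDParams(d_const=7.7e-12, a_sd=0.0),
        )
        profile = ox.simulate_dispersion(
            m, np.geomspace(0.01, 400, 30), ox.NoiseSpec("relative_gaussian", 0.0, 0)
        )
        res = ox.fit_dispersion(profile, d_const=7.7e-12, a_sd_fixed=0.0, seed=9)
        if res.converged:
            assert res.weakly_identified or (
                res.params.bpp1.tau_rot / res.params.bpp2.tau_rot >= 3
            )

    def test_round_trip_profile_reproduction(self, at28_profile_30pt, at28_params):
        res = ox.fit_dispersion(at28_profile_30pt, d_const=7.7e-12, seed=1)
        refit = ox.simulate_dispersion(
            res.params,
            at28_profile_30pt.freqs_mhz,
            ox.NoiseSpec("relative_gaussian", 0.0, 0),
        )
        rel = np.abs(refit.r1 / at28_profile_30pt.r1 - 1)
        assert rel.max() < 1e-3

    def test_fitted_total_monotone_nonincreasing(self, at28_profile_30pt):
        res = ox.fit_dispersion(at28_profile_30pt, d_const=7.7e-12, seed=1)
        nu = np.geomspace(1e3, 1e9, 400)
        total = ox.composite_rate(res.params, nu)
        assert np.all(np.diff(total) <= 1e-12 * total[0])

    def test_low_frequency_plateau_when_all_motions_fast(self):
        # every correlation time (incl. translational) << 1/omega here,
        # so R1 must be flat between 10 and 20 kHz
        m = ox.DispersionModelParams(
            bpp1=ox.BPPParams(1.08e8, 1.5e-8),
            bpp2=ox.BPPParams(3.15e9, 2.15e-10),
            sd=ox.SDParams(d_const=7.7e-12, jump_distance=3e-11, a_sd=3e3),
        )
        r10 = ox.composite_rate(m, 1e4)
        r20 = ox.composite_rate(m, 2e4)
        assert abs(r10 / r20 - 1) < 0.02

    def test_noisy_parameter_recovery_medians(self, at28_params):
        """3 % noise, 20 seeds: recovered parameter medians within 10 %."""
        freqs = np.geomspace(0.01, 400, 30)
        rec = {"a1": [], "t1": [], "a2": [], "t2": []}
        for seed in range(20):
            profile = ox.simulate_dispersion(
                at28_params, freqs, ox.NoiseSpec("relative_gaussian", 0.03, seed)
            )
            res = ox.fit_dispersion(profile, d_const=7.7e-12, seed=seed)
            if not res.converged:
                continue
            rec["a1"].append(res.params.bpp1.a_rot)
            rec["t1"].append(res.params.bpp1.tau_rot)
            rec["a2"].append(res.params.bpp2.a_rot)
            rec["t2"].append(res.params.bpp2.tau_rot)
        assert len(rec["a1"]) >= 15
        assert np.median(rec["a1"]) == pytest.approx(1.08e8, rel=0.10)
        assert np.median(rec["t1"]) == pytest.approx(1.5e-8, rel=0.10)
        assert np.median(rec["a2"]) == pytest.approx(3.15e9, rel=0.10)
        assert np.median(rec["t2"]) == pytest.approx(2.15e-10, rel=0.10)


class TestDecomposeContributions:
    def test_all_zero_amplitudes(self):
        m = ox.DispersionModelParams(
            bpp1=ox.BPPParams(0.0, 1e-8),
            bpp2=ox.BPPParams(0.0, 1e-10),
            sd=ox.SDParams(d_const=7.7e-12, a_sd=0.0),
        )
        table = ox.decompose_contributions(m, [1e4, 1e6, 1e8])
        assert (table[["bpp1", "bpp2", "sd", "total"]].to_numpy() == 0).all()

    def test_total_equals_composite_rate(self, at28_params):
        freqs = [1e4, 1e7]
        table = ox.decompose_contributions(at28_params, freqs)
        for i, nu in enumerate(freqs):
            assert table["total"][i] == pytest.approx(
                ox.composite_rate(at28_params, nu), rel=1e-14
            )
        np.testing.assert_array_equal(
            table["total"], table["bpp1"] + table["bpp2"] + table["sd"]
        )

    def test_single_frequency(self, at28_params):
        table = ox.decompose_contributions(at28_params, [2e6])
        assert len(table) == 1
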