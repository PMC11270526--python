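"""Synthetic-data generator: limits, noise model, determinism, chaining."""

import numpy as np
import pytest

import sabrekin as sk
from sabrekin.errors import DomainError, InsufficientDataError
from .conftest import make_spec_b


class TestSimulateSexsy:
    def test_decoupled_limit_is_pure_recovery(self):
        # k_d = 0: bound pool does inverted recovery at R_bound, free pool
        # stays at its thermal value (it starts unpolarized only in the
        # model; here its initial value is 0 and recovers at R_free)
        spec = make_spec_b(k_d=0.0, ratio_r=4.0, R_bound=0.5, R_free=0.125)
        t = np.geomspace(0.02, 12.0, 24)
        ds = sk.simulate_sexsy(sk.SimulationConfig(spec=spec, d_mix=t, noise_sd=0.0))
        e_expect = 1.0 - 2.0 * np.exp(-0.5 * t)
        f_expect = 4.0 * (1.0 - np.exp(-0.125 * t))
        assert np.allclose(ds.pool("e"), e_expect, atol=1e-12)
        assert np.allclose(ds.pool("f"), f_expect, atol=1e-12)

    def test_noise_mean_is_noiseless_curve(self, spec_b_py280):
        t = np.geomspace(0.05, 8.0, 6)
        clean = sk.simulate_sexsy(
            sk.SimulationConfig(spec=spec_b_py280, d_mix=t, noise_sd=0.0)
        )
        n_rep, sd_cfg = 10_000, 0.05
        acc = np.zeros_like(clean.integrals)
        sds = []
        for i in range(n_rep):
            ds = sk.simulate_sexsy(
                sk.SimulationConfig(spec=spec_b_py280, d_mix=t, noise_sd=sd_cfg, seed=i)
            )
            acc += ds.integrals
            sds.append(ds.integrals)
        mean = acc / n_rep
        sd_abs = sd_cfg * np.abs(sk.build_generator(spec_b_py280).M0).max()
        sem = sd_abs / np.sqrt(n_rep)
        assert np.all(np.abs(mean - clean.integrals) < 3 * sem + 1e-12)
        # empirical sd calibrated within 5%
        emp_sd = np.std(np.stack(sds) - clean.integrals[None], axis=0)
        assert np.all(np.abs(emp_sd / sd_abs - 1) < 0.05)

    def test_free_pool_peak_time_closed_form(self):
        # in the hyperpolarized limit (negligible thermal magnetization) the
        # free-pool transfer curve is a pure biexponential difference with
        # peak time ln(k/R)/(k - R); choose rates giving (k, R) = (1.55, 0.15)
        r = 7.46
        kappa = 1.55 - 0.15  # exchange eigenvalue on top of uniform R = 0.15
        k_ex = kappa * r / (1 + r)
        spec = sk.ExchangeModelSpec(
            "B", sk.RateConstants(k_d=2 * k_ex), R_bound=0.15, R_free=0.15,
            ratio_r=r, P0=0.0,
        )
        gen = sk.build_generator(spec)
        state = sk.MagnetizationState(gen.pools, np.array([-1.0, 0.0]), gen.M0)
        t = np.linspace(1e-4, 12.0, 200_000)
        f = sk.propagate_grid(gen, state, t)[1]
        t_peak = t[np.argmax(np.abs(f))]
        expect = np.log(1.55 / 0.15) / (1.55 - 0.15)
        assert t_peak == pytest.approx(expect, rel=1e-3)

    def test_transferred_component_peaks_then_decays(self, spec_b_py280):
        # the exchange-transferred part of the free-pool signal (relative to
        # the no-exchange recovery) builds up to a maximum and then relaxes
        # away again
        t = np.geomspace(0.02, 80.0, 400)
        with_ex = sk.simulate_sexsy(
            sk.SimulationConfig(spec=spec_b_py280, d_mix=t, noise_sd=0.0)
        ).pool("f")
        no_ex = sk.simulate_sexsy(
            sk.SimulationConfig(spec=make_spec_b(k_d=0.0), d_mix=t, noise_sd=0.0)
        ).pool("f")
        transfer = np.abs(with_ex - no_ex)
        i_max = int(np.argmax(transfer))
        assert 0 < i_max < transfer.size - 1
        assert transfer[-1] < 0.05 * transfer[i_max]

    def test_seed_determinism_byte_for_byte(self, spec_b_py280):
        cfg = sk.SimulationConfig(spec=spec_b_py280, noise_sd=0.1, seed=7)
        a = sk.simulate_sexsy(cfg).to_frame().to_csv(index=False)
        b = sk.simulate_sexsy(cfg).to_frame().to_csv(index=False)
        assert a == b


class TestSimulateExsy:
    def test_zero_mixing_time(self, spec_b_py280):
        x = sk.simulate_exsy(sk.SimulationConfig(spec=spec_b_py280, noise_sd=0.0), 0.0)
        assert x.I_cross == 0.0
        assert (x.I_ee, x.I_ff) == pytest.approx((1.0, 7.46))

    def test_cross_peaks_equal_under_equal_relaxation(self):
        spec = make_spec_b(k_d=3.0, ratio_r=5.0, R_bound=0.3, R_free=0.3)
        gen = sk.build_generator(spec)
        from scipy.linalg import expm

        A = expm(-gen.L * 0.2)
        I = A * gen.M0[None, :]
        assert I[0, 1] == pytest.approx(I[1, 0], rel=1e-12)

    def test_long_mixing_time_decays_to_thermal_scale(self, spec_b_py280):
        x = sk.simulate_exsy(sk.SimulationConfig(spec=spec_b_py280, noise_sd=0.0), 60.0)
        # everything relaxed: integrals small compared to M0
        assert abs(x.I_ee) < 1e-3 and abs(x.I_cross) < 1e-3


class TestTemperatureSeries:
    def test_noiseless_recovery_pipeline(self, spec_b_py280):
        dH, dS = 70e3, 20.0
        cfg = sk.SimulationConfig(
            spec=spec_b_py280, d_mix=np.geomspace(0.02, 12, 24), noise_sd=0.0
        )
        datasets, truth = sk.simulate_temperature_series(
            dH, dS, [280, 283, 288, 293, 298], cfg
        )
        kds = [sk.fit_sexsy(ds, "B").estimates["k_d"] for ds in datasets]
        fit = sk.eyring_fit(sk.RateSeries(T=truth.T, k_d=np.array(kds)))
        assert fit.dH == pytest.approx(dH, rel=0.02)
        assert fit.dS == pytest.approx(dS, abs=0.02 * abs(dH) / 280)

    def test_generated_rates_monotone_increasing(self, spec_b_py280):
        cfg = sk.SimulationConfig(spec=spec_b_py280, noise_sd=0.0)
        ref = sk.eyring_fit(sk.reference.rate_series("Py", "kd_mean"))
        _, truth = sk.simulate_temperature_series(
            ref.dH, ref.dS, [280, 283, 288, 293, 298], cfg
        )
        assert np.all(np.diff(truth.k_d) > 0)

    def test_single_temperature_insufficient_for_eyring(self, spec_b_py280):
        cfg = sk.SimulationConfig(spec=spec_b_py280, noise_sd=0.0)
        _, truth = sk.simulate_temperature_series(70e3, 20.0, [288.0], cfg)
        with pytest.raises(InsufficientDataError):
            sk.eyring_fit(truth)

    def test_out_of_range_temperature_rejected(self, spec_b_py280):
        cfg = sk.SimulationConfig(spec=spec_b_py280, noise_sd=0.0)
        with pytest.raises(DomainError):
            sk.simulate_temperature_series(70e3, 20.0, [250.0, 280.0, 290.0], cfg)
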