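import math

import numpy as np
import pytest

from conftest import sample_posterior_z
from diffinfo.distributions import NormalizedObservation
from diffinfo.infogain import LN2, info_gain_acentric
from diffinfo.likelihood import (
    FWEstimate,
    ModelCalc,
    exact_llg,
    french_wilson,
    llg_fw,
    llgi,
    llgi_params,
    rms_llg_error,
)
from diffinfo.simulate import SimulationConfig, simulate


class TestFrenchWilson:
    @pytest.mark.parametrize("sigma_z,e_fw,sigma_fw", [
        (2.57, 0.91, 0.44),   # ~0.01-bit observation
        (1.33, 0.99, 0.41),   # ~0.1 bits
        (0.63, 1.25, 0.26),   # ~1 bit
        (0.21, 1.40, 0.08),   # ~3 bits
    ])
    def test_posterior_amplitude_moments(self, sigma_z, e_fw, sigma_fw):
        # reference values are 2 d.p. rounded; allow a unit in the last place
        est = french_wilson(NormalizedObservation(2.0, sigma_z))
        assert est.e_fw == pytest.approx(e_fw, abs=0.01)
        assert est.sigma_fw == pytest.approx(sigma_fw, abs=0.01)

    def test_exact_measurement_limit(self):
        est = french_wilson(NormalizedObservation(2.0, 1e-5))
        assert est.e_fw == pytest.approx(math.sqrt(2.0), rel=1e-6)
        assert est.sigma_fw < 1e-4

    def test_uninformative_limit_recovers_prior_moments(self):
        # posterior -> Wilson prior: mean E is Gamma(3/2) = sqrt(pi)/2
        est = french_wilson(NormalizedObservation(0.5, 1e4))
        assert est.e_fw == pytest.approx(math.sqrt(math.pi) / 2.0, rel=1e-3)

    @pytest.mark.parametrize("centric", [False, True])
    def test_matches_monte_carlo_sampling(self, centric, rng):
        obs = NormalizedObservation(1.3, 0.8, centric)
        z = sample_posterior_z(obs, 100_000, rng)
        e = np.sqrt(z)
        est = french_wilson(obs)
        se1 = e.std() / math.sqrt(e.size)
        assert est.e_fw == pytest.approx(e.mean(), abs=3.0 * se1)
        assert est.sigma_fw == pytest.approx(e.std(), rel=0.02)

    def test_negative_intensity_supported(self):
        est = french_wilson(NormalizedObservation(-1.0, 0.8))
        assert 0.0 < est.e_fw < 1.0 and est.sigma_fw > 0.0


class TestInflatedVarianceTarget:
    def test_null_model_scores_zero(self):
        fw = FWEstimate(0.9, 0.4)
        for e_c in np.linspace(0.0, 2.0, 9):
            assert llg_fw(fw, ModelCalc(e_c, 0.0)) == pytest.approx(0.0, abs=1e-12)
            assert llg_fw(fw, ModelCalc(e_c, 0.0), centric=True) == \
                pytest.approx(0.0, abs=1e-12)

    def test_weak_data_curve_still_peaks_away_from_zero(self):
        # the known failure mode: even for a 0.01-bit observation, the
        # amplitude-based target keeps favouring E_C near the Wilson mean
        fw = french_wilson(NormalizedObservation(2.0, 2.57))
        z_c = np.linspace(0.0, 4.0, 81)
        vals = [llg_fw(fw, ModelCalc(math.sqrt(z), 0.8)) for z in z_c]
        peak = z_c[int(np.argmax(vals))]
        assert peak > 0.1
        assert max(vals) - vals[0] > 1e-3


class TestLLGIParams:
    def test_no_error_limit(self):
        p = llgi_params(NormalizedObservation(2.0, 1e-4))
        assert p.d_obs == pytest.approx(1.0, abs=1e-3)
        assert p.e_e == pytest.approx(math.sqrt(2.0), rel=1e-3)

    def test_flat_likelihood_limit(self):
        p = llgi_params(NormalizedObservation(2.0, 1e3))
        assert p.d_obs < 0.05

    @pytest.mark.parametrize("centric", [False, True])
    def test_weight_within_unit_interval_across_conditions(self, centric):
        for z_o in (-1.0, 0.0, 1.0, 3.0):
            for s in (0.1, 0.7, 3.0):
                p = llgi_params(NormalizedObservation(z_o, s, centric))
                assert 0.0 <= p.d_obs <= 1.0 and p.e_e >= 0.0


class TestTargetAccuracy:
    Z_C_GRID = np.linspace(0.001, 4.0, 17)

    def _curve_devs(self, obs, sigma_a):
        fw = french_wilson(obs)
        params = llgi_params(obs)
        dev_fw, dev_i = 0.0, 0.0
        flat = []
        for z_c in self.Z_C_GRID:
            model = ModelCalc(math.sqrt(z_c), sigma_a)
            exact = exact_llg(obs, model)
            dev_fw = max(dev_fw, abs(llg_fw(fw, model, obs.centric) - exact))
            dev_i = max(dev_i, abs(llgi(params, model, obs.centric) - exact))
            flat.append(llgi(params, model, obs.centric))
        return dev_fw, dev_i, flat

    @pytest.mark.parametrize("centric", [False, True])
    @pytest.mark.parametrize("sigma_z", [0.21, 0.63, 1.33, 2.57])
    def test_llgi_tracks_exact_target(self, sigma_z, centric):
        obs = NormalizedObservation(2.0, sigma_z, centric)
        _, dev_i, _ = self._curve_devs(obs, 0.8)
        assert dev_i < 0.05

    def test_inflated_variance_error_dominates_and_grows_for_weak_data(self):
        devs = {}
        for sigma_z in (0.21, 0.63, 2.57):
            obs = NormalizedObservation(2.0, sigma_z)
            dev_fw, dev_i, _ = self._curve_devs(obs, 0.8)
            assert dev_fw >= dev_i
            devs[sigma_z] = dev_fw
        # the breakdown worsens as the information content falls
        assert devs[2.57] > devs[0.63] > devs[0.21]

    def test_negligible_information_gives_flat_llgi(self):
        obs = NormalizedObservation(2.0, 2.57)  # ~0.01 bits
        _, _, flat = self._curve_devs(obs, 0.8)
        assert max(abs(v) for v in flat) < 0.1
        assert max(flat) - min(flat) < 0.2

    def test_llgi_zero_weight_is_flat_zero(self):
        from diffinfo.likelihood import LLGIParams
        p = LLGIParams(1.0, 0.0)
        for z_c in (0.0, 1.0, 4.0):
            assert llgi(p, ModelCalc(math.sqrt(z_c), 0.8)) == pytest.approx(0.0, abs=1e-12)

    def test_zero_error_limit_reduces_to_plain_rice(self):
        obs = NormalizedObservation(2.0, 1e-5)
        params = llgi_params(obs)
        fw = french_wilson(obs)
        for z_c in (0.5, 1.0, 2.0):
            model = ModelCalc(math.sqrt(z_c), 0.8)
            assert llgi(params, model) == pytest.approx(llg_fw(fw, model), abs=1e-3)


class TestExactLLG:
    def test_null_model_scores_zero(self):
        obs = NormalizedObservation(1.5, 0.5)
        for e_c in (0.0, 0.7, 1.5):
            assert exact_llg(obs, ModelCalc(e_c, 0.0)) == pytest.approx(0.0, abs=1e-8)

    def test_cutoff_invariance(self):
        obs = NormalizedObservation(1.5, 0.449)
        model = ModelCalc(1.1, 0.8)
        assert exact_llg(obs, model, cutoff_scale=1.0) == pytest.approx(
            exact_llg(obs, model, cutoff_scale=2.0), abs=1e-7)

    def test_perfect_model_matches_gaussian_log_ratio(self):
        # sigma_A = 1 collapses the marginalization onto the calculated value
        obs = NormalizedObservation(1.5, 0.449)
        val = exact_llg(obs, ModelCalc(math.sqrt(1.2), 1.0))
        from diffinfo.distributions import obs_density
        expected = (-0.5 * ((1.5 - 1.2) / 0.449) ** 2
                    - math.log(0.449 * math.sqrt(2 * math.pi))
                    - math.log(obs_density(obs)))
        assert val == pytest.approx(expected, rel=1e-10)


class TestRmsError:
    def test_zero_error_limit_hits_chi_square_floor(self):
        # with a perfect model the score fluctuates as (1 - u^2)/2 with u
        # standard normal even for an exact measurement, so the r.m.s. LLG
        # spread tends to sqrt(1/2) nats rather than zero
        floor = math.sqrt(0.5) / LN2
        assert rms_llg_error(NormalizedObservation(2.0, 1e-4)) == pytest.approx(
            floor, rel=1e-3)

    def test_relative_error_exceeds_information_for_weak_data(self):
        # once the gain drops below ~1 bit the likelihood error out-scales it
        for z_o, s in [(1.5, 2.47), (2.0, 2.57), (0.5, 1.5)]:
            obs = NormalizedObservation(z_o, s)
            info = info_gain_acentric(z_o, s).bits
            assert info < 1.0
            assert rms_llg_error(obs) / info > 1.0

    def test_matches_monte_carlo(self, rng):
        obs = NormalizedObservation(1.5, 1.0)
        fw = french_wilson(obs)
        z = sample_posterior_z(obs, 100_000, rng)
        vals = np.array([llg_fw(fw, ModelCalc(e, 1.0)) for e in np.sqrt(z)])
        dev = vals - vals.mean()
        mc = math.sqrt(np.mean(dev**2)) / LN2
        se = np.std(dev**2) / math.sqrt(vals.size) / (2 * mc * LN2 * LN2)
        assert rms_llg_error(obs) == pytest.approx(mc, abs=3.0 * max(se, 1e-3))


class TestDatasetScaleRegression:
    def test_weak_reflection_errors_favour_intensity_target(self):
        """On a synthetic dataset with a perfect model, the cumulative error
        of the inflated-variance target over sub-0.01-bit reflections
        exceeds that of the moment-matched intensity target."""
        cfg = SimulationConfig(d_min=6.0, b_iso=80.0, noise_sigma=100.0,
                               seed=11, centric_zone="none")
        df = simulate(cfg)
        assert 1500 <= len(df) <= 3000
        z = df["IOBS"] / df["SIGMA_EXPECTED"]
        s = df["SIGIOBS"] / df["SIGMA_EXPECTED"]
        from diffinfo.infogain import info_gain_acentric_nats
        bits = info_gain_acentric_nats(z.to_numpy(), s.to_numpy()) / LN2
        weak = bits < 0.01
        assert weak.sum() > 30
        err_fw = err_i = 0.0
        mag_i = []
        for z_o, sig, e_true in zip(z[weak], s[weak], np.sqrt(df["Z_TRUE"][weak])):
            obs = NormalizedObservation(float(z_o), float(sig))
            model = ModelCalc(float(e_true), 1.0)
            exact = exact_llg(obs, model)
            err_fw += abs(llg_fw(french_wilson(obs), model) - exact)
            val_i = llgi(llgi_params(obs), model)
            err_i += abs(val_i - exact)
            mag_i.append(abs(val_i))
        assert err_fw > err_i
        # the intensity target stays close to zero for these reflections
        assert np.median(mag_i) < 0.1
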