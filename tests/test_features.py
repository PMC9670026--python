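"""Feature extraction: interpolation, smoothed derivatives, exponential fits."""

import numpy as np
import pytest

from aggsense.features import (
    derivative_trace,
    fit_exponentials,
    response_at,
    summary_features,
)
from aggsense.kinetics import InjectionProtocol, Sensorgram
from aggsense.presets import AGGREGATE_KINETICS, MONOMER_KINETICS
from tests.conftest import make_protocol


def _trace(response, protocol=None, t=None):
    if t is None:
        t = np.arange(float(len(response)))
    return Sensorgram(
        time=t, response=np.asarray(response, dtype=float),
        protocol=protocol or InjectionProtocol(t_end=float(t[-1])),
    )


class TestResponseAt:
    def test_exact_at_grid_and_midpoint(self):
        tr = _trace(np.concatenate([np.zeros(100), [10.0, 20.0], np.zeros(199)]))
        assert response_at(tr, 100.0) == 10.0
        assert response_at(tr, 100.5) == 15.0

    def test_out_of_range_raises(self):
        tr = _trace(np.zeros(301))
        with pytest.raises(ValueError):
            response_at(tr, 301.0)

    def test_ph74_endpoint_ratio_matches_decay(self, mixture_trace_factory):
        tr = mixture_trace_factory(0.0, ph=7.4)
        ratio = response_at(tr, 300.0) / response_at(tr, 110.0)
        assert ratio == pytest.approx(np.exp(-2.9e-5 * 190.0), rel=1e-6)


class TestDerivativeTrace:
    def test_constant_trace_zero_derivative(self):
        d = derivative_trace(_trace(np.full(301, 42.0)))
        np.testing.assert_allclose(d.response, 0.0, atol=1e-10)

    def test_linear_ramp_exact(self):
        t = np.arange(301.0)
        d = derivative_trace(_trace(2.0 * t, t=t))
        np.testing.assert_allclose(d.response, 2.0, atol=1e-9)

    def test_window_validation(self):
        tr = _trace(np.zeros(301))
        for w in (4, 1, 999):
            with pytest.raises(ValueError):
                derivative_trace(tr, w)

    def test_dissociation_slope_matches_analytic(self, mixture_trace_factory):
        """Smoothed derivative at dissociation start ~ -k_off * r0 (within a
        few % at 1 Hz; the window must not cross the phase boundary)."""
        tr = mixture_trace_factory(0.0, ph=3.8)
        d = derivative_trace(tr, 11)
        k = MONOMER_KINETICS[3.8].k_off
        t_probe = 117.0  # dissociation start + 7 s keeps the window inside
        r_probe = response_at(tr, t_probe)
        assert response_at(d, t_probe) == pytest.approx(-k * r_probe, rel=0.02)

    def test_derivative_integrates_back_to_trace(self, mixture_trace_factory):
        tr = mixture_trace_factory(0.2, ph=3.8)
        d = derivative_trace(tr, 11)
        # fundamental-theorem check over the smooth dissociation interior
        lo, hi = 120, 290
        integral = np.trapezoid(d.response[lo:hi + 1], tr.time[lo:hi + 1])
        assert integral == pytest.approx(
            tr.response[hi] - tr.response[lo], abs=0.01 * abs(tr.response[lo])
        )


class TestSummaryFeatures:
    def test_zero_trace_zero_features(self):
        proto = make_protocol(3.8, total=0.0)
        tr = _trace(np.zeros(301), protocol=proto)
        fs = summary_features(tr)
        assert fs.r_max_obs == fs.r_300 == fs.d_max == fs.d_112 == 0.0
        assert fs.assoc_params.degenerate and fs.dissoc_params.degenerate
        assert fs.assoc_params.rate == 0.0

    def test_d112_closer_to_zero_at_high_aggregate(self, mixture_trace_factory):
        lo = summary_features(mixture_trace_factory(0.01), with_exponentials=False)
        hi = summary_features(mixture_trace_factory(0.98), with_exponentials=False)
        assert lo.d_112 < hi.d_112 < 0.0

    def test_r300_increases_with_aggregate_fraction(self, mixture_trace_factory):
        vals = [
            summary_features(mixture_trace_factory(f), with_exponentials=False).r_300
            for f in (0.01, 0.2, 0.98)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_time_shift_invariance(self, species):
        from aggsense.synthetic import simulate_mixture

        base = make_protocol(3.8, fraction=0.2)
        shifted = InjectionProtocol(
            t_baseline_end=base.t_baseline_end, t_assoc_end=base.t_assoc_end,
            t_end=base.t_end, ph=base.ph, concentrations=base.concentrations,
        )
        tr = simulate_mixture(base, species, None)
        fs = summary_features(tr, with_exponentials=False)
        tr2 = Sensorgram(time=tr.time + 50.0, response=tr.response,
                         protocol=shifted, metadata={})
        tr2.protocol = InjectionProtocol(
            t_baseline_end=60.0, t_assoc_end=160.0, t_end=350.0, ph=3.8,
            concentrations=base.concentrations,
        )
        fs2 = summary_features(tr2, with_exponentials=False)
        assert fs2.r_max_obs == pytest.approx(fs.r_max_obs)
        assert fs2.d_112 == pytest.approx(fs.d_112)

    def test_response_scaling_equivariance(self, mixture_trace_factory):
        tr = mixture_trace_factory(0.2)
        fs = summary_features(tr, with_exponentials=False)
        tr2 = Sensorgram(time=tr.time, response=3.0 * tr.response,
                         protocol=tr.protocol)
        fs2 = summary_features(tr2, with_exponentials=False)
        for name in ("r_max_obs", "r_300", "d_max", "d_112"):
            assert getattr(fs2, name) == pytest.approx(3.0 * getattr(fs, name))


class TestFitExponentials:
    def test_self_fit_recovers_parameters(self):
        t = np.arange(301.0)
        proto = InjectionProtocol()
        y = np.zeros(301)
        dissoc = t >= proto.t_assoc_end
        td = t[dissoc] - proto.t_assoc_end
        y[dissoc] = 50.0 + 450.0 * np.exp(-0.01 * td)
        fit = fit_exponentials(_trace(y, protocol=proto), "dissociation")
        assert fit.offset == pytest.approx(50.0, rel=1e-3)
        assert fit.amplitude == pytest.approx(450.0, rel=1e-3)
        assert fit.rate == pytest.approx(0.01, rel=1e-3)
        assert fit.rms < 1e-6

    def test_pure_dissociation_correspondence(self, mixture_trace_factory):
        """For a single-species 1:1 trace the dissociation IS this family:
        offset ~ 0, rate ~ k_off, amplitude ~ response at dissociation start."""
        tr = mixture_trace_factory(0.0, ph=3.8)
        fit = fit_exponentials(tr, "dissociation")
        assert abs(fit.offset) < 1.0
        assert fit.rate == pytest.approx(MONOMER_KINETICS[3.8].k_off, rel=0.01)
        assert fit.amplitude == pytest.approx(response_at(tr, 110.0), rel=0.01)

    def test_constant_trace_degenerate(self):
        fit = fit_exponentials(_trace(np.full(301, 7.0)), "dissociation")
        assert fit.degenerate and fit.rate == 0.0 and fit.amplitude == 0.0

    def test_mixture_effective_rate_between_species_rates(self, mixture_trace_factory):
        k_m = MONOMER_KINETICS[3.8].k_off
        k_a = AGGREGATE_KINETICS[3.8].k_off
        rates = []
        for f in (0.05, 0.2, 0.6, 0.98):
            _, dfit = fit_exponentials(mixture_trace_factory(f))
            rates.append(dfit.rate)
            assert k_a < dfit.rate < k_m
        assert all(np.diff(rates) < 0)  # slower effective decay with more aggregate
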