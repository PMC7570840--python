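"""Feature definitions checked against direct loop-based evaluations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricetact.features import (
    FEATURE_LETTERS,
    box_dimension,
    dimensional_features,
    dimensionless_features,
    extract_features,
    hurst_exponent,
)


def loop_dimensional(x):
    """Straightforward loop transcription of the five dimensional statistics."""
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    std = math.sqrt(var)
    rms = math.sqrt(sum(v * v for v in x) / n)
    pk = max(x) - min(x)
    return mean, var, std, rms, pk


def loop_dimensionless(x):
    n = len(x)
    mean, var, std, rms, pk = loop_dimensional(x)
    kurt = sum((v - mean) ** 4 for v in x) / n / var**2
    skew = sum((v - mean) ** 3 for v in x) / n / std**3
    clearance = (sum(math.sqrt(abs(v)) for v in x) / n) ** 2
    return kurt, skew, rms / abs(mean), pk / abs(mean), pk / rms, pk / clearance


class TestDimensional:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([4.49] * 32, (4.49, 0.0, 0.0, 4.49, 0.0)),
            ([1.0, 3.0], (2.0, 1.0, 1.0, math.sqrt(5), 2.0)),
            ([0.0, 0.0, 0.0, 4.0], (1.0, 3.0, math.sqrt(3), 2.0, 4.0)),
        ],
    )
    def test_hand_computed_values(self, x, expected):
        got = dimensional_features(x)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_loop_oracle_on_random_signals(self, rng):
        for _ in range(100):
            x = rng.normal(4.5, 0.5, size=rng.integers(8, 200))
            got = dimensional_features(x)
            assert np.allclose(got, loop_dimensional(list(x)), rtol=1e-12)

    def test_moment_identities(self, rng):
        for _ in range(20):
            x = rng.normal(size=64)
            mean, var, std, rms, _ = dimensional_features(x)
            assert var == std**2
            assert rms**2 == pytest.approx(mean**2 + var, rel=1e-12)
            assert rms >= abs(mean)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            dimensional_features([])


class TestDimensionless:
    def test_constant_signal_limits(self):
        kurt, skew, wf, pf, cf, mf = dimensionless_features([4.49] * 32)
        assert wf == pytest.approx(1.0)
        assert (pf, cf, mf) == (0.0, 0.0, 0.0)

    def test_two_point_signal(self):
        kurt, skew, wf, *_ = dimensionless_features([1.0, 3.0])
        assert kurt == pytest.approx(1.0)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert wf == pytest.approx(math.sqrt(5) / 2)

    def test_loop_oracle_on_random_signals(self, rng):
        for _ in range(100):
            x = rng.normal(4.5, 0.5, size=rng.integers(8, 200))
            got = dimensionless_features(x)
            assert np.allclose(got, loop_dimensionless(list(x)), rtol=1e-12)

    def test_gaussian_moments(self, rng):
        x = rng.normal(size=100_000)
        kurt, skew, *_ = dimensionless_features(x + 10.0)
        assert kurt == pytest.approx(3.0, abs=0.1)
        assert skew == pytest.approx(0.0, abs=0.05)

    def test_near_constant_positive_trace_factor_magnitude(self, rng):
        # A ~4.49 V trace with millivolt fluctuations: the pulse factor is
        # PK/mu, three orders of magnitude below one.
        x = 4.4887 + 1e-3 * rng.standard_normal(2048)
        _, _, wf, pf, cf, mf = dimensionless_features(x)
        assert wf == pytest.approx(1.0, abs=1e-5)
        assert 5e-4 < pf < 5e-3
        assert pf == pytest.approx(cf, rel=1e-4)
        assert pf == pytest.approx(mf, rel=1e-3)

    def test_scale_invariance(self, rng):
        x = 4.5 + 0.01 * rng.standard_normal(512)
        base = np.array(dimensionless_features(x))
        for k in (0.5, 3.0, 1e3):
            scaled = np.array(dimensionless_features(k * x))
            assert np.allclose(scaled, base, rtol=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        xs=st.lists(
            st.floats(min_value=1.0, max_value=10.0), min_size=4, max_size=64
        ),
        k=st.floats(min_value=0.05, max_value=50.0),
    )
    def test_scale_invariance_property(self, xs, k):
        base = np.array(dimensionless_features(xs))
        scaled = np.array(dimensionless_features([k * v for v in xs]))
        assert np.allclose(scaled, base, rtol=1e-9, atol=1e-12)

    def test_zero_mean_is_an_error(self):
        with pytest.raises(ValueError):
            dimensionless_features([-1.0, 1.0])

    def test_max_peak_mode(self, rng):
        x = 4.5 + 0.01 * rng.standard_normal(512)
        _, _, _, pf, cf, _ = dimensionless_features(x, peak_mode="max")
        # max(x)/mu is pinned near one for a near-constant positive trace
        assert pf == pytest.approx(1.0, abs=0.01)


class TestFractal:
    def test_smooth_curves_have_dimension_one(self):
        t = np.linspace(0, 1, 4096)
        assert box_dimension(np.full(4096, 2.5)) == pytest.approx(1.0, abs=0.1)
        assert box_dimension(1.0 + 0.5 * t) == pytest.approx(1.0, abs=0.1)

    def test_brownian_graph_dimension(self, rng):
        dims = [
            box_dimension(np.cumsum(rng.standard_normal(4096))) for _ in range(10)
        ]
        assert np.mean(dims) == pytest.approx(1.5, abs=0.15)

    def test_direct_grid_count_oracle(self, rng):
        # Independent oracle: rasterise the polyline onto a delta-grid and
        # count occupied cells, then regress as the estimator does.
        x = np.cumsum(rng.standard_normal(4096))
        xn = (x - x.min()) / (x.max() - x.min())
        t = np.arange(x.size) / (x.size - 1)
        deltas = 2.0 ** -np.arange(2, 8)
        logs = []
        for d in deltas:
            cells = set()
            for i in range(x.size - 1):
                for f in np.linspace(0, 1, 8):
                    ti = t[i] + f * (t[i + 1] - t[i])
                    xi = xn[i] + f * (xn[i + 1] - xn[i])
                    cells.add((min(int(ti / d), int(1 / d) - 1),
                               min(int(xi / d), int(1 / d) - 1)))
            logs.append(np.log(len(cells)))
        oracle = np.polyfit(np.log(1.0 / deltas), logs, 1)[0]
        assert box_dimension(x) == pytest.approx(oracle, abs=0.12)

    def test_box_dimension_in_valid_range(self, rng):
        for _ in range(5):
            d = box_dimension(rng.standard_normal(512))
            assert 1.0 <= d <= 2.0 + 0.05

    def test_white_noise_hurst(self, rng):
        estimates = [hurst_exponent(rng.standard_normal(4096)) for _ in range(10)]
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.1)

    @pytest.mark.parametrize("h", [0.3, 0.5, 0.7, 0.9])
    def test_fgn_parameter_recovery(self, h, rng):
        from ricetact.signals import fractional_gaussian_noise

        estimates = [
            hurst_exponent(fractional_gaussian_noise(h, 4096, rng))
            for _ in range(10)
        ]
        assert np.mean(estimates) == pytest.approx(h, abs=0.1)

    @pytest.mark.parametrize("h", [0.3, 0.5, 0.7, 0.9])
    def test_fbm_graph_dimension(self, h, rng):
        from ricetact.signals import fractional_brownian_motion

        dims = [
            box_dimension(fractional_brownian_motion(h, 4096, rng))
            for _ in range(10)
        ]
        assert np.mean(dims) == pytest.approx(2.0 - h, abs=0.15)

    def test_too_few_scales_rejected(self, rng):
        with pytest.raises(ValueError):
            box_dimension(rng.standard_normal(256), scales=[0.25, 0.125])
        with pytest.raises(ValueError):
            hurst_exponent(rng.standard_normal(256), window_sizes=[8, 16])


class TestComposition:
    def test_composition_matches_suboperations(self, rng):
        x = 4.5 + 0.01 * np.cumsum(rng.standard_normal(512))
        fv = extract_features(x)
        assert fv.to_array()[:5] == pytest.approx(dimensional_features(x), rel=1e-12)
        assert fv.to_array()[5:11] == pytest.approx(dimensionless_features(x), rel=1e-12)
        assert fv.box_dimension == box_dimension(x)
        assert fv.hurst_exponent == hurst_exponent(x)

    def test_letter_indexing(self, rng):
        x = 4.5 + 0.01 * rng.standard_normal(256)
        fv = extract_features(x)
        assert fv["b"] == fv.variance
        assert fv["m"] == fv.hurst_exponent
        assert len(FEATURE_LETTERS) == 13
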