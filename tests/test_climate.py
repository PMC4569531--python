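"""P:E, AIC model selection, climate envelope and height classes."""
import numpy as np
import pandas as pd
import pytest

from tallstand import (
    classify_height_class,
    climate_envelope,
    fit_agc_climate,
    gaussian_aic,
    pe_ratio,
)
from tallstand.errors import (
    DegenerateEnvelopeError,
    InsufficientDataError,
    SingularDesignError,
)


class TestPeRatio:
    @pytest.mark.parametrize("p,e,expected", [(1000, 1000, 1.0), (500, 1000, 0.5)])
    def test_scalar(self, p, e, expected):
        assert pe_ratio(p, e) == expected

    def test_zero_evaporation_rejected(self):
        with pytest.raises(ValueError):
            pe_ratio(1000, 0)

    def test_vector_matches_scalar_loop(self, rng):
        p = rng.uniform(800, 2000, 30)
        e = rng.uniform(600, 1800, 30)
        got = pe_ratio(p, e)
        for i in range(30):
            assert got[i] == pytest.approx(p[i] / e[i], rel=1e-15)


def synth_frame(n=46, slope=-14.3, noise=60.0, seed=0):
    rng = np.random.default_rng(seed)
    mat = rng.uniform(6.6, 20.5, n)
    return pd.DataFrame(
        {
            "mat": mat,
            "map": rng.uniform(853, 1895, n),
            "pe": rng.uniform(0.6, 2.0, n),
            "agc": 400.0 + slope * (mat - 6.0) + rng.normal(0, noise, n),
        }
    )


class TestAgcClimateFit:
    def test_noiseless_linear_data_recovered_exactly(self):
        mat = np.arange(6.0, 20.5, 1.0)
        frame = pd.DataFrame(
            {"mat": mat, "map": np.linspace(900, 1800, len(mat)),
             "pe": np.linspace(0.7, 1.9, len(mat)),
             "agc": 400.0 - 14.0 * (mat - 6.0)}
        )
        fits = fit_agc_climate(frame)
        best = fits[0]
        assert best.predictors == ("mat",)
        assert best.coefficients["mat"] == pytest.approx(-14.0, abs=1e-8)
        assert best.coefficients["intercept"] == pytest.approx(400.0 + 14.0 * 6.0, abs=1e-7)
        assert best.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_selects_null(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(
            {"mat": rng.uniform(6, 20, 40), "map": rng.uniform(900, 1800, 40),
             "pe": rng.uniform(0.6, 2.0, 40), "agc": np.full(40, 300.0)}
        )
        fits = fit_agc_climate(frame)
        # the penalty dominates: no slope model can beat the exact null fit
        assert fits[0].predictors == ()

    def test_aic_matches_direct_loglik_formula(self):
        # fixed 10-point fixture
        frame = pd.DataFrame(
            {
                "mat": [6.8, 8.1, 9.9, 11.3, 12.6, 14.0, 15.8, 17.1, 18.9, 20.2],
                "map": [1400, 950, 1650, 1200, 1750, 1000, 1500, 1300, 1600, 1450],
                "pe": [1.9, 0.8, 1.7, 1.1, 1.8, 0.7, 1.2, 0.9, 1.0, 0.8],
                "agc": [392.0, 355.0, 341.0, 310.0, 330.0, 262.0, 271.0, 230.0, 215.0, 189.0],
            }
        )
        fits = {f.predictors: f for f in fit_agc_climate(frame)}
        for preds, fit in fits.items():
            # independent oracle: refit with polyfit-style lstsq and plug into
            # n(ln 2pi + ln(RSS/n) + 1) + 2k
            X = np.column_stack([np.ones(10)] + [frame[p] for p in preds])
            beta, *_ = np.linalg.lstsq(X, frame["agc"], rcond=None)
            rss = float(np.sum((frame["agc"] - X @ beta) ** 2))
            k = len(preds) + 2
            expected = 10 * (np.log(2 * np.pi) + np.log(rss / 10) + 1) + 2 * k
            assert fit.aic == pytest.approx(expected, abs=1e-8)

    def test_coefficients_match_statsmodels(self):
        import statsmodels.api as sm

        frame = synth_frame(seed=5)
        fit = {f.predictors: f for f in fit_agc_climate(frame)}[("mat",)]
        ref = sm.OLS(frame["agc"], sm.add_constant(frame["mat"])).fit()
        assert fit.coefficients["intercept"] == pytest.approx(ref.params["const"], rel=1e-9)
        assert fit.coefficients["mat"] == pytest.approx(ref.params["mat"], rel=1e-9)
        assert fit.r2 == pytest.approx(ref.rsquared, rel=1e-9)

    def test_ranking_invariant_to_response_shift(self):
        frame = synth_frame(seed=7)
        order = [f.predictors for f in fit_agc_climate(frame)]
        shifted = frame.assign(agc=frame["agc"] + 500.0)
        assert [f.predictors for f in fit_agc_climate(shifted)] == order

    def test_singular_design_names_collinear_predictor(self):
        frame = synth_frame(seed=3)
        frame["map"] = 2.0 * frame["mat"]
        with pytest.raises(SingularDesignError, match="map"):
            fit_agc_climate(frame, candidate_sets=((), ("mat", "map")))

    def test_too_few_points_rejected(self):
        frame = synth_frame(n=3)
        with pytest.raises(InsufficientDataError):
            fit_agc_climate(frame, candidate_sets=(("mat", "map"),))

    def test_delta_aic_and_equivalent_support_flags(self):
        fits = fit_agc_climate(synth_frame(seed=1))
        assert fits[0].delta_aic == 0.0
        assert fits[0].equivalent_support
        assert all(f.delta_aic >= 0 for f in fits)

    def test_mat_model_selected_under_simulated_gradient(self):
        wins = 0
        for seed in range(20):
            fits = fit_agc_climate(synth_frame(seed=seed))
            wins += fits[0].predictors == ("mat",)
        assert wins >= 18


class TestClimateEnvelope:
    def reference(self, rng, n=40):
        return np.column_stack([rng.uniform(6, 21, n), rng.uniform(850, 1900, n)])

    def test_reference_point_is_inside_with_zero_distance_on_hull(self, rng):
        ref = self.reference(rng)
        from scipy.spatial import ConvexHull

        hull_vertex = ref[ConvexHull((ref - ref.mean(0)) / ref.std(0)).vertices[0]]
        placement = climate_envelope(ref, hull_vertex)
        assert placement.inside
        assert placement.distance == pytest.approx(0.0, abs=1e-9)

    def test_interior_point_is_inside(self, rng):
        ref = self.reference(rng)
        placement = climate_envelope(ref, ref.mean(axis=0))
        assert placement.inside and placement.distance > 0

    def test_extreme_query_is_outside(self, rng):
        ref = self.reference(rng)
        placement = climate_envelope(ref, (40.0, 1400.0))
        assert not placement.inside

    def test_membership_agrees_with_half_plane_oracle(self):
        rng = np.random.default_rng(21)
        ref = self.reference(rng, n=25)
        mu, sd = ref.mean(0), ref.std(0)
        z = (ref - mu) / sd

        def oracle_inside(q):
            # exhaustive check: q is in the hull iff for every directed pair
            # of reference points whose line supports the cloud, q is on the
            # same (inner) side
            qz = (np.asarray(q) - mu) / sd
            for i in range(len(z)):
                for j in range(len(z)):
                    if i == j:
                        continue
                    d = z[j] - z[i]
                    normal = np.array([-d[1], d[0]])
                    side = (z - z[i]) @ normal
                    if np.all(side <= 1e-12):  # supporting line
                        if (qz - z[i]) @ normal > 1e-9:
                            return False
            return True

        queries = np.column_stack([rng.uniform(0, 28, 50), rng.uniform(500, 2300, 50)])
        for q in queries:
            assert climate_envelope(ref, q).inside == oracle_inside(q)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(DegenerateEnvelopeError):
            climate_envelope([(10.0, 1000.0), (12.0, 1100.0)], (11.0, 1050.0))
        collinear = [(t, 1000.0) for t in (8.0, 10.0, 12.0, 14.0)]
        with pytest.raises(DegenerateEnvelopeError):
            climate_envelope(collinear, (11.0, 1000.0))


class TestHeightClasses:
    @pytest.mark.parametrize(
        "height,label",
        [(46.0, ">45 m"), (35.0, "35-45 m"), (25.0, "25-35 m"), (44.999, "35-45 m"),
         (20.0, "below-range")],
    )
    def test_half_open_convention(self, height, label):
        assert classify_height_class(height) == label

    def test_grid_matches_interval_scan_oracle(self):
        classes = [(25.0, 35.0), (35.0, 45.0), (45.0, float("inf"))]
        for h in np.arange(20.0, 80.5, 0.5):
            got = classify_height_class(float(h))
            expected = "below-range"
            for lo, hi in classes:
                if lo <= h < hi:
                    expected = f">{lo:g} m" if np.isinf(hi) else f"{lo:g}-{hi:g} m"
            assert got == expected

    def test_rejects_non_positive_height(self):
        with pytest.raises(ValueError):
            classify_height_class(0.0)


def test_gaussian_aic_perfect_fit_is_minus_inf():
    assert gaussian_aic(10, 0.0, 3) == float("-inf")
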