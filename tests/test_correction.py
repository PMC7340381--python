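"""Generalized PN loop: fits, scores, combination, closed-loop recovery."""

import numpy as np
import pytest

from starletao import (
    InvalidArgumentError,
    NoInformationError,
    ZernikeAberration,
    combine_candidates,
    correct_mode,
    fit_parabola,
    random_unit_aberration,
    run_pn,
    score_fit,
    simulated_image_source,
)
from starletao.correction import EPSILON_FLOOR


class TestFitParabola:
    def test_exact_parabola_recovered(self):
        x = np.array([-1, -0.5, 0, 0.5, 1])
        y = (x - 0.3) ** 2
        fit = fit_parabola(x, y)
        assert fit.vertex == pytest.approx(0.3, abs=1e-12)
        assert fit.residual == pytest.approx(0.0, abs=1e-12)

    def test_negative_concavity_handled_identically(self):
        x = np.array([-1, -0.5, 0, 0.5, 1])
        y = -((x + 0.2) ** 2) + 1.0
        fit = fit_parabola(x, y)
        assert fit.vertex == pytest.approx(-0.2, abs=1e-12)

    def test_pure_line_is_non_informative(self):
        x = np.linspace(-1, 1, 7)
        y = 2.0 * x + 1.0
        fit = fit_parabola(x, y)
        assert not fit.informative
        assert fit.score == 0.0
        assert np.isnan(fit.vertex)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_parabola([0, 1], [0, 1])

    def test_duplicate_biases_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_parabola([0, 0, 1], [0, 1, 2])


class TestScoreFit:
    def test_printed_formula(self):
        assert score_fit(1.0, 0.5, 0.1) == pytest.approx(0.125 / 0.1)

    def test_zero_dynamic_range_scores_zero(self):
        assert score_fit(0.7, 0.7, 0.01) == 0.0
        assert score_fit(0.0, 0.0, 0.01) == 0.0

    def test_perfect_fit_uses_epsilon_floor(self):
        s = score_fit(1.0, 0.5, 0.0)
        assert s == pytest.approx(0.125 / EPSILON_FLOOR)
        assert np.isfinite(s)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(InvalidArgumentError):
            score_fit(0.1, 0.5, 0.01)


class TestCombineCandidates:
    @pytest.mark.parametrize(
        "vertices,scores,expected",
        [
            ([1, 2, 3, 4], [1, 1, 1, 1], 2.5),
            ([1, 2, 3, 4], [0, 5, 0, 0], 2.0),
            ([0, 1], [1, 3], 0.75),
        ],
    )
    def test_weighted_means(self, vertices, scores, expected):
        assert combine_candidates(vertices, scores) == pytest.approx(expected)

    def test_all_zero_scores_rejected(self):
        with pytest.raises(NoInformationError):
            combine_candidates([1.0, 2.0], [0.0, 0.0])

    def test_combination_in_convex_hull(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.uniform(-2, 2, 4)
            s = rng.uniform(0, 10, 4)
            c = combine_candidates(v, s)
            assert v.min() - 1e-12 <= c <= v.max() + 1e-12


class CountingSource:
    """Wraps an image source and counts images consumed."""

    def __init__(self, source):
        self.source = source
        self.calls = 0

    def __call__(self, correction):
        self.calls += 1
        return self.source(correction)


class TestCorrectMode:
    def test_budget_and_fit_count(self, config, filament_object):
        source = CountingSource(
            simulated_image_source(filament_object, config, ZernikeAberration())
        )
        rec = correct_mode(source, 7, p=7)
        assert source.calls == 7
        assert rec.images_used == 7
        assert len(rec.fits) == 4  # depth 5, finest skipped

    def test_null_aberration_fixed_point(self, config, filament_object):
        source = simulated_image_source(filament_object, config, ZernikeAberration())
        rec = correct_mode(source, 7)
        assert abs(rec.correction) <= 0.05

    def test_moderate_single_mode_recovery(self, config, filament_object):
        """A hidden -0.3 rad coma is recovered to better than 0.1 rad."""
        true = ZernikeAberration({7: -0.3})
        source = simulated_image_source(filament_object, config, true)
        rec = correct_mode(source, 7)
        assert rec.correction == pytest.approx(0.3, abs=0.1)

    def test_large_single_mode_recovery_tracks_estimator(self, config, filament_object):
        """A hidden -0.5 rad aberration with a +/-1 rad scan sits in the
        regime where the least-squares parabola's vertex overshoots a
        peaked response: fitting an idealized unit-width peak centered at
        +0.5 with the same 7 samples predicts the overshoot.  The
        closed-loop estimate must agree with that estimator model and
        carry the right sign and magnitude."""
        x = np.linspace(-1, 1, 7)
        a, b, _ = np.polyfit(x, np.exp(-((x - 0.5) ** 2)), 2)
        toy_vertex = -b / (2 * a)  # ~0.63: the estimator's intrinsic bias
        true = ZernikeAberration({7: -0.5})
        source = simulated_image_source(filament_object, config, true)
        rec = correct_mode(source, 7)
        assert rec.correction == pytest.approx(toy_vertex, abs=0.1)
        assert 0.4 <= rec.correction <= 0.75

    def test_rejects_bad_parameters(self, config, filament_object):
        source = simulated_image_source(filament_object, config, ZernikeAberration())
        with pytest.raises(InvalidArgumentError):
            correct_mode(source, 7, p=2)
        with pytest.raises(InvalidArgumentError):
            correct_mode(source, 7, bias_amplitude=0.0)


class TestRunPN:
    def test_image_budget_two_rounds(self, config, blob_object):
        source = CountingSource(
            simulated_image_source(blob_object, config, ZernikeAberration())
        )
        result = run_pn(source, p=5, rounds=2)
        n_modes = 7
        assert result.total_images == 2 * 5 * n_modes
        assert source.calls == result.total_images

    def test_zero_aberration_stays_near_zero(self, config, filament_object):
        source = simulated_image_source(filament_object, config, ZernikeAberration())
        result = run_pn(source)
        assert result.correction.rms() <= 0.05

    def test_single_round_reduces_residual(self, config, filament_object):
        """One round cuts a 1 rad rms injected aberration to well under
        half, in the median over a handful of random directions."""
        residuals = []
        for seed in range(5):
            true = random_unit_aberration(seed=seed)
            source = simulated_image_source(filament_object, config, true)
            result = run_pn(source)
            residuals.append((true + result.correction).rms() / true.rms())
        assert np.median(residuals) <= 0.4

    def test_second_round_refines_first(self, config, blob_object):
        """Median residual is non-increasing round over round (20 trials)."""
        r0, r1, r2 = [], [], []
        for seed in range(20):
            true = random_unit_aberration(seed=seed)
            source = simulated_image_source(blob_object, config, true)
            one = run_pn(source, rounds=1)
            two = run_pn(source, rounds=1, initial_correction=one.correction)
            r0.append(true.rms())
            r1.append((true + one.correction).rms())
            r2.append((true + two.correction).rms())
        assert np.median(r1) <= np.median(r0)
        assert np.median(r2) <= np.median(r1)

    def test_report_is_serializable(self, config, blob_object):
        import json

        true = random_unit_aberration(seed=5).scaled(0.5)
        source = simulated_image_source(blob_object, config, true)
        result = run_pn(source, p=5, mode_order=(11, 5, 6))
        text = json.dumps(result.to_dict())
        assert "metric_history" in text

    def test_empty_mode_order_rejected(self, config, blob_object):
        source = simulated_image_source(blob_object, config, ZernikeAberration())
        with pytest.raises(InvalidArgumentError):
            run_pn(source, mode_order=())
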