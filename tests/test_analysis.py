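"""Tuning-curve statistics: argmax preferences, averaging, scale transforms, fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numspike import (
    AverageTuningCurve,
    TuningCurve,
    average_normalized_curves,
    compute_tuning_curves,
    fit_gaussian,
    mean_r2_per_scale,
    preference_distribution,
    sigma_vs_preference,
    transform_scale,
)
from numspike.analysis import GaussianFit, _gaussian, curve_skewness, trials_to_frame
from numspike.errors import (
    EmptyResultError,
    FitDegenerateError,
    MissingClassError,
    MissingScaleError,
)
from numspike.network import TrialResult

CLASSES = np.arange(1, 6)


def _trial(label: int, rates) -> TrialResult:
    rates = np.asarray(rates, dtype=float)
    return TrialResult(
        spike_counts=(rates * 2).astype(int),
        rates=rates,
        image_label=label,
        kind="numerosity",
        seed=0,
    )


def _curve(pref, responses, classes=CLASSES) -> TuningCurve:
    return TuningCurve(0, np.asarray(classes), np.asarray(responses, float), pref)


# ---------------------------------------------------------------------------
# Tuning curves and preferences


def test_unique_argmax_defines_preference():
    trials = [_trial(c, [1, 2, 5, 2, 1][c - 1] * np.ones(1)) for c in CLASSES]
    curves = compute_tuning_curves(trials)
    assert curves[0].preferred_class == 3


def test_tied_or_silent_units_are_non_selective():
    flat = [_trial(c, [2.0, 0.0]) for c in CLASSES]  # unit 0 tied, unit 1 silent
    curves = compute_tuning_curves(flat)
    assert curves[0].preferred_class is None
    assert curves[1].preferred_class is None


def test_mean_rates_match_hand_average():
    """30 trials per class on a 3-unit toy table reproduce the arithmetic mean."""
    rng = np.random.default_rng(0)
    table = rng.uniform(0, 50, size=(5, 30, 3))
    trials = [
        _trial(c, table[c - 1, k]) for c in CLASSES for k in range(30)
    ]
    curves = compute_tuning_curves(trials)
    expected = table.mean(axis=1)  # (class, unit)
    for u in range(3):
        assert np.allclose(curves[u].mean_rate_per_class, expected[:, u])


def test_missing_declared_class_raises():
    trials = [_trial(c, [1.0]) for c in (1, 2, 3)]
    with pytest.raises(MissingClassError):
        compute_tuning_curves(trials, class_values=CLASSES)


def test_preference_distribution_counts():
    curves = [_curve(p, [0, 0, 0, 0, 0]) for p in (1, 1, 5, 3)]
    dist = preference_distribution(curves)
    assert np.allclose(dist.percent_per_class, [50, 0, 25, 0, 25])
    assert dist.n_selective == 4


def test_all_units_one_class_gives_100_percent():
    curves = [_curve(2, np.eye(5)[1]) for _ in range(6)]
    dist = preference_distribution(curves)
    assert dist.percent_per_class[1] == 100.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(prefs=st.lists(st.sampled_from([1, 2, 3, 4, 5, None]), min_size=1, max_size=100))
def test_preference_distribution_matches_brute_force_tally(prefs):
    """Percentages over a random assignment agree with direct counting and sum to 100."""
    curves = [_curve(p, [0, 0, 0, 0, 0]) for p in prefs]
    selective = [p for p in prefs if p is not None]
    if not selective:
        with pytest.raises(EmptyResultError):
            preference_distribution(curves)
        return
    dist = preference_distribution(curves)
    for idx, cls in enumerate(CLASSES):
        assert np.isclose(
            dist.percent_per_class[idx], 100.0 * selective.count(cls) / len(selective)
        )
    assert abs(dist.percent_per_class.sum() - 100.0) < 1e-6


# ---------------------------------------------------------------------------
# Average curves


def test_min_max_normalization_arithmetic():
    curves = [_curve(3, [2, 4, 10, 4, 2])]
    avg = average_normalized_curves(curves)[0]
    assert np.allclose(avg.normalized_response, [0, 0.25, 1, 0.25, 0])


def test_averaging_identical_curves_is_idempotent():
    curves = [_curve(2, [1, 9, 5, 3, 1]), _curve(2, [1, 9, 5, 3, 1])]
    avg = average_normalized_curves(curves)[0]
    assert np.allclose(avg.normalized_response, (np.array([1, 9, 5, 3, 1]) - 1) / 8)
    assert avg.n_units == 2


def test_average_curves_attain_zero_and_one():
    rng = np.random.default_rng(1)
    curves = [_curve(rng.integers(1, 6), rng.uniform(0, 30, 5)) for _ in range(40)]
    for avg in average_normalized_curves(curves):
        assert avg.normalized_response.min() == 0.0
        assert avg.normalized_response.max() == 1.0


def test_unrepresented_class_is_omitted_not_fatal():
    curves = [_curve(1, [9, 1, 1, 1, 1])]
    averages = average_normalized_curves(curves)
    assert [a.preferred_class for a in averages] == [1]


# ---------------------------------------------------------------------------
# Scale transforms


@pytest.mark.parametrize(
    "x,scale,expected",
    [(3, "linear", 3.0), (4, "log2", 2.0), (8, "cbrt", 2.0), (9, "sqrt", 3.0)],
)
def test_transform_closed_forms(x, scale, expected):
    assert np.isclose(transform_scale(x, scale), expected)


def test_log2_shift_for_digit_zero():
    assert transform_scale(0, "log2", log2_shift=1.0) == 0.0
    with pytest.raises(ValueError):
        transform_scale(0, "log2")


def test_transforms_are_monotone():
    x = np.arange(1, 10)
    for scale in ("linear", "sqrt", "cbrt", "log2"):
        t = transform_scale(x, scale)
        assert np.all(np.diff(t) > 0)


def test_unknown_scale_rejected():
    with pytest.raises(ValueError):
        transform_scale(3, "log10")


# ---------------------------------------------------------------------------
# Gaussian fits


def _avg(responses, pref=3, classes=CLASSES) -> AverageTuningCurve:
    return AverageTuningCurve(pref, np.asarray(classes), np.asarray(responses, float), 1)


def test_exact_gaussian_recovery():
    """Noise-free Gaussian data is recovered to 1e-6 with r^2 = 1."""
    t = CLASSES.astype(float)
    y = _gaussian(t, 1.0, 2.0, 0.8)
    fit = fit_gaussian(_avg(y, pref=2), "linear")
    assert fit.converged
    assert abs(fit.amplitude - 1.0) < 1e-6
    assert abs(fit.center - 2.0) < 1e-6
    assert abs(fit.sigma - 0.8) < 1e-6
    assert abs(fit.r2 - 1.0) < 1e-9


def test_symmetric_curve_centers_at_three():
    """(0, .25, 1, .25, 0) is symmetric about class 3; a grid search confirms."""
    fit = fit_gaussian(_avg([0, 0.25, 1, 0.25, 0]), "linear")
    assert abs(fit.center - 3.0) < 0.01
    # brute-force least squares over a center grid agrees
    grid = np.linspace(2.5, 3.5, 101)
    y = np.array([0, 0.25, 1, 0.25, 0], float)
    t = CLASSES.astype(float)
    best = min(
        grid,
        key=lambda mu: min(
            np.sum((y - _gaussian(t, a, mu, s)) ** 2)
            for a in np.linspace(0.8, 1.2, 9)
            for s in np.linspace(0.3, 2.0, 40)
        ),
    )
    assert abs(best - 3.0) < 0.01


def test_r2_never_exceeds_one():
    rng = np.random.default_rng(2)
    for _ in range(10):
        y = rng.uniform(0, 1, 5)
        y = (y - y.min()) / np.ptp(y)
        for scale in ("linear", "sqrt", "cbrt", "log2"):
            fit = fit_gaussian(_avg(y), scale)
            if fit.converged:
                assert fit.r2 <= 1.0 + 1e-12


def test_constant_curve_is_degenerate():
    with pytest.raises(FitDegenerateError):
        fit_gaussian(_avg([0.5] * 5), "linear")


def test_mean_r2_arithmetic():
    fits = [
        GaussianFit("linear", p, 1, p, 1, r2, True)
        for p, r2 in zip((1, 2, 3), (0.8, 0.9, 1.0))
    ]
    assert np.isclose(mean_r2_per_scale(fits)["linear"], 0.9)


def test_mean_r2_requires_converged_fits():
    fits = [GaussianFit("linear", 1, np.nan, np.nan, np.nan, np.nan, False)]
    with pytest.raises(MissingScaleError):
        mean_r2_per_scale(fits)


def test_sigma_ordering_constructed():
    widening = [
        GaussianFit("linear", p, 1, p, 0.2 * p, 0.99, True) for p in (1, 2, 3, 4, 5)
    ]
    classes, sigmas = sigma_vs_preference(widening, "linear")
    assert np.all(np.diff(sigmas) > 0)
    constant = [GaussianFit("log2", p, 1, p, 0.4, 0.99, True) for p in (1, 2, 3)]
    _, sigmas = sigma_vs_preference(constant, "log2")
    assert np.ptp(sigmas) == 0.0


def test_curve_skewness_signs():
    right_tailed = _avg([0, 1, 0.5, 0.3, 0.2], pref=2)
    left_tailed = _avg([0.2, 0.3, 0.5, 1, 0], pref=4)
    assert curve_skewness(right_tailed, "linear") > 0
    assert curve_skewness(left_tailed, "linear") < 0


def test_trials_frame_layout():
    frame = trials_to_frame([_trial(1, [1.0, 2.0]), _trial(2, [3.0, 4.0])])
    assert list(frame.columns) == ["trial", "label", "unit", "spike_count", "rate_hz"]
    assert len(frame) == 4
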