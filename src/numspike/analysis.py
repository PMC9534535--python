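"""Tuning-curve statistics for the network's output layer.

Given per-trial output rates, this module computes, per unit, the mean
firing rate for every stimulus class (the tuning curve) and the preferred
class (the unique argmax).  Units that never fired, or whose maximum is
tied, are non-selective and carry no preference.  Tuning curves sharing a
preference are averaged and min-max normalized, and a three-parameter
Gaussian a*exp(-(t-mu)^2/(2 sigma^2)) is fitted to each average curve on
four abscissa scales — linear, square root, cube root and log2 — to
quantify the Weber-Fechner log compression of numerical tuning: if tuning
is symmetric on a compressed axis, goodness of fit (r^2) rises with
abscissa non-linearity and the fitted sigma stops growing with the
preferred value.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    EmptyResultError,
    FitDegenerateError,
    MissingClassError,
    MissingScaleError,
)
from .network import TrialResult

logger = logging.getLogger(__name__)

SCALES = ("linear", "sqrt", "cbrt", "log2")


@dataclass(frozen=True)
class TuningCurve:
    unit_id: int
    class_values: np.ndarray
    mean_rate_per_class: np.ndarray  # Hz
    preferred_class: int | None


@dataclass(frozen=True)
class AverageTuningCurve:
    """Unit-wise mean of same-preference tuning curves, min-max normalized."""

    preferred_class: int
    class_values: np.ndarray
    normalized_response: np.ndarray  # in [0, 1], min 0 and max 1
    n_units: int


@dataclass(frozen=True)
class PreferenceDistribution:
    class_values: np.ndarray
    counts: np.ndarray
    percent_per_class: np.ndarray  # over selective units; sums to 100
    n_selective: int


@dataclass(frozen=True)
class GaussianFit:
    """One Gaussian fit of an average tuning curve on one abscissa scale."""

    scale: str
    preferred_class: int
    amplitude: float
    center: float
    sigma: float
    r2: float
    converged: bool


def compute_tuning_curves(
    trials: Sequence[TrialResult],
    class_values: Sequence[int] | None = None,
) -> list[TuningCurve]:
    """Per-unit mean rate per class and unique-argmax preference.

    ``class_values``, when given, declares the classes that must be present;
    a declared class with no trials raises MissingClassError.  Units whose
    rates are all zero or whose maximum is attained by more than one class
    get ``preferred_class=None`` (ties are excluded, never broken).
    """
    if not trials:
        raise MissingClassError("no trials supplied")
    labels = np.array([t.image_label for t in trials])
    present = np.unique(labels)
    if class_values is None:
        classes = present
    else:
        classes = np.asarray(sorted(class_values))
        missing = np.setdiff1d(classes, present)
        if missing.size:
            raise MissingClassError(f"no trials for class(es) {missing.tolist()}")
    rates = np.stack([t.rates for t in trials])  # (trials, units)
    n_units = rates.shape[1]
    means = np.stack(
        [rates[labels == c].mean(axis=0) for c in classes], axis=1
    )  # (units, classes)
    curves = []
    for u in range(n_units):
        row = means[u]
        peak = row.max()
        if peak <= 0 or int((row == peak).sum()) != 1:
            preferred = None
        else:
            preferred = int(classes[int(np.argmax(row))])
        curves.append(
            TuningCurve(
                unit_id=u,
                class_values=classes,
                mean_rate_per_class=row,
                preferred_class=preferred,
            )
        )
    return curves


def preference_distribution(curves: Iterable[TuningCurve]) -> PreferenceDistribution:
    """Percentage of selective units preferring each class (selective denominator)."""
    curves = list(curves)
    if not curves:
        raise EmptyResultError("no tuning curves supplied")
    classes = curves[0].class_values
    selective = [c for c in curves if c.preferred_class is not None]
    if not selective:
        raise EmptyResultError("no selective units (all curves flat or tied)")
    counts = np.array(
        [sum(c.preferred_class == cls for c in selective) for cls in classes]
    )
    return PreferenceDistribution(
        class_values=classes,
        counts=counts,
        percent_per_class=100.0 * counts / counts.sum(),
        n_selective=len(selective),
    )


def average_normalized_curves(
    curves: Iterable[TuningCurve],
) -> list[AverageTuningCurve]:
    """Average same-preference tuning curves and min-max normalize each mean.

    Preferred classes with zero selective units are omitted with a logged
    note rather than raising, so a sparse run still yields the curves it
    can support.
    """
    curves = list(curves)
    if not curves:
        raise EmptyResultError("no tuning curves supplied")
    classes = curves[0].class_values
    out = []
    for cls in classes:
        members = [c.mean_rate_per_class for c in curves if c.preferred_class == cls]
        if not members:
            logger.info("no selective units prefer class %s; curve omitted", cls)
            continue
        mean = np.mean(members, axis=0)
        span = mean.max() - mean.min()
        normalized = (mean - mean.min()) / span if span > 0 else np.zeros_like(mean)
        out.append(
            AverageTuningCurve(
                preferred_class=int(cls),
                class_values=classes,
                normalized_response=normalized,
                n_units=len(members),
            )
        )
    return out


def transform_scale(
    x: float | np.ndarray, scale: str, log2_shift: float = 0.0
) -> np.ndarray:
    """Apply one of the four abscissa transforms (x, sqrt, cbrt, log2).

    ``log2_shift`` is added to x before log2 only; digit datasets use a
    shift of 1 so class 0 stays in-domain.
    """
    x = np.asarray(x, dtype=np.float64)
    if scale == "linear":
        return x
    if scale == "sqrt":
        return np.sqrt(x)
    if scale == "cbrt":
        return np.cbrt(x)
    if scale == "log2":
        shifted = x + log2_shift
        if np.any(shifted <= 0):
            raise ValueError(
                f"log2 scale needs positive values; got {x} with shift {log2_shift}"
            )
        return np.log2(shifted)
    raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")


def _gaussian(t, a, mu, sigma):
    return a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(
    curve: AverageTuningCurve, scale: str, log2_shift: float = 0.0
) -> GaussianFit:
    """Least-squares 3-parameter Gaussian fit on the transformed abscissa.

    Initialization: amplitude at the curve maximum, center at the
    transformed argmax, sigma at half the transformed range (floored at
    1e-3 to avoid collapse).  Non-convergence is reported as a failed fit,
    never an exception; constant curves raise FitDegenerateError.
    """
    y = curve.normalized_response
    if y.size < 3:
        raise FitDegenerateError("need at least 3 points to fit a Gaussian")
    if np.ptp(y) == 0:
        raise FitDegenerateError(
            f"curve for preferred class {curve.preferred_class} is constant"
        )
    t = transform_scale(curve.class_values, scale, log2_shift)
    span = t.max() - t.min()
    spacing = float(np.min(np.diff(np.sort(t))))
    mu0 = float(t[int(np.argmax(y))])
    # Multi-start over sigma: half the abscissa range suits broad curves,
    # sub-spacing widths suit near-delta curves that spike on one class.
    starts = [
        (float(y.max()), mu0, max(s, 1e-3))
        for s in (span / 2.0, spacing, spacing / 4.0)
    ]
    # Center and width are bounded to a broad neighbourhood of the abscissa
    # and the amplitude to twice the normalized peak: monotone edge curves
    # otherwise diverge along the a, mu, sigma ridge of half-Gaussian fits.
    lower = [0.0, t.min() - 2.0 * span, 1e-3]
    upper = [2.0, t.max() + 2.0 * span, 10.0 * max(span, 1.0)]
    best: tuple[float, np.ndarray] | None = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _gaussian,
                t,
                y,
                p0=p0,
                bounds=(lower, upper),
                maxfev=20_000,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((y - _gaussian(t, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt)
    if best is None:
        logger.warning(
            "Gaussian fit did not converge (scale %s, preferred class %s)",
            scale,
            curve.preferred_class,
        )
        return GaussianFit(scale, curve.preferred_class, np.nan, np.nan, np.nan, np.nan, False)
    popt = best[1]
    residuals = y - _gaussian(t, *popt)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return GaussianFit(
        scale=scale,
        preferred_class=curve.preferred_class,
        amplitude=float(popt[0]),
        center=float(popt[1]),
        sigma=float(popt[2]),
        r2=r2,
        converged=True,
    )


def fit_all_scales(
    curves: Iterable[AverageTuningCurve], log2_shift: float = 0.0
) -> list[GaussianFit]:
    """Fit every average curve on every abscissa scale."""
    return [
        fit_gaussian(curve, scale, log2_shift)
        for curve in curves
        for scale in SCALES
    ]


def mean_r2_per_scale(fits: Iterable[GaussianFit]) -> dict[str, float]:
    """Arithmetic mean of r^2 over converged fits, per scale present in the input."""
    fits = list(fits)
    scales = {f.scale for f in fits}
    out = {}
    for scale in [s for s in SCALES if s in scales]:
        values = [f.r2 for f in fits if f.scale == scale and f.converged]
        if not values:
            raise MissingScaleError(f"no converged fits on scale {scale!r}")
        out[scale] = float(np.mean(values))
    return out


def sigma_vs_preference(
    fits: Iterable[GaussianFit], scale: str
) -> tuple[np.ndarray, np.ndarray]:
    """Fitted sigma ordered by preferred class, for one scale.

    Returns (preferred classes, sigmas) for converged fits; used to test the
    size effect (sigma growing with preferred numerosity on the linear scale)
    and its disappearance on compressed scales.
    """
    chosen = sorted(
        (f for f in fits if f.scale == scale and f.converged),
        key=lambda f: f.preferred_class,
    )
    if not chosen:
        raise MissingScaleError(f"no converged fits on scale {scale!r}")
    return (
        np.array([f.preferred_class for f in chosen]),
        np.array([f.sigma for f in chosen]),
    )


def distance_effect_violation(curve: AverageTuningCurve) -> float:
    """Largest single-step increase of the curve moving away from its peak.

    Zero for a curve that is non-increasing on both flanks of the preferred
    class (a perfect distance effect); the return value is in normalized
    response units.
    """
    y = curve.normalized_response
    peak = int(np.argmax(curve.class_values == curve.preferred_class))
    worst = 0.0
    for i in range(peak + 1, y.size):  # rightward flank
        worst = max(worst, float(y[i] - y[i - 1]))
    for i in range(peak - 1, -1, -1):  # leftward flank
        worst = max(worst, float(y[i] - y[i + 1]))
    return worst


def curve_skewness(curve: AverageTuningCurve, scale: str, log2_shift: float = 0.0) -> float:
    """Signed skewness of a curve treated as a mass distribution over the abscissa.

    Weights are the normalized responses; the statistic is the weighted third
    central moment over the cubed weighted standard deviation.  Near-zero on
    an axis where the curve is symmetric.
    """
    t = transform_scale(curve.class_values, scale, log2_shift)
    w = curve.normalized_response
    total = w.sum()
    if total <= 0:
        raise FitDegenerateError("curve has no mass")
    mu = float((w * t).sum() / total)
    var = float((w * (t - mu) ** 2).sum() / total)
    if var == 0:
        return 0.0
    return float((w * (t - mu) ** 3).sum() / total / var**1.5)


# ---------------------------------------------------------------------------
# Tabular output


def trials_to_frame(trials: Sequence[TrialResult]) -> pd.DataFrame:
    """Long-format per-trial, per-unit spike counts and rates."""
    n_units = trials[0].spike_counts.size
    return pd.DataFrame(
        {
            "trial": np.repeat(np.arange(len(trials)), n_units),
            "label": np.repeat([t.image_label for t in trials], n_units),
            "unit": np.tile(np.arange(n_units), len(trials)),
            "spike_count": np.concatenate([t.spike_counts for t in trials]),
            "rate_hz": np.concatenate([t.rates for t in trials]),
        }
    )


def curves_to_frame(curves: Sequence[TuningCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for cls, rate in zip(c.class_values, c.mean_rate_per_class):
            rows.append(
                {
                    "unit": c.unit_id,
                    "class": int(cls),
                    "mean_rate_hz": rate,
                    "preferred_class": -1 if c.preferred_class is None else c.preferred_class,
                }
            )
    return pd.DataFrame(rows)


def fits_to_frame(fits: Sequence[GaussianFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scale": [f.scale for f in fits],
            "preferred_class": [f.preferred_class for f in fits],
            "amplitude": [f.amplitude for f in fits],
            "center": [f.center for f in fits],
            "sigma": [f.sigma for f in fits],
            "r2": [f.r2 for f in fits],
            "converged": [f.converged for f in fits],
        }
    )


def summarize(
    curves: Sequence[TuningCurve],
    fits: Sequence[GaussianFit],
    distribution: PreferenceDistribution,
) -> dict:
    """JSON-ready run summary: mean r^2 per scale and preference statistics.

    Preference percentages are reported under both denominators — selective
    units only and all output units — since either reading of "the total
    number of units" is defensible.
    """
    n_units = len(curves)
    return {
        "n_units": n_units,
        "n_selective": int(distribution.n_selective),
        "mean_r2_per_scale": mean_r2_per_scale(fits),
        "n_failed_fits": int(sum(not f.converged for f in fits)),
        "preference_percent_selective": {
            int(c): float(p)
            for c, p in zip(distribution.class_values, distribution.percent_per_class)
        },
        "preference_percent_all_units": {
            int(c): float(100.0 * n / n_units)
            for c, n in zip(distribution.class_values, distribution.counts)
        },
    }


def write_outputs(
    out_dir: str | Path,
    trials: Sequence[TrialResult],
    curves: Sequence[TuningCurve],
    average_curves: Sequence[AverageTuningCurve],
    fits: Sequence[GaussianFit],
    distribution: PreferenceDistribution,
) -> dict[str, Path]:
    """Write the standard CSV/JSON artifact set; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.csv",
        "tuning_curves": out / "tuning_curves.csv",
        "average_curves": out / "average_tuning_curves.csv",
        "preferences": out / "preferences.csv",
        "fits": out / "fits.csv",
        "summary": out / "summary.json",
    }
    trials_to_frame(trials).to_csv(paths["trials"], index=False)
    curves_to_frame(curves).to_csv(paths["tuning_curves"], index=False)
    pd.DataFrame(
        [
            {
                "preferred_class": ac.preferred_class,
                "class": int(cls),
                "normalized_response": resp,
                "n_units": ac.n_units,
            }
            for ac in average_curves
            for cls, resp in zip(ac.class_values, ac.normalized_response)
        ]
    ).to_csv(paths["average_curves"], index=False)
    pd.DataFrame(
        {
            "class": distribution.class_values,
            "count": distribution.counts,
            "percent": distribution.percent_per_class,
        }
    ).to_csv(paths["preferences"], index=False)
    fits_to_frame(fits).to_csv(paths["fits"], index=False)
    paths["summary"].write_text(
        json.dumps(summarize(curves, fits, distribution), indent=2, sort_keys=True)
    )
    return paths
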