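"""Gaussian self-benchmarking: the core calibration machinery.

The method rests on a dual-model design.  *Modeling data* assume uniform
coverage (every k-mer counted once); aggregating modeling counts by GC or
MFE category and fitting a free Gaussian fixes a transcript-specific mean
and SD that are independent of any sequencing data.  *Observed* aggregates
are then fitted with those parameters locked, freeing only the amplitude —
the single remaining scale.  The amplitude has a closed-form least-squares
solution; predicted per-category counts, averaged over the k-mers of each
category, replace the biased per-k-mer counts.  A cumulative (Gaussian CDF)
variant of the fixed-parameter fit turns the amplitude into a bias-corrected
abundance estimate for a region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._errors import FitDegeneracyError, FitError, InputError
from .binning import CategoryTable


@dataclass
class GaussianParams:
    """Amplitude / mean / SD of a Gaussian (or Gaussian-CDF) model plus the
    coefficient of determination of the fit.  ``reliable`` is False when R²
    falls below the configured floor."""

    A: float
    mu: float
    sigma: float
    r2: float
    reliable: bool = True


@dataclass
class CalibrationResult:
    """Output of a fixed-parameter amplitude fit on one category table."""

    amplitude: float
    mu: float
    sigma: float
    predicted: np.ndarray  # per category
    residual: np.ndarray  # observed - predicted, per category
    cumulative: bool = False


def gaussian(x, A, mu, sigma):
    x = np.asarray(x, dtype=float)
    return A * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def gaussian_cdf(x, A, mu, sigma):
    x = np.asarray(x, dtype=float)
    return A * stats.norm.cdf((x - mu) / sigma)


def _r2(y, yhat):
    y = np.asarray(y, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def _select_aggregate(table: CategoryTable, which: str) -> np.ndarray:
    if which == "model":
        return table.agg_model.astype(float)
    if which == "obs":
        return table.agg_obs.astype(float)
    raise InputError(f"unknown aggregate {which!r} (use 'model' or 'obs')")


def _weighted_moments(x, y):
    w = np.clip(y, 0.0, None)
    if w.sum() <= 0:
        return float(np.mean(x)), float(np.std(x)) or 1.0
    mu = float(np.average(x, weights=w))
    var = float(np.average((x - mu) ** 2, weights=w))
    return mu, float(np.sqrt(var)) if var > 0 else 1.0


def fit_gaussian_free(
    table: CategoryTable,
    which: str = "model",
    r2_floor: float = 0.9,
    cumulative: bool = False,
    weighted: bool = False,
) -> GaussianParams:
    """Nonlinear least squares of category aggregates against a Gaussian.

    y_c = A exp(-(x_c - mu)^2 / (2 sigma^2)) over categories (or the
    Gaussian CDF of cumulative aggregates when ``cumulative=True``).
    Initialisation: mu0/sigma0 from count-weighted moments of the category
    values, A0 = max aggregate.  A grid of sigma restarts is tried before
    declaring non-convergence; a :class:`FitError` then carries the best
    parameters seen.  ``weighted=True`` weights each category point by its
    k-mer multiplicity.

    R² below ``r2_floor`` flags the parameters unreliable (with a warning)
    but still returns them.
    """
    x = table.values.astype(float)
    y = _select_aggregate(table, which)
    if len(x) < 4:
        raise InputError(f"need >= 4 categories for a free fit, got {len(x)}")
    if cumulative:
        y = np.cumsum(y)
        model = gaussian_cdf
        a0 = float(y[-1])
    else:
        model = gaussian
        a0 = float(np.max(y))
    if np.allclose(y, y[0]):
        raise FitDegeneracyError("constant aggregates: Gaussian fit is degenerate")
    mu0, sigma0 = _weighted_moments(x, np.diff(y, prepend=0.0) if cumulative else y)
    sigma_w = None
    if weighted:
        sigma_w = 1.0 / np.sqrt(np.clip(table.n_kmers.astype(float), 1.0, None))
    best = None
    best_sse = np.inf
    for s_scale in (1.0, 0.5, 2.0, 0.25, 4.0):
        p0 = (a0 if a0 > 0 else 1.0, mu0, max(sigma0 * s_scale, 1e-6))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    model, x, y, p0=p0, sigma=sigma_w, maxfev=20000
                )
        except RuntimeError:
            continue
        A, mu, sigma = popt
        sigma = abs(float(sigma))
        if sigma <= 0:
            continue
        sse = float(np.sum((y - model(x, A, mu, sigma)) ** 2))
        if sse < best_sse:
            best_sse = sse
            best = (float(A), float(mu), sigma)
    if best is None:
        raise FitError(
            "Gaussian fit did not converge after restart grid",
            best_params=None,
        )
    A, mu, sigma = best
    r2 = _r2(y, model(x, A, mu, sigma))
    reliable = bool(np.isnan(r2) or r2 >= r2_floor)
    if not reliable:
        warnings.warn(
            f"free Gaussian fit R²={r2:.4f} below floor {r2_floor}; "
            "parameters flagged unreliable"
        )
    return GaussianParams(A=A, mu=mu, sigma=sigma, r2=float(r2), reliable=reliable)


def amplitude_fixed(x, y, mu: float, sigma: float, template=None) -> tuple[float, np.ndarray]:
    """Closed-form least-squares amplitude for y ~ A * g(x) at fixed (mu, sigma).

    g is the unit-amplitude Gaussian unless an explicit ``template`` vector
    is given.  A* = sum(y g) / sum(g^2) — the exact minimiser of
    SSE(A) = sum (y - A g)^2.  Returns (A*, g).
    """
    if sigma <= 0:
        raise InputError("sigma must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if template is None:
        g = np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))
    else:
        g = np.asarray(template, dtype=float)
    denom = float(np.sum(g * g))
    if denom <= 0 or not np.isfinite(denom):
        raise FitDegeneracyError(
            "all template weights numerically zero: (mu, sigma) inconsistent "
            "with the category values"
        )
    return float(np.sum(y * g) / denom), g


def fit_amplitude_fixed(
    table: CategoryTable, mu: float, sigma: float, which: str = "obs"
) -> CalibrationResult:
    """Fixed-parameter Gaussian fit of category aggregates: only the
    amplitude is free, (mu, sigma) are locked to the modeling-data values.

    predicted_c = A* g(x_c); residual_c = y_c - predicted_c.  Zero-count
    categories are retained (they inform the amplitude).
    """
    y = _select_aggregate(table, which)
    A, g = amplitude_fixed(table.values, y, mu, sigma)
    predicted = A * g
    return CalibrationResult(
        amplitude=A,
        mu=mu,
        sigma=sigma,
        predicted=predicted,
        residual=y - predicted,
    )


def fit_cdf_amplitude(
    table: CategoryTable, mu: float, sigma: float, which: str = "obs"
) -> CalibrationResult:
    """Fixed-parameter Gaussian-CDF fit of cumulative aggregates.

    Categories must be in ascending key order (they are, by construction);
    cumulative aggregates Y_c are fitted as A * Phi((x_c - mu)/sigma) with
    (mu, sigma) locked, so A* = sum(Y Phi) / sum(Phi^2).  The amplitude is
    the bias-corrected cumulative count — the abundance estimate of the
    region the table came from.
    """
    if sigma <= 0:
        raise InputError("sigma must be > 0")
    x = table.values.astype(float)
    if np.any(np.diff(x) <= 0):
        raise InputError("categories must be strictly ascending for a CDF fit")
    Y = np.cumsum(_select_aggregate(table, which))
    phi = stats.norm.cdf((x - mu) / sigma)
    A, _ = amplitude_fixed(x, Y, mu, sigma, template=phi)
    predicted = A * phi
    return CalibrationResult(
        amplitude=A,
        mu=mu,
        sigma=sigma,
        predicted=predicted,
        residual=Y - predicted,
        cumulative=True,
    )


def calibrate_kmers(
    kmers: pd.DataFrame, table: CategoryTable, fit: CalibrationResult
) -> tuple[pd.DataFrame, dict]:
    """Distribute predicted category counts evenly over their k-mers.

    For a k-mer in category c, ``count_cal = predicted_c / n_kmers(c)`` —
    the average of the adjusted prediction for its category.  Returns the
    calibrated table plus summary statistics (mean, SD, CV of per-k-mer
    counts before and after).
    """
    if fit.cumulative:
        raise InputError("calibrate_kmers expects a PDF-mode fit, not CDF")
    if len(fit.predicted) != table.n_categories:
        raise InputError("fit and category table sizes disagree")
    if len(table.assignment) != len(kmers):
        raise InputError("category table was built from a different k-mer table")
    per_kmer = fit.predicted[table.assignment] / table.n_kmers[table.assignment]
    out = kmers.copy()
    out["count_cal"] = per_kmer
    summary = {
        "cv_raw": cv(kmers["count_obs"].to_numpy(dtype=float)),
        "cv_cal": cv(per_kmer),
        "mean_cal": float(np.mean(per_kmer)),
        "sd_cal": float(np.std(per_kmer)),
        "amplitude": fit.amplitude,
    }
    return out, summary


def cv(values) -> float:
    """Coefficient of variation (SD/mean); NaN for zero mean."""
    values = np.asarray(values, dtype=float)
    m = float(np.mean(values))
    if m == 0.0:
        return float("nan")
    return float(np.std(values) / m)


def rpkm(amplitude: float, region_length_nt: float, library_total: float) -> float:
    """Reads per kilobase per million from a region amplitude."""
    if region_length_nt <= 0 or library_total <= 0:
        raise InputError("region length and library total must be > 0")
    return amplitude / (region_length_nt / 1e3) / (library_total / 1e6)


def tpm(amplitudes, region_lengths_nt) -> np.ndarray:
    """Transcripts-per-million over a set of region amplitudes; sums to 1e6."""
    a = np.asarray(amplitudes, dtype=float)
    ln = np.asarray(region_lengths_nt, dtype=float)
    if np.any(ln <= 0):
        raise InputError("region lengths must be > 0")
    rate = a / ln
    total = rate.sum()
    if total <= 0:
        raise InputError("all amplitudes are zero; TPM undefined")
    return rate / total * 1e6


def normalize_abundance(amplitude, region_length_nt, library_total):
    """RPKM of one region amplitude (TPM needs the full set; see :func:`tpm`)."""
    return {
        "rpkm": rpkm(amplitude, region_length_nt, library_total),
        "per_million": amplitude / (library_total / 1e6),
    }
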