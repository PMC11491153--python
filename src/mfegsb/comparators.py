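"""Empirical-data bias corrections for head-to-head comparison with the
self-benchmarking framework.

Four comparators, each targeting one bias in isolation the way popular
quantifiers do:

* GC-content LOESS weighting of fragment counts (0.5-percentage-point GC
  bins, tricube local-linear smoothing);
* fragment-size correction via a global empirical Gaussian of fragment
  lengths whose (mu, sigma) are then locked for per-transcript amplitude
  fits;
* hexamer-priming weights: observed counts of each of the 4096 possible
  first-hexamers standardised against a theoretical even baseline;
* LOESS smoothing of category aggregates — the smoothing baseline the
  Gaussian benchmark is compared against.

Each comparator learns its weights from the (biased) empirical data itself;
that dependence is exactly what the self-benchmarking framework avoids.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._errors import FitDegeneracyError, InputError
from .binning import CategoryTable
from .gsb import GaussianParams, amplitude_fixed, fit_gaussian_free
from .seqio import Transcript, gc_count

ALL_HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]


@dataclass
class WeightTable:
    """Per-key multiplicative correction weights.

    ``kind`` is one of gc_bin / hexamer / fragment_length; keys are GC bin
    lower edges (percent, 0.5-wide), hexamer strings, or lengths in nt.
    Keys absent from the table get the neutral weight 1.0.
    """

    kind: str
    weights: dict
    pseudocount: float

    def weight(self, key) -> float:
        return self.weights.get(key, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"key": list(self.weights), "weight": list(self.weights.values())}
        )


def fragment_gc_percent(fragments: pd.DataFrame,
                        transcripts: dict[str, Transcript]) -> np.ndarray:
    """GC percentage of each fragment's sequence."""
    out = np.empty(len(fragments), dtype=float)
    for i, (tid, s, e) in enumerate(
        zip(fragments["transcript_id"], fragments["start"], fragments["end"])
    ):
        seq = transcripts[tid].sequence[s:e]
        out[i] = 100.0 * gc_count(seq) / len(seq)
    return out


def gc_bin(gc_percent, width: float = 0.5) -> np.ndarray:
    """Lower edge of the GC bin (percentage points) containing each value."""
    return np.round(np.floor(np.asarray(gc_percent) / width) * width, 6)


def loess_gc_weights(fragments: pd.DataFrame,
                     transcripts: dict[str, Transcript],
                     span: float = 0.3,
                     bin_width: float = 0.5,
                     pseudocount: float = 0.5) -> WeightTable:
    """GC-bias weights from LOESS-smoothed binned fragment GC counts.

    Fragment GC% is binned at ``bin_width`` (default 0.5 percentage
    points); per-bin fragment counts are smoothed by tricube local-linear
    LOESS at the given span; weight(bin) = global mean bin count /
    smoothed(bin), with the smoothed denominator floored at ``pseudocount``.
    """
    if len(fragments) == 0:
        raise InputError("loess_gc_weights: no fragments")
    bins = gc_bin(fragment_gc_percent(fragments, transcripts), bin_width)
    uniq, counts = np.unique(bins, return_counts=True)
    if len(uniq) < 10:
        raise InputError(
            f"only {len(uniq)} occupied GC bins (< 10); "
            "use coarser bins or more fragments"
        )
    smoothed = lowess(
        counts.astype(float), uniq, frac=span, it=0, return_sorted=False
    )
    smoothed = np.clip(smoothed, pseudocount, None)
    mean_count = float(np.mean(counts))
    weights = {float(b): float(mean_count / s) for b, s in zip(uniq, smoothed)}
    return WeightTable(kind="gc_bin", weights=weights, pseudocount=pseudocount)


def loess_mean_weights(key_values, counts, span: float = 0.3,
                       pseudocount: float = 0.5,
                       kind: str = "generic") -> WeightTable:
    """LOESS weights from per-key mean counts (k-mer-level analogue of
    :func:`loess_gc_weights`): the mean observed count of every distinct key
    is smoothed over the key axis and weight(key) = global mean count /
    smoothed(key), floored at ``pseudocount``."""
    key_values = np.asarray(key_values, dtype=float)
    counts = np.asarray(counts, dtype=float)
    uniq, inv = np.unique(key_values, return_inverse=True)
    if len(uniq) < 10:
        raise InputError(
            f"only {len(uniq)} distinct keys (< 10); too few for LOESS weights"
        )
    means = np.bincount(inv, weights=counts) / np.bincount(inv)
    smoothed = np.clip(
        lowess(means, uniq, frac=span, it=0, return_sorted=False), pseudocount, None
    )
    gmean = float(np.mean(counts))
    weights = {float(u): float(gmean / s) for u, s in zip(uniq, smoothed)}
    return WeightTable(kind=kind, weights=weights, pseudocount=pseudocount)


def apply_weights(records: pd.DataFrame, table: WeightTable, key_extractor,
                  count_col: str = "count_obs") -> tuple[pd.DataFrame, dict]:
    """Multiply per-record counts by weight(key_extractor(record row)).

    ``key_extractor`` maps a row (as namedtuple) to the weight key.  Returns
    (corrected table, summary with totals before/after).
    """
    out = records.copy()
    keys = [key_extractor(row) for row in records.itertuples(index=False)]
    w = np.asarray([table.weight(k) for k in keys], dtype=float)
    raw = out[count_col].to_numpy(dtype=float) if count_col in out else np.ones(len(out))
    corrected = raw * w
    out[count_col + "_corrected"] = corrected
    summary = {
        "total_before": float(raw.sum()),
        "total_after": float(corrected.sum()),
        "n_records": len(out),
    }
    return out, summary


def fragment_size_model(fragments: pd.DataFrame,
                        r2_floor: float = 0.0) -> GaussianParams:
    """Free Gaussian fit of the global fragment-length histogram.

    Requires >= 100 fragments; all-equal lengths are degenerate.  Returns
    the (mu_f, sigma_f) every per-transcript size calibration then locks.
    """
    if len(fragments) < 100:
        raise InputError(
            f"fragment_size_model: need >= 100 fragments, got {len(fragments)}"
        )
    lengths = fragments["length"].to_numpy(dtype=float)
    vals, counts = np.unique(lengths, return_counts=True)
    if len(vals) < 4:
        raise FitDegeneracyError(
            "fragment lengths nearly constant: size model is degenerate"
        )
    table = CategoryTable(
        key="fragment_length",
        values=vals,
        n_kmers=counts,
        agg_model=counts.astype(float),
        agg_obs=counts.astype(float),
        assignment=np.searchsorted(vals, lengths),
    )
    return fit_gaussian_free(table, which="obs", r2_floor=r2_floor)


def calibrate_by_size(transcript_fragments: pd.DataFrame,
                      params: GaussianParams,
                      cumulative: bool = False) -> dict:
    """Amplitude-only fit of one transcript's length histogram at the global
    (mu_f, sigma_f).

    The Gaussian template is normalised to sum 1 over the evaluation grid so
    the amplitude is directly a size-calibrated fragment count (a histogram
    exactly proportional to the global shape with total T gives amplitude T).
    The CDF variant fits cumulative counts against the normalised Gaussian
    CDF.
    """
    if len(transcript_fragments) == 0:
        raise InputError("calibrate_by_size: no fragments for transcript")
    lengths = transcript_fragments["length"].to_numpy(dtype=float)
    vals, counts = np.unique(lengths, return_counts=True)
    lo = min(vals.min(), params.mu - 4 * params.sigma)
    hi = max(vals.max(), params.mu + 4 * params.sigma)
    grid = np.arange(np.floor(lo), np.ceil(hi) + 1)
    y = np.zeros(len(grid))
    y[np.searchsorted(grid, vals)] = counts
    g = np.exp(-((grid - params.mu) ** 2) / (2 * params.sigma**2))
    g = g / g.sum()
    if cumulative:
        from scipy.stats import norm

        phi = norm.cdf((grid - params.mu) / params.sigma)
        A, _ = amplitude_fixed(grid, np.cumsum(y), params.mu, params.sigma,
                               template=phi)
    else:
        A, _ = amplitude_fixed(grid, y, params.mu, params.sigma, template=g)
    return {
        "amplitude": float(A),
        "raw_total": float(counts.sum()),
        "mu": params.mu,
        "sigma": params.sigma,
        "cumulative": cumulative,
    }


def hexamer_weights(fragments: pd.DataFrame,
                    pseudocount: float = 0.5) -> WeightTable:
    """Hexamer-priming weights over all 4096 possible start hexamers.

    n_h = fragments starting with hexamer h; the theoretical even baseline
    is N/4096; weight_h = baseline / (n_h + pseudocount), rescaled so the
    count-weighted mean weight is 1 (corrected library size equals raw).
    The table always has 4096 rows.
    """
    n_total = len(fragments)
    if n_total < 4096:
        warnings.warn(
            f"only {n_total} fragments for 4096 hexamers; weights will be noisy"
        )
    counts = dict.fromkeys(ALL_HEXAMERS, 0)
    if n_total:
        for h, c in fragments["first6"].value_counts().items():
            if h not in counts:
                raise InputError(f"invalid hexamer {h!r} in fragment table")
            counts[h] = int(c)
    baseline = n_total / 4096.0 if n_total else 1.0
    raw_w = {h: baseline / (counts[h] + pseudocount) for h in ALL_HEXAMERS}
    # count-weighted mean weight -> 1
    denom = sum(counts[h] * raw_w[h] for h in ALL_HEXAMERS)
    scale = n_total / denom if denom > 0 else 1.0
    weights = {h: raw_w[h] * scale for h in ALL_HEXAMERS}
    return WeightTable(kind="hexamer", weights=weights, pseudocount=pseudocount)


def smooth_category_counts(table: CategoryTable, span: float = 0.3) -> np.ndarray:
    """LOESS-smoothed observed aggregates per category — the smoothing
    baseline against which the Gaussian benchmark is compared.

    Per-k-mer averaging of these predictions mirrors the benchmark's
    calibration (predicted_c / n_kmers(c)).
    """
    if table.n_categories < 5:
        raise InputError(
            f"smooth_category_counts: need >= 5 categories, got {table.n_categories}"
        )
    x = table.values.astype(float)
    y = table.agg_obs.astype(float)
    pred = lowess(y, x, frac=span, it=0, return_sorted=False)
    return np.asarray(pred, dtype=float)
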