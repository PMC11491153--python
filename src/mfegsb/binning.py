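"""Categorization of k-mers by GC or MFE, and isoform overlap profiles.

A *category* is the aggregation unit of the self-benchmarking fits: all
k-mers sharing one GC count (integer) or one rounded MFE value (at the fold
engine's precision, default 0.1 kcal/mol).  MFE categories are distinct
rounded values, not interval bins — the rounding performed by the fold
engine defines category identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import InputError
from .seqio import Transcript

#: Default quantum used to snap MFE values to category identity.
MFE_PRECISION = 0.1


@dataclass
class CategoryTable:
    """K-mers grouped by one key (GC count or rounded MFE).

    ``values`` is strictly ascending; ``assignment[i]`` gives the category
    index of input k-mer row ``i`` so per-k-mer calibration can be mapped
    back.  ``agg_model``/``agg_obs`` are the summed modeling/observed counts
    per category.
    """

    key: str  # "gc" or "mfe"
    values: np.ndarray
    n_kmers: np.ndarray
    agg_model: np.ndarray
    agg_obs: np.ndarray
    assignment: np.ndarray = field(repr=False)

    @property
    def n_categories(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "key": self.key,
                "category_value": self.values,
                "n_kmers": self.n_kmers,
                "agg_model": self.agg_model,
                "agg_obs": self.agg_obs,
            }
        )

    def write_tsv(self, path, predicted=None) -> None:
        df = self.to_frame()
        if predicted is not None:
            df["predicted"] = np.asarray(predicted)
        df.to_csv(path, sep="\t", index=False)


def categorize(kmers: pd.DataFrame, key: str,
               mfe_precision: float = MFE_PRECISION) -> CategoryTable:
    """Group a k-mer table into GC or MFE categories with aggregate counts.

    For ``key="mfe"`` values are snapped to ``mfe_precision`` before
    grouping (engines already round, so this is normally a no-op).
    """
    if len(kmers) == 0:
        raise InputError("categorize: empty k-mer table")
    if key == "gc":
        x = kmers["gc"].to_numpy(dtype=float)
    elif key == "mfe":
        x = kmers["mfe"].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise InputError("categorize: mfe column contains NaN; run the fold engine first")
        x = np.round(np.round(x / mfe_precision) * mfe_precision, 10)
    else:
        raise InputError(f"unknown category key {key!r}")
    values, assignment = np.unique(x, return_inverse=True)
    n_cat = len(values)
    n_kmers = np.bincount(assignment, minlength=n_cat)
    agg_model = np.bincount(
        assignment, weights=kmers["count_model"].to_numpy(dtype=float), minlength=n_cat
    )
    agg_obs = np.bincount(
        assignment, weights=kmers["count_obs"].to_numpy(dtype=float), minlength=n_cat
    )
    return CategoryTable(
        key=key,
        values=values,
        n_kmers=n_kmers,
        agg_model=agg_model,
        agg_obs=agg_obs,
        assignment=assignment,
    )


def gc_mfe_regression(kmers: pd.DataFrame):
    """OLS of mean MFE per GC class against GC class.

    Returns ``(slope, intercept, r)``; on constant MFE the slope is 0 and r
    is NaN (flagged degenerate).  Requires at least 3 distinct GC classes.
    """
    if kmers["mfe"].isna().any():
        raise InputError("gc_mfe_regression: mfe column contains NaN")
    means = kmers.groupby("gc")["mfe"].mean()
    if len(means) < 3:
        raise InputError(
            f"gc_mfe_regression: need >= 3 distinct GC classes, got {len(means)}"
        )
    x = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), float("nan")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


@dataclass
class OverlapProfile:
    """Per-start-position isoform overlap degree of one transcript.

    ``degree[i]`` counts the isoforms (including self) whose sequence
    contains the k-mer starting at position ``i``; runs of degree 1 are the
    transcript's unique regions (maximal, disjoint, sorted, half-open in
    start coordinates).
    """

    transcript_id: str
    k: int
    degree: np.ndarray
    unique_intervals: list[tuple[int, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.transcript_id,
                "start": np.arange(len(self.degree)),
                "degree": self.degree,
            }
        )


def _maximal_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean array."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def overlap_degree(isoforms: list[Transcript], k: int) -> list[OverlapProfile]:
    """Isoform overlap degree of every k-mer of every isoform.

    Degree is exact k-mer substring containment against the supplied
    isoform set only (transcript space, not genome-wide).
    """
    if not isoforms:
        raise InputError("overlap_degree: need at least one isoform")
    if k < 1:
        raise InputError("overlap_degree: k must be >= 1")
    membership: dict[str, set[str]] = {}
    for t in isoforms:
        seq = t.sequence
        for i in range(max(t.length - k + 1, 0)):
            membership.setdefault(seq[i : i + k], set()).add(t.id)
    profiles = []
    for t in isoforms:
        n = max(t.length - k + 1, 0)
        deg = np.fromiter(
            (len(membership[t.sequence[i : i + k]]) for i in range(n)),
            dtype=np.int64,
            count=n,
        )
        profiles.append(
            OverlapProfile(
                transcript_id=t.id,
                k=k,
                degree=deg,
                unique_intervals=_maximal_runs(deg == 1),
            )
        )
    return profiles


def write_overlap_bed(profiles: list[OverlapProfile], path) -> None:
    """BED-like TSV of unique intervals in transcript-space coordinates."""
    rows = []
    for p in profiles:
        for s, e in p.unique_intervals:
            rows.append((p.transcript_id, s, e, "unique_region", 1))
    pd.DataFrame(
        rows, columns=["transcript_id", "start", "end", "name", "degree"]
    ).to_csv(path, sep="\t", index=False)
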