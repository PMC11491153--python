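"""Synthetic data: spike-in enumeration, random transcripts, bias-injected
k-mer counts and paired-end fragments.

The generator emulates the three data-generating processes the rest of the
package corrects for:

* a degenerate spike-in panel — a fixed 50-mer core with 8 variable (N)
  positions flanked by 8-mer poly-A tails, enumerating 4^8 = 65,536 variants
  whose GC counts follow the binomial profile C(8, g) * 2^8;
* per-k-mer observed counts with multiplicative GC- and MFE-dependent biases
  around a true abundance, plus Poisson or negative-binomial count noise;
* paired-end fragments with a Gaussian size distribution and hexamer (and
  optionally GC) start preferences, injected by acceptance resampling.

All outputs are byte-identical at a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from ._errors import InputError
from .seqio import Transcript, gc_count

#: Fixed 50-mer spike-in scaffold: 42 constant bases with 8 interleaved N
#: positions (every 6th base starting at offset 5 is degenerate).
DEFAULT_BACKBONE = (
    "GCTAC" "N" "GATCG" "N" "CTAGC" "N" "GTCAT" "N"
    "CGATG" "N" "TAGCT" "N" "AGCTA" "N" "TCGAG" "N" "GC"
)

_BASES = "ACGT"


@dataclass(frozen=True)
class SpikeinDesign:
    """A 50-nt core with degenerate N positions and poly-A flanks."""

    backbone: str = DEFAULT_BACKBONE
    flank5: str = "A" * 8
    flank3: str = "A" * 8

    def __post_init__(self):
        if len(self.backbone) != 50:
            raise InputError(
                f"backbone must be 50 nt, got {len(self.backbone)}"
            )
        if self.n_variable == 0:
            pass  # a fully fixed design is allowed (enumerates to itself)

    @property
    def n_variable(self) -> int:
        return self.backbone.count("N")


def enumerate_spikeins(design: SpikeinDesign = SpikeinDesign(),
                       with_flanks: bool = True) -> list[str]:
    """All 4^n variants of a spike-in design, in lexicographic A<C<G<T order
    of the variable positions.  Guarded at n <= 12."""
    n = design.n_variable
    if n > 12:
        raise InputError(f"refusing to enumerate 4^{n} sequences (n > 12)")
    positions = [i for i, b in enumerate(design.backbone) if b == "N"]
    core = list(design.backbone)
    out = []
    for idx in range(4**n):
        rem = idx
        digits = []
        for _ in range(n):
            rem, d = divmod(rem, 4)
            digits.append(d)
        # most-significant digit at the first variable position =>
        # lexicographic order over variable positions
        for p, d in zip(positions, reversed(digits)):
            core[p] = _BASES[d]
        seq = "".join(core)
        out.append(design.flank5 + seq + design.flank3 if with_flanks else seq)
    return out


def random_transcript(length: int, gc_prob: float = 0.5,
                      seed: int | None = None, id: str = "synthetic") -> Transcript:
    """I.i.d. random transcript with P(G)+P(C) = gc_prob, split evenly."""
    if length < 1:
        raise InputError("length must be >= 1")
    if not 0.0 <= gc_prob <= 1.0:
        raise InputError("gc_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_prob) / 2, gc_prob / 2, gc_prob / 2, (1 - gc_prob) / 2]
    seq = "".join(rng.choice(list("AGCT"), size=length, p=p))
    return Transcript(id, seq)


@dataclass
class BiasModel:
    """Multiplicative bias curves and count noise for synthetic data.

    Linear forms (chosen for analytical tractability):
    gc multiplier 1 + beta_gc * (gc - k/2); mfe multiplier
    1 + beta_mfe * (mfe - mean mfe of the k-mer set).  Arbitrary callables
    ``gc_bias_fn(gc)`` / ``mfe_bias_fn(mfe)`` override the linear forms for
    stress tests.  All multipliers must stay positive.
    """

    beta_gc: float = 0.04
    beta_mfe: float = 0.03
    gc_bias_fn: Callable | None = None
    mfe_bias_fn: Callable | None = None
    hexamer_pref: Mapping[str, float] = field(default_factory=dict)
    size_mu: float = 300.0
    size_sigma: float = 30.0
    noise: str = "poisson"  # or "negbinom"
    dispersion: float = 10.0  # negbinom size parameter
    seed: int = 0

    def gc_multiplier(self, gc, k: int):
        if self.gc_bias_fn is not None:
            return np.asarray([self.gc_bias_fn(g) for g in np.atleast_1d(gc)])
        return 1.0 + self.beta_gc * (np.asarray(gc, dtype=float) - k / 2.0)

    def mfe_multiplier(self, mfe, mfe_mean: float):
        if self.mfe_bias_fn is not None:
            return np.asarray([self.mfe_bias_fn(m) for m in np.atleast_1d(mfe)])
        return 1.0 + self.beta_mfe * (np.asarray(mfe, dtype=float) - mfe_mean)


def simulate_counts(kmers: pd.DataFrame, abundance: float,
                    bias: BiasModel | None = None) -> pd.DataFrame:
    """Draw biased observed counts for a k-mer table.

    Expected count of k-mer i is ``abundance * gc_mult(gc_i) * mfe_mult(mfe_i)``
    (the MFE factor is skipped when the table has no MFE annotation and no
    explicit mfe_bias_fn); counts are drawn from the configured noise law.
    """
    if abundance <= 0:
        raise InputError("abundance must be > 0")
    bias = bias or BiasModel()
    k = len(kmers["kmer"].iloc[0]) if len(kmers) else 0
    if len(kmers) == 0:
        raise InputError("simulate_counts: empty k-mer table")
    lam = abundance * np.asarray(
        bias.gc_multiplier(kmers["gc"].to_numpy(), k), dtype=float
    )
    mfe = kmers["mfe"].to_numpy(dtype=float)
    use_mfe = not np.isnan(mfe).all()
    if use_mfe:
        if np.isnan(mfe).any():
            raise InputError("simulate_counts: partially missing MFE values")
        lam = lam * np.asarray(
            bias.mfe_multiplier(mfe, float(np.mean(mfe))), dtype=float
        )
    bad = np.nonzero(lam <= 0)[0]
    if len(bad):
        i = int(bad[0])
        raise InputError(
            f"non-positive expected count for k-mer {kmers['kmer'].iloc[i]!r} "
            f"(row {i}): bias multipliers too strong"
        )
    rng = np.random.default_rng(bias.seed)
    if bias.noise == "poisson":
        counts = rng.poisson(lam)
    elif bias.noise == "negbinom":
        r = bias.dispersion
        counts = rng.negative_binomial(r, r / (r + lam))
    else:
        raise InputError(f"unknown noise law {bias.noise!r}")
    out = kmers.copy()
    out["count_obs"] = counts.astype(float)
    return out


def simulate_fragments(transcript: Transcript, n_frags: int,
                       bias: BiasModel | None = None,
                       gc_pref: Callable | None = None) -> pd.DataFrame:
    """Paired-end fragments: uniform starts, Gaussian lengths truncated to
    fit, acceptance-resampled by hexamer start preference (and optionally a
    GC-fraction preference ``gc_pref(gc_frac)`` for stress tests).

    Returns a fragment table (transcript_id, start, end, length, first6).
    """
    bias = bias or BiasModel()
    L = transcript.length
    if n_frags < 0:
        raise InputError("n_frags must be >= 0")
    if L <= bias.size_mu:
        raise InputError(
            f"transcript length {L} must exceed mean fragment size {bias.size_mu}"
        )
    cols = ["transcript_id", "start", "end", "length", "first6"]
    if n_frags == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(bias.seed)
    max_pref = max(bias.hexamer_pref.values(), default=1.0)
    max_pref = max(max_pref, 1.0)
    seq = transcript.sequence
    rows = []
    attempts = 0
    while len(rows) < n_frags:
        attempts += 1
        if attempts > 1000 * n_frags + 10000:
            raise InputError(
                "fragment simulation infeasible: acceptance rate too low "
                "(check size parameters and preferences)"
            )
        start = int(rng.integers(0, L - 6 + 1))
        length = int(round(rng.normal(bias.size_mu, bias.size_sigma)))
        if length < 6:
            continue
        if start + length > L:  # truncate to fit
            length = L - start
            if length < 6:
                continue
        first6 = seq[start : start + 6]
        accept = bias.hexamer_pref.get(first6, 1.0) / max_pref
        if gc_pref is not None:
            frag = seq[start : start + length]
            accept *= gc_pref(gc_count(frag) / length)
        if accept < 1.0 and rng.random() >= accept:
            continue
        rows.append((transcript.id, start, start + length, length, first6))
    return pd.DataFrame(rows, columns=cols)


def write_manifest(path, **params) -> None:
    """JSON manifest of simulation/run parameters (includes the seed)."""
    import json

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
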