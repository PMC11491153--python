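# Methods

## Model

The package treats per-k-mer sequencing counts of one transcript as

  y_i = α · b(x_i) · ε_i,

where α is the true per-k-mer abundance, b(·) a multiplicative bias acting
through structural covariates x_i of the k-mer (GC count, MFE), and ε_i
count noise.  The correction does not model b directly.  Instead it relies
on a *self-benchmark*: for the uniform-coverage modeling data (every k-mer
counted once) the category-aggregated counts follow a bell curve over the
category axis, because the GC counts of fixed-length windows are
binomial-like and MFE inherits that shape through its tight inverse linear
relation with GC.  A free Gaussian fit of the modeling aggregates fixes a
transcript-specific mean μ and SD σ that owe nothing to the sequencing
data.  Observed aggregates are then fitted with (μ, σ) locked and only the
amplitude free; the prediction A\*·g(x_c) is the benchmark for category c,
and its per-k-mer average predicted_c / n_c replaces the biased counts
("replace" semantics — the per-category averaging formula implies
replacement, not rescaling of individual counts; rescaling would keep all
within-category noise and add the same between-category fit error, so it is
strictly worse for uniformity).

The amplitude is solved in closed form, A\* = Σ y_c g_c / Σ g_c² with
g_c = exp(−(x_c−μ)²/2σ²): it is the exact minimiser of SSE(A) (verified in
tests against a 1-D numerical minimiser to 1e-6 relative), deterministic,
and immune to optimiser quirks.  Fits are unweighted over categories; a
`weighted` switch divides residuals by √n_c for users who prefer
multiplicity weighting.

For abundance the fit is done in cumulative form: Y_c = Σ_{c'≤c} y_{c'}
over ascending MFE is fitted by A·Φ((x_c−μ)/σ) with (μ, σ) fixed from the
modeling fit, so A\* = Σ Y_c Φ_c / Σ Φ_c².  Since Φ → 1 at the upper end,
the amplitude is a bias-corrected cumulative count of the region and is
normalised to RPKM/TPM by the standard formulas.  By default the CDF reuses
the PDF-fit (μ, σ); `refit_cdf` refits them on the modeling CDF instead
(the two differ only by discretisation of the category grid).

Isoform quantification uses each isoform's unique region: the overlap
degree of a k-mer is the number of supplied isoforms containing it as an
exact substring, and maximal degree-1 runs are unique regions.  When no
unique region exists the pipeline falls back to the longest contiguous run
of smallest maximum degree with at least `min_region` (default 100) k-mers,
and otherwise reports the isoform as unquantifiable rather than returning
a silent zero.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| k | 50 | nt | window length; every start position of the transcript is used |
| MFE precision | 0.1 | kcal/mol | rounding quantum that *defines* MFE category identity |
| temperature | 37 | °C | nearest-neighbor engine setting |
| r2_floor | 0.9 | — | modeling fits below this R² are flagged unreliable (with a warning), not rejected |
| LOESS span | 0.3 | fraction | local-linear tricube window of the comparators; robustness iterations are disabled so the smoother follows genuine excesses (a doubled bin must be downweighted, not treated as an outlier) |
| hexamer pseudocount | 0.5 | counts | keeps weights of unseen hexamers finite; hexamer weights are rescaled so the count-weighted mean weight is 1 (library size preserved) |
| min_region | 100 | k-mers | smallest fallback minimal-shared region |

Keys absent from a weight table receive the neutral weight 1.0 (an unseen
GC bin should not be extrapolated from the pseudocount floor).

## Fold engines

The `builtin` engine is a Nussinov-style dynamic program minimising summed
base-pair energies (GC −3.0, AU −2.0, GU −1.0 kcal/mol, minimum hairpin
loop 3, no pseudoknots).  It is exact for its own energy model — tests
compare it against an explicit enumeration of all nested structures for
lengths ≤ 14 — and reproduces the strong GC–MFE anticorrelation the
categorization transfer needs (class-mean regression r ≈ −0.9 on random
50-mers).  Because its pair energies are integers, its rounded MFE values
are integer-spaced: a 2 kb transcript yields ~17 MFE categories, about as
many as GC classes.  The `vienna` adapter (nearest-neighbor model at 37 °C)
produces the much richer 0.1-kcal/mol value set under which MFE categories
far outnumber GC classes; analyses of real transcripts should use it when
the `RNA` bindings are available.

## What the simulator emulates — and what it does not

`simulate` generates (a) the degenerate spike-in panel (fixed 50-mer
scaffold, 8 N positions, poly-A flanks; GC class sizes are exactly
C(8,g)·2⁸), (b) per-k-mer counts with linear multiplicative biases
1 + β_gc(gc − k/2) and 1 + β_mfe(mfe − mfe̅) (defaults β_gc = 0.04,
β_mfe = 0.03, giving multipliers roughly 0.6–1.4 over a random 2 kb
transcript — a moderate, realistic distortion) under Poisson or
negative-binomial noise, and (c) paired-end fragments with uniform starts,
truncated-Gaussian lengths (default 300 ± 30 nt) and acceptance-resampled
hexamer/GC start preferences.  Arbitrary callable bias curves are accepted
for stress tests.  All outputs are byte-identical at a fixed seed.

Not emulated: read-level sequencing errors and quality, PCR duplication
structure, positional (5′/3′) coverage decay, and real secondary-structure
energetics beyond the chosen engine.  Passing tests therefore demonstrate
the *mechanics* of the correction under controlled multiplicative biases,
not performance on any particular protocol's error profile.

## Numerical choices and degenerate inputs

* Free Gaussian fits: Levenberg–Marquardt from moment-based starts
  (count-weighted mean/SD, A₀ = max aggregate) with a σ restart grid
  (×0.25…×4); non-convergence raises carrying the best parameters seen.
  Constant aggregates are a degeneracy error, not a fit.
* MFE ≤ 0 is enforced (the open chain at energy 0 is always admissible);
  sequences with no admissible pair return exactly 0.0.
* Zero-observed categories stay in fits (they inform the amplitude).
* Duplicated k-mer sequences share one observed count, assigned to every
  position and flagged; positions are bookkeeping, counts are per sequence.
* Reads shorter than k are skipped and tallied, never padded; counting is
  exact substring matching (deterministic and alignment-free; the
  forward strand is assumed, `strand="both"` also matches reverse
  complements).
* Category order is strictly ascending; CDF fits reject unsorted input and
  σ ≤ 0.

## Design choices where the design was open

* **Replace vs rescale** in calibration: replace (see above).
* **MFE categories are distinct rounded values**, not interval bins — the
  observed growth of category counts with sequence diversity behaves like a
  distinct-value count.
* **Unique-region fallback order**: degree-1 region first, then smallest
  maximum degree above 1, then unquantifiable status.
* **Amplitude-only fixed fits in closed form** rather than iterative.
* **Fragment-size amplitude** uses a sum-normalised Gaussian template so a
  histogram exactly proportional to the global shape returns its own total.

## Known limitations

* Calibrated counts inherit the lack-of-fit of the Gaussian to the
  modeling histogram: post-calibration CV cannot drop below the weighted
  relative deviation of n_c from A·g(x_c).  On small transcripts or very
  fine category grids (few k-mers per category) this floor can approach the
  raw CV; the benchmark shines when categories are well populated, as in
  the spike-in panel (≈7k per GC class) or k ≫ category-count regimes.
* The fixed-parameter CDF amplitude estimates the *observed-scale*
  abundance anchored to the modeling shape; when the bias tilts counts
  along the MFE axis it recovers the truth better than a free fit, but a
  uniform global suppression of counts is indistinguishable from lower
  abundance for any amplitude-only method.
* No uncertainty intervals on amplitudes; no joint deconvolution of
  regions shared between isoforms (unique/minimal-shared regions sidestep
  it).
* Acceptance and example problem sizes (2 kb transcripts, 100×, 8 N
  spike-ins) were chosen to exercise every code path at desk scale while
  keeping the full suite fast; all are parameters, not constants.
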