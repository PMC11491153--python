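"""Minimum free energy of k-mers under pluggable secondary-structure engines.

Two engines are provided:

* ``builtin`` — a Nussinov-style dynamic program that minimises the summed
  base-pair energy over all nested (pseudoknot-free) structures, with pair
  energies GC = -3.0, AU = -2.0, GU = -1.0 kcal/mol and a minimum hairpin
  loop of 3 unpaired bases.  Deterministic, dependency-free, and strongly
  GC-MFE anticorrelated, which is all the self-benchmarking machinery
  requires of an MFE scalar.
* ``vienna`` — an adapter to the ViennaRNA nearest-neighbor model at a
  configurable temperature (default 37 degC), used when the ``RNA`` Python
  bindings are importable.

Both engines return MFE <= 0 (the open chain at energy 0 is always an
admissible structure) rounded to a precision quantum (default 0.1 kcal/mol);
this rounding defines MFE category identity downstream.
"""

from __future__ import annotations

from ._errors import InputError

#: Base-pair stacking-free pair energies of the builtin engine, kcal/mol.
PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

#: Minimum number of unpaired bases enclosed by a hairpin-closing pair.
MIN_HAIRPIN = 3

_RNA_BASES = frozenset("ACGU")


def _to_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_BASES
    if bad:
        raise InputError(f"unsupported characters for folding: {sorted(bad)}")
    if not s:
        raise InputError("cannot fold an empty sequence")
    return s


class FoldEngine:
    """Base class: deterministic sequence -> MFE (kcal/mol), with a
    per-engine cache so duplicated k-mers fold once."""

    name = "abstract"

    def __init__(self, temperature: float = 37.0, precision: float = 0.1):
        if precision <= 0:
            raise InputError("precision must be > 0")
        self.temperature = float(temperature)
        self.precision = float(precision)
        self._cache: dict[str, float] = {}
        self.n_calls = 0  # raw folding calls (cache misses)

    def _fold(self, rna: str) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def mfe(self, seq: str) -> float:
        """MFE of ``seq`` rounded to the engine precision; 0.0 when no base
        pair is admissible.  T and U spellings are equivalent."""
        rna = _to_rna(seq)
        if rna not in self._cache:
            self.n_calls += 1
            raw = min(self._fold(rna), 0.0)
            q = self.precision
            self._cache[rna] = round(round(raw / q) * q, 10)
        return self._cache[rna]

    def mfe_batch(self, seqs) -> list[float]:
        """Element-wise :meth:`mfe`, order preserved, cached by sequence."""
        out = []
        for i, s in enumerate(seqs):
            try:
                out.append(self.mfe(s))
            except InputError as exc:
                raise InputError(f"sequence #{i}: {exc}") from exc
        return out


class BuiltinEngine(FoldEngine):
    """Nussinov-style pair-energy minimisation (no pseudoknots).

    E[i,j] = min( E[i,j-1],
                  min over pairable t with j-t > MIN_HAIRPIN of
                      E[i,t-1] + E[t+1,j-1] + e(t,j) ).
    """

    name = "builtin"

    def _fold(self, rna: str) -> float:
        n = len(rna)
        if n <= MIN_HAIRPIN + 1:
            return 0.0
        E = [[0.0] * n for _ in range(n)]
        for span in range(MIN_HAIRPIN + 1, n):
            for i in range(n - span):
                j = i + span
                row_i = E[i]
                best = row_i[j - 1]
                bj = rna[j]
                for t in range(i, j - MIN_HAIRPIN):
                    e = PAIR_ENERGY.get((rna[t], bj))
                    if e is None:
                        continue
                    cand = (row_i[t - 1] if t > i else 0.0) + E[t + 1][j - 1] + e
                    if cand < best:
                        best = cand
                row_i[j] = best
        return E[0][n - 1]


class ViennaEngine(FoldEngine):
    """Adapter to the ViennaRNA nearest-neighbor model (requires the ``RNA``
    Python bindings)."""

    name = "vienna"

    def __init__(self, temperature: float = 37.0, precision: float = 0.1):
        super().__init__(temperature=temperature, precision=precision)
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise InputError(
                "ViennaRNA Python bindings not available; "
                "use engine='builtin'"
            ) from exc
        self._RNA = RNA
        self._md = RNA.md()
        self._md.temperature = self.temperature

    def _fold(self, rna: str) -> float:
        fc = self._RNA.fold_compound(rna, self._md)
        _, e = fc.mfe()
        return float(e)


def get_engine(name: str = "builtin", temperature: float = 37.0,
               precision: float = 0.1) -> FoldEngine:
    """Factory for fold engines by name ('builtin' or 'vienna')."""
    if name == "builtin":
        return BuiltinEngine(temperature=temperature, precision=precision)
    if name == "vienna":
        return ViennaEngine(temperature=temperature, precision=precision)
    raise InputError(f"unknown fold engine {name!r}")


def annotate_mfe(kmers, engine: FoldEngine):
    """Fill the ``mfe`` column of a k-mer table (in a copy)."""
    out = kmers.copy()
    out["mfe"] = engine.mfe_batch(out["kmer"].tolist())
    return out
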