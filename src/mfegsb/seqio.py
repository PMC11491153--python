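"""Sequence and count-table I/O plus k-mer extraction and counting.

The package works on two in-memory containers:

* :class:`Transcript` — a named nucleotide sequence (typically one isoform).
* a *k-mer table* — a :class:`pandas.DataFrame` with one row per k-mer start
  position of a transcript (columns in :data:`KMER_COLUMNS`).  Three count
  columns carry the three roles a k-mer count plays in self-benchmarking:
  ``count_model`` (the uniform-coverage modeling count, 1 per k-mer),
  ``count_obs`` (observed sequencing count) and ``count_cal`` (calibrated
  count, filled by :mod:`mfegsb.gsb`).

Coordinates are 0-based half-open throughout; TSV output additionally prints
a 1-based start for human reading.
"""

from __future__ import annotations

import gzip
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._errors import InputError

#: Column order of a k-mer table.
KMER_COLUMNS = [
    "transcript_id",
    "start",
    "kmer",
    "gc",
    "mfe",
    "count_obs",
    "count_model",
    "count_cal",
    "duplicated",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Transcript:
    """A named nucleotide sequence; U is normalised to T on construction."""

    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise InputError(f"transcript {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path, ambiguous: str = "error") -> list[Transcript]:
    """Read transcripts from a (optionally gzipped) FASTA file.

    Parameters
    ----------
    path : path-like
        FASTA file; record IDs are taken from the header up to the first
        whitespace.
    ambiguous : {"error", "mask"}
        How to treat non-ACGT/U characters: ``error`` rejects the record
        naming the offending position, ``mask`` replaces them with ``N``
        (k-mers containing N are later dropped by :func:`extract_kmers`).

    Raises
    ------
    InputError
        On an empty file, duplicate IDs, or ambiguous characters with
        ``ambiguous="error"``.
    """
    if ambiguous not in ("error", "mask"):
        raise InputError(f"unknown ambiguous policy {ambiguous!r}")
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise InputError(f"duplicate FASTA ID {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = str(rec.seq).upper().replace("U", "T")
            bad = [i for i, b in enumerate(seq) if b not in _VALID_BASES]
            if bad:
                if ambiguous == "error":
                    raise InputError(
                        f"record {rec.id!r}: non-ACGTU character "
                        f"{seq[bad[0]]!r} at position {bad[0]} "
                        f"({len(bad)} offending positions total)"
                    )
                seq = "".join(
                    b if b in _VALID_BASES else "N" for b in seq
                )
            transcripts.append(Transcript(rec.id, seq))
    if not transcripts:
        raise InputError(f"no FASTA records found in {path}")
    return transcripts


def gc_count(seq: str) -> int:
    """Number of G or C characters in ``seq`` (case-insensitive)."""
    if not seq:
        raise InputError("gc_count: empty sequence")
    s = seq.upper()
    return s.count("G") + s.count("C")


def extract_kmers(transcript: Transcript, k: int) -> pd.DataFrame:
    """Enumerate every k-mer of a transcript from its 5' end.

    Returns a k-mer table with ``max(L - k + 1, 0)`` rows, one per start
    position.  Counts are initialised to 0 (observed, calibrated NaN) and 1
    (modeling — the uniform-coverage assumption).  ``duplicated`` flags k-mer
    sequences occurring at more than one position.  K-mers containing ``N``
    (masked input) are dropped.

    If ``k > L`` an empty table is returned with a warning.
    """
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    L = transcript.length
    n = L - k + 1
    if n <= 0:
        warnings.warn(
            f"transcript {transcript.id!r} shorter than k "
            f"({L} < {k}): no k-mers extracted"
        )
        n = 0
    seq = transcript.sequence
    starts, kmers = [], []
    for i in range(n):
        km = seq[i : i + k]
        if "N" in km:
            continue
        starts.append(i)
        kmers.append(km)
    df = pd.DataFrame(
        {
            "transcript_id": transcript.id,
            "start": np.asarray(starts, dtype=np.int64),
            "kmer": kmers,
            "gc": np.asarray([gc_count(s) for s in kmers], dtype=np.int64)
            if kmers
            else np.asarray([], dtype=np.int64),
            "count_obs": 0.0,
            "count_model": 1.0,
            "count_cal": np.nan,
        }
    )
    df["mfe"] = np.nan
    df["duplicated"] = df["kmer"].duplicated(keep=False) if len(df) else pd.Series([], dtype=bool)
    return df[KMER_COLUMNS]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iter_reads(reads, fmt=None):
    """Yield read sequences from a path (FASTA/FASTQ, optionally gzipped) or
    an iterable of strings."""
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        name = path.name[:-3] if path.name.endswith(".gz") else path.name
        if fmt is None:
            if name.endswith((".fq", ".fastq")):
                fmt = "fastq"
            else:
                fmt = "fasta"
        with _open_maybe_gzip(path) as fh:
            for rec in SeqIO.parse(fh, fmt):
                yield str(rec.seq).upper().replace("U", "T")
    else:
        for r in reads:
            yield str(r).upper().replace("U", "T")


def count_kmers_in_reads(
    reads,
    kmers: Iterable[str],
    strand: str = "forward",
    fmt: str | None = None,
) -> tuple[Counter, dict]:
    """Count exact occurrences of query k-mers in sequencing reads.

    Every length-k substring of every read (sliding window, step 1) is
    matched exactly against the query set; with ``strand="both"`` the
    reverse complement of each substring is matched as well.  Reads shorter
    than k are skipped and tallied, never padded.

    Returns ``(counts, summary)`` where ``counts`` maps k-mer sequence to
    its total count and ``summary`` reports reads processed, reads skipped
    as too short, and total matches.
    """
    query = set(kmers)
    if not query:
        raise InputError("count_kmers_in_reads: empty query k-mer set")
    ks = {len(s) for s in query}
    if len(ks) != 1:
        raise InputError(f"query k-mers have mixed lengths: {sorted(ks)}")
    if strand not in ("forward", "both"):
        raise InputError(f"unknown strand {strand!r}")
    k = ks.pop()
    counts: Counter = Counter()
    n_reads = n_short = n_matches = 0
    for read in _iter_reads(reads, fmt=fmt):
        n_reads += 1
        if len(read) < k:
            n_short += 1
            continue
        for i in range(len(read) - k + 1):
            sub = read[i : i + k]
            if sub in query:
                counts[sub] += 1
                n_matches += 1
            if strand == "both":
                rc = reverse_complement(sub)
                if rc in query:
                    counts[rc] += 1
                    n_matches += 1
    summary = {
        "reads": n_reads,
        "reads_too_short": n_short,
        "total_matches": n_matches,
        "k": k,
        "strand": strand,
    }
    return counts, summary


def attach_observed_counts(kmers: pd.DataFrame, counts: Mapping[str, float]) -> pd.DataFrame:
    """Fill ``count_obs`` from a k-mer sequence -> count mapping.

    A k-mer sequence occurring at several positions shares one observed
    count, assigned to every position carrying it (those rows are already
    flagged ``duplicated``).  Missing k-mers get 0.
    """
    out = kmers.copy()
    out["count_obs"] = out["kmer"].map(counts).fillna(0.0).astype(float)
    return out


def write_kmer_table(kmers: pd.DataFrame, path, category_id=None) -> None:
    """Write a k-mer table as TSV (adds 1-based ``start1`` for humans)."""
    out = kmers.copy()
    out.insert(2, "start1", out["start"] + 1)
    out = out.rename(columns={"start": "start0"})
    if category_id is not None:
        out["category_id"] = np.asarray(category_id)
    out.to_csv(path, sep="\t", index=False)


def read_kmer_table(path) -> pd.DataFrame:
    """Read a k-mer table TSV written by :func:`write_kmer_table` (or a
    minimal table with at least transcript_id/start0/kmer columns)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise InputError(f"malformed k-mer TSV {path}: {exc}") from exc
    if "start0" in df.columns:
        df = df.rename(columns={"start0": "start"})
    missing = {"transcript_id", "start", "kmer"} - set(df.columns)
    if missing:
        raise InputError(f"k-mer TSV {path} missing columns {sorted(missing)}")
    for col, default in [
        ("gc", None),
        ("mfe", np.nan),
        ("count_obs", 0.0),
        ("count_model", 1.0),
        ("count_cal", np.nan),
        ("duplicated", False),
    ]:
        if col not in df.columns:
            if col == "gc":
                df["gc"] = [gc_count(s) for s in df["kmer"]]
            else:
                df[col] = default
    return df[KMER_COLUMNS + [c for c in df.columns if c not in KMER_COLUMNS and c != "start1"]]
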