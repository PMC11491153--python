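"""Shared fixtures: all data are generated programmatically at test time."""

import numpy as np
import pandas as pd
import pytest

import mfegsb as m

# Frozen study scenario: a 2 kb random transcript at 100x abundance with the
# default multiplicative GC+MFE biases and Poisson noise.
STUDY_SEED = 1
STUDY_BIAS_SEED = 101
STUDY_L = 2000
STUDY_K = 50
STUDY_ALPHA = 100.0


@pytest.fixture(scope="session")
def engine():
    return m.get_engine("builtin")


@pytest.fixture(scope="session")
def study_transcript():
    return m.random_transcript(STUDY_L, 0.5, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_kmers(study_transcript, engine):
    return m.annotate_mfe(m.extract_kmers(study_transcript, STUDY_K), engine)


@pytest.fixture(scope="session")
def study_obs(study_kmers):
    bias = m.BiasModel(seed=STUDY_BIAS_SEED)
    return m.simulate_counts(study_kmers, STUDY_ALPHA, bias)


@pytest.fixture(scope="session")
def spikein_cores():
    return m.enumerate_spikeins(m.SpikeinDesign(), with_flanks=False)


@pytest.fixture(scope="session")
def spikein_kmers(spikein_cores):
    """Spike-in panel as a k-mer table (one 50-mer per variant)."""
    return pd.DataFrame(
        {
            "transcript_id": "spikein",
            "start": np.arange(len(spikein_cores)),
            "kmer": spikein_cores,
            "gc": [m.gc_count(s) for s in spikein_cores],
            "mfe": np.nan,
            "count_obs": 0.0,
            "count_model": 1.0,
            "count_cal": np.nan,
            "duplicated": False,
        }
    )


def make_kmer_table(seqs, counts=None):
    """Minimal k-mer table around explicit sequences (test helper)."""
    df = pd.DataFrame(
        {
            "transcript_id": "t",
            "start": np.arange(len(seqs)),
            "kmer": list(seqs),
            "gc": [m.gc_count(s) for s in seqs],
            "mfe": np.nan,
            "count_obs": 0.0,
            "count_model": 1.0,
            "count_cal": np.nan,
            "duplicated": False,
        }
    )
    if counts is not None:
        df["count_obs"] = np.asarray(counts, dtype=float)
    return df
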