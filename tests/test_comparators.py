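"""Empirical bias comparators: GC LOESS weights, fragment-size model,
hexamer weights and the smoothing baseline."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.nonparametric.smoothers_lowess import lowess

import mfegsb as m
from mfegsb import comparators
from mfegsb._errors import FitDegeneracyError, InputError
from mfegsb.binning import CategoryTable


def fragment_table(transcript, starts, lengths):
    rows = []
    for s, ln in zip(starts, lengths):
        rows.append((transcript.id, s, s + ln, ln,
                     transcript.sequence[s : s + 6]))
    return pd.DataFrame(
        rows, columns=["transcript_id", "start", "end", "length", "first6"]
    )


@pytest.fixture(scope="module")
def long_transcript():
    return m.random_transcript(5000, 0.5, seed=20, id="frag_t")


class TestLoessGcWeights:
    def test_flat_counts_give_unit_weights(self):
        """Equal fragment multiplicity in every GC bin -> weights all 1."""
        # synthetic fragments: one per distinct GC bin, repeated equally
        seqs = ["".join(["G"] * g + ["A"] * (50 - g)) for g in range(10, 30)]
        ts = {f"t{g}": m.Transcript(f"t{g}", s) for g, s in zip(range(10, 30), seqs)}
        frags = pd.DataFrame(
            [(tid, 0, 50, 50, t.sequence[:6]) for tid, t in ts.items()] * 5,
            columns=["transcript_id", "start", "end", "length", "first6"],
        )
        table = comparators.loess_gc_weights(frags, ts)
        for w in table.weights.values():
            assert w == pytest.approx(1.0, abs=1e-9)

    def test_local_excess_downweighted(self):
        """Bins carrying double the typical count are downweighted, in exact
        agreement with a direct LOESS oracle at that point."""
        gcs = np.arange(10.0, 40.0)  # 30 bins of 20, three doubled
        counts = np.full(30, 20)
        counts[14:17] = 40
        rows = []
        for g, c in zip(gcs, counts):
            seq = "G" * int(g) + "A" * (100 - int(g))  # gc% == g
            rows.extend([(f"t{int(g)}", 0, 100, 100, seq[:6])] * int(c))
        ts = {
            f"t{int(g)}": m.Transcript(f"t{int(g)}", "G" * int(g) + "A" * (100 - int(g)))
            for g in gcs
        }
        frags = pd.DataFrame(
            rows, columns=["transcript_id", "start", "end", "length", "first6"]
        )
        table = comparators.loess_gc_weights(frags, ts, span=0.3)
        smoothed = lowess(counts.astype(float), gcs, frac=0.3, it=0,
                          return_sorted=False)
        oracle = counts.mean() / smoothed[15]
        assert table.weights[25.0] == pytest.approx(oracle, rel=1e-9)
        assert table.weights[25.0] < 0.75  # excess bins are downweighted

    def test_too_few_bins_errors(self):
        t = m.Transcript("t", "ACGT" * 30)
        frags = fragment_table(t, [0] * 20, [40] * 20)
        with pytest.raises(InputError, match="GC bins"):
            comparators.loess_gc_weights(frags, {"t": t})


class TestApplyWeights:
    def test_unit_weights_identity(self, long_transcript):
        frags = fragment_table(long_transcript, range(100), [50] * 100)
        frags["count_obs"] = 2.0
        table = comparators.WeightTable("hexamer", {}, 0.5)  # all default 1
        out, summary = comparators.apply_weights(
            frags, table, lambda r: r.first6
        )
        np.testing.assert_allclose(out["count_obs_corrected"], 2.0)
        assert summary["total_before"] == summary["total_after"]

    def test_doubling_one_weight_hits_only_matches(self, long_transcript):
        frags = fragment_table(long_transcript, range(200), [50] * 200)
        frags["count_obs"] = 1.0
        target = frags["first6"].iloc[0]
        table = comparators.WeightTable("hexamer", {target: 2.0}, 0.5)
        out, _ = comparators.apply_weights(frags, table, lambda r: r.first6)
        matches = out["first6"] == target
        np.testing.assert_allclose(out.loc[matches, "count_obs_corrected"], 2.0)
        np.testing.assert_allclose(out.loc[~matches, "count_obs_corrected"], 1.0)

    def test_inverse_weights_round_trip(self, long_transcript):
        rng = np.random.default_rng(9)
        frags = fragment_table(long_transcript, range(150), [60] * 150)
        frags["count_obs"] = rng.uniform(1, 10, 150)
        hexes = frags["first6"].unique()
        w = {h: rng.uniform(0.2, 5.0) for h in hexes}
        winv = {h: 1.0 / v for h, v in w.items()}
        fwd, _ = comparators.apply_weights(
            frags, comparators.WeightTable("hexamer", w, 0.5), lambda r: r.first6
        )
        fwd["count_obs"] = fwd["count_obs_corrected"]
        back, _ = comparators.apply_weights(
            fwd, comparators.WeightTable("hexamer", winv, 0.5), lambda r: r.first6
        )
        np.testing.assert_allclose(
            back["count_obs_corrected"], frags["count_obs"], rtol=1e-12
        )


class TestFragmentSizeModel:
    def test_recovers_gaussian_lengths(self, long_transcript):
        rng = np.random.default_rng(30)
        lengths = np.clip(rng.normal(300, 30, 10000).round().astype(int), 10, 4000)
        starts = rng.integers(0, 1000, 10000)
        frags = fragment_table(long_transcript, starts, lengths)
        params = comparators.fragment_size_model(frags)
        assert params.mu == pytest.approx(300.0, abs=1.0)
        assert params.sigma == pytest.approx(30.0, abs=1.0)

    def test_proportional_histogram_amplitude(self):
        """A transcript whose length histogram is exactly proportional to
        the global Gaussian shape with total 500 gets amplitude 500."""
        params = m.GaussianParams(A=1.0, mu=300.0, sigma=30.0, r2=1.0)
        grid = np.arange(int(300 - 4 * 30), int(300 + 4 * 30) + 1)
        shape = np.exp(-((grid - 300.0) ** 2) / (2 * 30.0**2))
        shape = shape / shape.sum()
        counts = np.round(500 * shape * 1e6) / 1e6
        lengths = np.repeat(grid, np.maximum((500 * shape * 100).astype(int), 0))
        frags = pd.DataFrame(
            {"transcript_id": "t", "start": 0, "end": lengths,
             "length": lengths, "first6": "ACGTAC"}
        )
        out = comparators.calibrate_by_size(frags, params)
        total = len(lengths)
        assert out["amplitude"] == pytest.approx(total, rel=0.01)

    def test_truncated_sizes_shift_amplitude(self, long_transcript):
        rng = np.random.default_rng(31)
        global_lengths = rng.normal(300, 30, 5000).round().astype(int)
        frags = fragment_table(long_transcript, rng.integers(0, 1000, 5000),
                               np.clip(global_lengths, 10, 4000))
        params = comparators.fragment_size_model(frags)
        capped = np.clip(rng.normal(300, 30, 400).round().astype(int), 10, 290)
        tfrags = fragment_table(long_transcript, rng.integers(0, 1000, 400), capped)
        out = comparators.calibrate_by_size(tfrags, params)
        assert out["raw_total"] == 400
        assert out["amplitude"] != pytest.approx(400, rel=0.02)

    def test_degenerate_lengths_error(self, long_transcript):
        frags = fragment_table(long_transcript, range(200), [50] * 200)
        with pytest.raises(FitDegeneracyError):
            comparators.fragment_size_model(frags)

    def test_too_few_fragments_error(self, long_transcript):
        frags = fragment_table(long_transcript, range(50), [50] * 50)
        with pytest.raises(InputError, match=">= 100"):
            comparators.fragment_size_model(frags)


class TestHexamerWeights:
    def test_always_4096_rows(self):
        frags = pd.DataFrame({"first6": ["AAAAAA", "ACGTAC"]})
        with pytest.warns(UserWarning, match="noisy"):
            table = m.hexamer_weights(frags)
        assert len(table.weights) == 4096

    def test_uniform_starts_give_exact_unit_weights(self):
        frags = pd.DataFrame({"first6": comparators.ALL_HEXAMERS * 3})
        table = m.hexamer_weights(frags)
        w = np.array(list(table.weights.values()))
        assert len(w) == 4096
        np.testing.assert_allclose(w, 1.0, atol=1e-12)

    def test_single_hexamer_limit(self):
        frags = pd.DataFrame({"first6": ["AAAAAA"] * 8192})
        table = m.hexamer_weights(frags)
        # observed hexamer strongly downweighted; unseen ones capped at
        # baseline/pseudocount before rescaling
        assert table.weights["AAAAAA"] * 8192 == pytest.approx(8192 / 8192 * 8192 * table.weights["AAAAAA"])
        assert table.weights["AAAAAA"] < table.weights["CCCCCC"]
        # count-weighted mean weight is one
        assert table.weights["AAAAAA"] == pytest.approx(1.0)

    def test_simulated_preference_corrected(self):
        """A 4x preference for one hexamer is flattened by the weights."""
        rng = np.random.default_rng(17)
        p = np.ones(4096)
        p[0] = 4.0  # AAAAAA
        p /= p.sum()
        draws = rng.multinomial(200_000, p)
        frags = pd.DataFrame(
            {"first6": np.repeat(comparators.ALL_HEXAMERS, draws)}
        )
        table = m.hexamer_weights(frags)
        corrected = np.array(
            [draws[i] * table.weights[h]
             for i, h in enumerate(comparators.ALL_HEXAMERS)]
        )
        resid = (corrected - corrected.mean()) / np.sqrt(corrected.mean())
        # the formerly 4x hexamer is now within 3 SE of the common mean
        assert abs(resid[0]) < 3

    def test_invalid_hexamer_errors(self):
        frags = pd.DataFrame({"first6": ["ACGTXX"] * 5000})
        with pytest.raises(InputError, match="invalid hexamer"):
            m.hexamer_weights(frags)


class TestSmoothing:
    def _table(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return CategoryTable(
            key="mfe", values=x, n_kmers=np.ones(len(x), dtype=int),
            agg_model=np.ones(len(x)), agg_obs=y,
            assignment=np.zeros(0, dtype=int),
        )

    def test_exact_gaussian_preserved(self):
        x = np.linspace(-20, 0, 40)
        y = 100 * np.exp(-((x + 10) ** 2) / 18.0)
        pred = m.smooth_category_counts(self._table(x, y), span=0.3)
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_flat_input_flat_output(self):
        x = np.arange(10.0)
        pred = m.smooth_category_counts(self._table(x, np.full(10, 7.0)))
        np.testing.assert_allclose(pred, 7.0, atol=1e-9)

    def test_spike_attenuated(self):
        x = np.arange(20.0)
        y = np.full(20, 5.0)
        y[10] = 50.0
        pred = m.smooth_category_counts(self._table(x, y), span=0.4)
        assert pred.max() < y.max()

    def test_too_few_categories_errors(self):
        with pytest.raises(InputError, match=">= 5"):
            m.smooth_category_counts(self._table([0, 1, 2, 3], [1, 2, 2, 1]))


class TestOwnBiasReduction:
    """Each comparator, fed data carrying only its own bias, reduces the
    spread of counts over its key."""

    def test_hexamer_comparator(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(0.5, 2.0, 4096)
        p /= p.sum()
        draws = rng.multinomial(500_000, p)
        frags = pd.DataFrame({"first6": np.repeat(comparators.ALL_HEXAMERS, draws)})
        table = m.hexamer_weights(frags)
        corrected = np.array(
            [draws[i] * table.weights[h]
             for i, h in enumerate(comparators.ALL_HEXAMERS)]
        )
        assert m.cv(corrected) < m.cv(draws.astype(float))

    def test_gc_loess_comparator(self, study_obs):
        """GC-only biased k-mer counts become more uniform after GC LOESS
        weighting."""
        base = study_obs.copy()
        bias = m.BiasModel(beta_gc=0.06, beta_mfe=0.0, seed=77)
        obs = m.simulate_counts(base.assign(mfe=np.nan), 100.0, bias)
        table = comparators.loess_mean_weights(obs["gc"], obs["count_obs"])
        w = np.array([table.weight(float(g)) for g in obs["gc"]])
        corrected = obs["count_obs"].to_numpy() * w
        assert m.cv(corrected) < m.cv(obs["count_obs"].to_numpy())

    def test_size_comparator_neutral_on_conforming_transcript(self, long_transcript):
        """A transcript whose fragment sizes follow the global law keeps its
        count: the size-calibrated amplitude matches the raw total."""
        rng = np.random.default_rng(41)
        lengths = np.clip(rng.normal(300, 30, 8000).round().astype(int), 10, 4000)
        frags = fragment_table(long_transcript, rng.integers(0, 1000, 8000), lengths)
        params = comparators.fragment_size_model(frags)
        sub = np.clip(rng.normal(300, 30, 400).round().astype(int), 10, 4000)
        tfrags = fragment_table(long_transcript, rng.integers(0, 1000, 400), sub)
        out = comparators.calibrate_by_size(tfrags, params)
        assert out["amplitude"] == pytest.approx(out["raw_total"], rel=0.05)


class TestMixedBiasComparison:
    def test_mfe_benchmark_beats_single_bias_comparators(self, study_obs):
        """With GC and MFE biases acting together, MFE-keyed self-
        benchmarking yields the most uniform per-k-mer counts: each
        empirical comparator corrects its one axis and leaves the rest."""
        cvs = {}
        for key in ("gc", "mfe"):
            table = m.categorize(study_obs, key)
            params = m.fit_gaussian_free(table, which="model")
            fit = m.fit_amplitude_fixed(table, params.mu, params.sigma)
            _, summary = m.calibrate_kmers(study_obs, table, fit)
            cvs[f"{key}_benchmark"] = summary["cv_cal"]
            smoothed = comparators.smooth_category_counts(table, span=0.3)
            cvs[f"{key}_smoothing"] = m.cv(
                smoothed[table.assignment] / table.n_kmers[table.assignment]
            )
        wt = comparators.loess_mean_weights(study_obs["gc"], study_obs["count_obs"])
        w = np.array([wt.weight(float(g)) for g in study_obs["gc"]])
        cvs["gc_loess_weighting"] = m.cv(study_obs["count_obs"].to_numpy() * w)
        best = cvs.pop("mfe_benchmark")
        for method, value in cvs.items():
            assert best <= value, (method, value, best)
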