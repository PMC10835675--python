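"""Attention aggregation, integrated gradients, extremes and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import probedepth as pp
from probedepth.interpret import ig_core


class TestAttentionScores:
    def test_conservation_single_sequence(self, trained_tiny):
        """Softmax rows sum to 1, so each head's aggregate over one
        unmasked sequence equals its query count."""
        model, _, panel = trained_tiny
        one = pp.ProbeSet([panel.records[0]])
        t = len(panel.records[0].sequence) - model.config.k + 1 + 1  # tokens + CLS
        summary = pp.attention_scores(model, one)
        np.testing.assert_allclose(summary.forward_scores, t, atol=1e-4)
        np.testing.assert_allclose(summary.reverse_scores, t, atol=1e-4)

    def test_additive_over_dataset(self, trained_tiny):
        model, _, panel = trained_tiny
        once = pp.attention_scores(model, panel)
        doubled_set = pp.ProbeSet(
            list(panel.records)
            + [pp.ProbeRecord(r.probe_id + "_b", r.sequence, r.observed_depth)
               for r in panel.records]
        )
        twice = pp.attention_scores(model, doubled_set)
        np.testing.assert_allclose(twice.forward_scores, 2 * once.forward_scores, rtol=1e-5)

    def test_branches_differ_for_untied_model(self, trained_tiny):
        """The two untied encoders learn distinct attention patterns; the
        per-pair weight distributions (not the conserved per-head totals)
        carry the difference."""
        model, _, panel = trained_tiny
        ids_f, ids_r, mask = pp.encode_batch(panel.sequences[:4], model.vocab)
        cap = {}
        model.forward_ids(ids_f, ids_r, mask, capture_attention=cap)
        diff = max(
            np.abs(pf - pr).max() for pf, pr in zip(cap["fwd"], cap["rev"])
        )
        assert diff > 1e-3

    def test_long_format_frame(self, trained_tiny):
        model, _, panel = trained_tiny
        frame = pp.attention_scores(model, panel).to_frame()
        cfg = model.config
        assert len(frame) == 2 * cfg.n_layers * cfg.n_heads
        assert set(frame["branch"]) == {"forward", "reverse"}


class TestIntegratedGradients:
    def test_linear_function_closed_form(self):
        """IG is exact for linear maps: IG_i = w_i * (x_i - b_i) at any
        step count."""
        rng = np.random.default_rng(0)
        w = rng.normal(size=(6, 4))
        x = rng.normal(size=(6, 4))
        baseline = np.zeros((6, 4))

        def forward_fn(batch):
            vals = (batch * w).sum(axis=(-2, -1))
            grads = np.broadcast_to(w, batch.shape).copy()
            return vals, grads

        attr, fx, fb = ig_core(forward_fn, x, baseline, steps=8)
        np.testing.assert_allclose(attr, w * x, atol=1e-6)
        assert fx - fb == pytest.approx(attr.sum(), abs=1e-9)

    def test_constant_model_zero_attributions(self, small_model_cfg):
        model = pp.DepthModel(small_model_cfg)
        model.params["head.W2"].data[:] = 0.0  # output is the head bias only
        att = pp.integrated_gradients(model, "ACGTACGTACGT", steps=8)
        np.testing.assert_allclose(att.ig_values, 0.0, atol=1e-6)
        assert att.completeness_gap == pytest.approx(0.0, abs=1e-6)

    def test_completeness_on_trained_model(self, trained_tiny):
        model, _, panel = trained_tiny
        for rec in panel.records[:8]:
            att = pp.integrated_gradients(model, rec, steps=128)
            delta = att.prediction - att.baseline_prediction
            assert abs(att.completeness_gap) <= 0.05 * abs(delta) + 1e-3

    def test_token_count_matches_sequence(self, small_model_cfg):
        model = pp.DepthModel(small_model_cfg)
        att = pp.integrated_gradients(model, "ACGTACGTACGTACG", steps=8)
        assert att.ig_values.shape == (15 - 3 + 1,)

    def test_too_few_steps_rejected(self, small_model_cfg):
        model = pp.DepthModel(small_model_cfg)
        with pytest.raises(ValueError):
            pp.integrated_gradients(model, "ACGTACGT", steps=4)


class TestPositionalImportance:
    def test_zero_attributions_zero_profile(self):
        atts = [pp.AttributionResult("p", np.zeros(5), 0.0, 0.0, 0.0, 8)
                for _ in range(3)]
        np.testing.assert_array_equal(pp.positional_importance(atts), np.zeros(5))

    def test_profile_length_matches_tokens(self, trained_tiny):
        model, _, panel = trained_tiny
        atts = [pp.integrated_gradients(model, r, steps=8) for r in panel.records[:4]]
        profile = pp.positional_importance(atts)
        assert profile.shape == (len(panel.records[0].sequence) - 3 + 1,)

    def test_ragged_lengths_rejected(self):
        atts = [pp.AttributionResult("a", np.zeros(5), 0, 0, 0, 8),
                pp.AttributionResult("b", np.zeros(7), 0, 0, 0, 8)]
        with pytest.raises(ValueError, match="group"):
            pp.positional_importance(atts)


class TestMotifTokenMask:
    def test_interior_motif_covers_expected_windows(self):
        # CTT at positions 3-5 of a 10-mer: trimer windows 1..5 overlap it
        mask = pp.motif_token_mask("AAACTTAAAA", "CTT", k=3)
        assert mask.tolist() == [False, True, True, True, True, True, False, False]

    def test_absent_motif_empty_mask(self):
        assert not pp.motif_token_mask("AAAAAAA", "CTT", k=3).any()


class TestExtremeDepthSets:
    def test_rate_05_thresholds(self):
        """The per-tail cut at rate 0.05 is the 1.6449 standard-normal quantile."""
        z = np.array([-2.0, -1.7, -1.0, 0.0, 1.0, 1.7, 2.0])
        ids = list("abcdefg")
        high, low = pp.extreme_depth_sets(z, ids, rate=0.05)
        assert high == ["f", "g"] and low == ["a", "b"]

    def test_tail_counts_near_expectation(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(10_000)
        high, low = pp.extreme_depth_sets(z, [str(i) for i in range(10_000)], rate=0.05)
        lo_bound, hi_bound = stats.binom.ppf([0.005, 0.995], 10_000, 0.05)
        assert lo_bound <= len(high) <= hi_bound
        assert lo_bound <= len(low) <= hi_bound

    def test_monotone_in_rate(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(500)
        ids = [str(i) for i in range(500)]
        h1, l1 = pp.extreme_depth_sets(z, ids, rate=0.02)
        h2, l2 = pp.extreme_depth_sets(z, ids, rate=0.10)
        assert set(h1) <= set(h2) and set(l1) <= set(l2)

    def test_rate_out_of_range(self):
        with pytest.raises(ValueError):
            pp.extreme_depth_sets(np.zeros(3), ["a", "b", "c"], rate=0.6)


def _random_probes(n, length, seed, prefix="p"):
    rng = np.random.default_rng(seed)
    return pp.ProbeSet(
        [pp.ProbeRecord(f"{prefix}{i}", "".join(rng.choice(list("ACGT"), length)), 1.0)
         for i in range(n)]
    )


class TestKmerEnrichment:
    def test_subset_equals_background_all_ratios_one(self):
        probes = _random_probes(30, 30, seed=0)
        table = pp.kmer_enrichment(probes, probes, k=3)
        np.testing.assert_allclose(table["ratio"], 1.0)

    def test_poly_c_subset_enriches_ccc(self):
        subset = pp.ProbeSet([pp.ProbeRecord("c1", "C" * 20, 1.0)])
        background = _random_probes(50, 20, seed=1, prefix="b")
        table = pp.kmer_enrichment(subset, background, k=3).set_index("kmer")
        assert table.loc["CCC", "ratio"] > 10

    def test_planted_double_frequency_ratio_near_two(self):
        """Doubling a k-mer's frequency in the subset doubles its ratio."""
        rng = np.random.default_rng(2)
        background = _random_probes(400, 60, seed=3, prefix="bg")
        # subset: background-like probes with extra CTT insertions
        records = []
        for i in range(400):
            seq = list("".join(rng.choice(list("ACGT"), 60)))
            for start in rng.choice(57, size=2, replace=False):
                seq[start:start + 3] = "CTT"
            records.append(pp.ProbeRecord(f"s{i}", "".join(seq), 1.0))
        subset = pp.ProbeSet(records)
        table = pp.kmer_enrichment(subset, background, k=3).set_index("kmer")
        bg_freq = table.loc["CTT", "freq_background"]
        expected = table.loc["CTT", "freq_subset"] / bg_freq
        assert table.loc["CTT", "ratio"] == pytest.approx(expected)
        # planted two occurrences per 58 windows over background ~1/64 rate
        assert 1.5 < table.loc["CTT", "ratio"] < 4.0

    def test_empty_group_rejected(self):
        probes = _random_probes(3, 10, seed=4)
        with pytest.raises(ValueError):
            pp.kmer_enrichment(pp.ProbeSet([]), probes)


class TestThermoCorrelation:
    def test_identical_and_reversed_rankings(self):
        ig = pd.Series(np.arange(12, dtype=float), index=[f"p{i}" for i in range(12)])
        table = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(12)],
            "free_energy": np.arange(12, dtype=float),
            "stability": -np.arange(12, dtype=float),
        })
        taus = pp.thermo_correlation(ig, table)
        assert taus["free_energy"] == pytest.approx(1.0)
        assert taus["stability"] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        ids = [f"p{i}" for i in range(1000)]
        ig = pd.Series(rng.normal(size=1000), index=ids)
        table = pd.DataFrame({"probe_id": ids, "metric": rng.normal(size=1000)})
        assert abs(pp.thermo_correlation(ig, table)["metric"]) < 0.08

    def test_too_few_pairs_rejected(self):
        ig = pd.Series([1.0, 2.0], index=["a", "b"])
        table = pd.DataFrame({"probe_id": ["a", "b"], "m": [1.0, 2.0]})
        with pytest.raises(ValueError, match="10"):
            pp.thermo_correlation(ig, table)

    def test_constant_column_rejected(self):
        ids = [f"p{i}" for i in range(20)]
        ig = pd.Series(np.arange(20.0), index=ids)
        table = pd.DataFrame({"probe_id": ids, "m": np.ones(20)})
        with pytest.raises(ValueError, match="constant"):
            pp.thermo_correlation(ig, table)
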