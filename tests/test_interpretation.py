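import numpy as np
import pandas as pd
import pytest

from revhom.encoding import ALPHABET, AA_INDEX, encode_batch
from revhom.interpretation import (LetterMap, build_feature_logo,
                                   extract_features, feature_name,
                                   feature_values, letter_map_summary,
                                   max_feature_span, mutation_map,
                                   parse_feature_name, position_activations,
                                   rank_top_features, smooth_activations)

L = 48  # length of the rrxs_detector standard input


def _seq_with_motif(pos, motif="RRAS", filler="A"):
    return filler * pos + motif + filler * (L - pos - len(motif))


class TestFeatureNames:
    def test_roundtrip(self):
        assert feature_name(("max", 244)) == "Max F244"
        assert feature_name(("avg", 3)) == "Average F3"
        assert parse_feature_name("Max F244") == ("max", 244)
        assert parse_feature_name("Average F3") == ("avg", 3)


class TestExtractFeatures:
    def test_column_layout_and_determinism(self, tiny_model):
        feats = extract_features(tiny_model, ["MKRS", "MKRS", "AAAA"],
                                 ids=["a", "b", "c"])
        assert feats.shape == (3, 2 * tiny_model.config.conv3_filters)
        assert list(feats.columns[:2]) == ["Max F0", "Max F1"]
        assert feats.columns[tiny_model.config.conv3_filters] == "Average F0"
        # duplicate sequences give identical rows
        np.testing.assert_array_equal(feats.loc["a"].values,
                                      feats.loc["b"].values)
        again = extract_features(tiny_model, ["MKRS"], ids=["a"])
        np.testing.assert_array_equal(again.loc["a"].values,
                                      feats.loc["a"].values)

    def test_detector_feature_value(self, rrxs_detector):
        X = encode_batch([_seq_with_motif(10), "A" * L], L)
        vals = feature_values(rrxs_detector, X, ("max", 0))
        assert vals[0] == pytest.approx(1.0)
        assert vals[1] == 0.0


class TestPositionActivations:
    def test_trace_length_and_argmax_consistency(self, rrxs_detector):
        seq = _seq_with_motif(20)
        trace = position_activations(rrxs_detector, seq, 0)
        assert trace.shape == (L,)
        # the max of the trace is what max pooling reports
        X = encode_batch([seq], L)
        assert trace.max() == feature_values(rrxs_detector, X, ("max", 0))[0]
        assert trace.argmax() == 22  # R at 20,21 and S at 23 sit at offsets
        # -2,-1,+1 of the kernel, centered at 22

    def test_invalid_channel(self, rrxs_detector):
        with pytest.raises(ValueError):
            position_activations(rrxs_detector, "AAAA", 7)


class TestBuildFeatureLogo:
    def test_polya_single_sequence_max_feature(self, tiny_model):
        cfg = tiny_model.config
        pfm = build_feature_logo(tiny_model, ["A" * cfg.L_std], ("max", 0),
                                 min_sequences=1)
        probs = pfm.probabilities()
        ok = pfm.n_contributions > 0
        assert ok.any()
        assert np.all(probs[ok, AA_INDEX["A"]] == 1.0)

    def test_detector_recovers_planted_consensus(self, rrxs_detector):
        rng = np.random.default_rng(0)
        seqs = []
        for _ in range(30):
            pos = int(rng.integers(5, L - 10))
            # vary the wildcard position
            wc = ALPHABET[int(rng.integers(20))]
            seqs.append(_seq_with_motif(pos, "RR" + wc + "S", filler="G"))
        pfm = build_feature_logo(rrxs_detector, seqs, ("max", 0))
        probs = pfm.probabilities()
        # RF=5, window centered one right of the first R: offsets 0,1,3
        assert ALPHABET[probs[0].argmax()] == "R"
        assert ALPHABET[probs[1].argmax()] == "R"
        assert ALPHABET[probs[3].argmax()] == "S"

    def test_boundary_windows_contribute_nothing(self, rrxs_detector):
        # motif at the very end: the window's trailing column hangs over
        seq = "G" * (L - 4) + "RRAS"
        pfm = build_feature_logo(rrxs_detector, [seq], ("max", 0),
                                 min_sequences=1)
        assert pfm.n_contributions[-1] == 0
        assert pfm.n_contributions[2] > 0

    def test_top20_fallback_and_threshold_rule(self, rrxs_detector):
        strong = [_seq_with_motif(10, filler="G") for _ in range(5)]
        weak = ["G" * L for _ in range(45)]
        pfm = build_feature_logo(rrxs_detector, strong + weak, ("max", 0))
        # only 5 pass 70% threshold -> top 20 collected; center column always
        # in range so its weight counts the collected sequences
        assert pfm.n_contributions[2] == 20
        many_strong = [_seq_with_motif(10, filler="G") for _ in range(25)]
        pfm2 = build_feature_logo(rrxs_detector, many_strong + weak,
                                  ("max", 0))
        assert pfm2.n_contributions[2] == 25

    def test_dead_feature_raises(self, rrxs_detector):
        with pytest.raises(ValueError, match="Max F0"):
            build_feature_logo(rrxs_detector, ["G" * L], ("max", 0))

    def test_avg_feature_weighting(self, rrxs_detector):
        # two matches: both windows contribute, weighted by relative activation
        seq = _seq_with_motif(8, filler="G")[:24] + _seq_with_motif(8, filler="G")[:24]
        pfm = build_feature_logo(rrxs_detector, [seq], ("avg", 0),
                                 min_sequences=1)
        assert pfm.counts.sum() > 0

    def test_information_content_bounds(self, rrxs_detector):
        seqs = [_seq_with_motif(10, filler="G"), _seq_with_motif(20, filler="G")]
        pfm = build_feature_logo(rrxs_detector, seqs, ("max", 0),
                                 min_sequences=2)
        ic = pfm.information_content()
        assert np.all(ic >= 0) and np.all(ic <= 4.0)
        probs = pfm.probabilities()
        ok = pfm.n_contributions > 0
        np.testing.assert_allclose(probs[ok].sum(axis=1), 1.0)


class TestMutationMap:
    def test_wild_type_column_zero_and_oracle_equality(self, rrxs_detector):
        seq = _seq_with_motif(12, filler="G")
        lmap = mutation_map(rrxs_detector, seq, ("max", 0))
        assert lmap.deltas.shape == (L, 20)
        for i, aa in enumerate(seq):
            assert lmap.deltas[i, AA_INDEX[aa]] == 0.0
        # independent re-evaluation oracle
        from revhom.encoding import one_hot, standardize_length
        rng = np.random.default_rng(1)
        for _ in range(25):
            i = int(rng.integers(L))
            a = int(rng.integers(20))
            mutated = seq[:i] + ALPHABET[a] + seq[i + 1:]
            X = encode_batch([mutated], L)
            direct = feature_values(rrxs_detector, X, ("max", 0))[0] - 1.0
            assert lmap.deltas[i, a] == pytest.approx(direct, abs=1e-12)

    def test_mutating_required_serine_decreases_feature(self, rrxs_detector):
        seq = _seq_with_motif(12, filler="G")  # S at position 15
        lmap = mutation_map(rrxs_detector, seq, ("max", 0))
        s_row = lmap.deltas[15]
        assert np.all(s_row[np.arange(20) != AA_INDEX["S"]] == -1.0)

    def test_positions_outside_receptive_overlap_are_zero(self, rrxs_detector):
        seq = _seq_with_motif(12, filler="G")
        lmap = mutation_map(rrxs_detector, seq, ("max", 0))
        # far from the only match, no substitution can create a new one
        # with filler G except completing R/R/S patterns; position 40..47
        # region is all G: single substitutions cannot create RRxS
        assert np.all(lmap.deltas[40:] == 0)

    def test_repeat_padded_copies_mutated_together(self, rrxs_detector):
        # a short sequence is tiled; mutating one original position must
        # change all padded copies consistently (delta from re-encoding)
        seq = "GGGRRASGGGGG"  # len 12, tiled 4x into L=48
        lmap = mutation_map(rrxs_detector, seq, ("max", 0))
        assert lmap.deltas.shape == (12, 20)
        assert np.all(lmap.deltas[5, np.arange(20) != AA_INDEX["A"]] <= 0)


class TestLetterMapSummary:
    def _map(self, deltas, wt="A" * 3):
        return LetterMap(deltas=np.asarray(deltas, dtype=float),
                         wild_type=wt, feature_id=("max", 0))

    def test_all_zero_map(self):
        summary = letter_map_summary(self._map(np.zeros((3, 20))))
        assert (summary["height"] == 0).all()
        assert (summary["letters"] == "").all()

    def test_position_where_mutations_hurt_is_above_axis(self):
        deltas = np.zeros((3, 20))
        deltas[1] = -1.0
        deltas[1, 0] = 0.0  # wild type A
        summary = letter_map_summary(self._map(deltas))
        assert summary.loc[1, "sign"] == 1
        assert summary.loc[1, "height"] == pytest.approx(19.0)
        assert summary.loc[1, "letters"][0] == "A"  # best residue = wild type

    def test_mirrored_deltas_flip_sides(self):
        rng = np.random.default_rng(0)
        deltas = rng.normal(size=(5, 20))
        deltas[np.arange(5), 0] = 0.0
        up = letter_map_summary(self._map(deltas, "A" * 5))
        down = letter_map_summary(self._map(-deltas, "A" * 5))
        assert (up["sign"] == -down["sign"]).all()

    def test_favourability_sign_convention(self):
        deltas = np.zeros((2, 20))
        deltas[0, 1:] = -0.5   # mutations decrease -> favourable, positive
        deltas[1, 1:] = 0.5    # mutations increase -> negative
        lmap = self._map(deltas, "AA")
        fav = lmap.favourability
        assert fav[0] == pytest.approx(9.5)
        assert fav[1] == pytest.approx(-9.5)


class TestSmoothActivations:
    def test_constant_trace_unchanged(self):
        out = smooth_activations(np.full(50, 2.5), 15.0)
        np.testing.assert_allclose(out, 2.5)

    def test_impulse_bell_sums_to_one(self):
        x = np.zeros(301)
        x[150] = 1.0
        out = smooth_activations(x, 15.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(out[:150], out[151:][::-1], atol=1e-12)

    def test_zero_width_is_identity(self):
        x = np.arange(10, dtype=float)
        np.testing.assert_array_equal(smooth_activations(x, 0.0), x)

    def test_reflective_boundary_preserves_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        out = smooth_activations(x, 15.0)
        assert out.mean() == pytest.approx(x.mean(), abs=1e-3)


class TestRankTopFeatures:
    def _matrix(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(10, 6)),
                          index=[f"p{i}" for i in range(10)],
                          columns=[f"Max F{i}" for i in range(6)])
        return df

    def test_dataset_maximum_has_top_z(self):
        df = self._matrix()
        df.loc["p0", "Max F2"] = 100.0
        top = rank_top_features(df, "p0", k=1)
        assert top.iloc[0]["feature"] == "Max F2"

    def test_zero_variance_excluded_and_default_k(self):
        df = self._matrix()
        df["Max F5"] = 1.0
        top = rank_top_features(df, "p1")
        assert len(top) == 5
        assert "Max F5" not in set(top["feature"])

    def test_affine_invariance(self):
        df = self._matrix()
        a = rank_top_features(df, "p3", k=3)
        df["Max F1"] = df["Max F1"] * 7.0 + 11.0
        b = rank_top_features(df, "p3", k=3)
        assert list(a["feature"]) == list(b["feature"])
        np.testing.assert_allclose(a["z_score"], b["z_score"], atol=1e-12)


class TestMaxFeatureSpan:
    def _map(self, totals):
        deltas = np.zeros((len(totals), 20))
        deltas[:, 1] = totals  # put the whole mass in one column
        return LetterMap(deltas=deltas, wild_type="A" * len(totals),
                         feature_id=("max", 0))

    def test_all_zero_gives_empty(self):
        assert max_feature_span(self._map([0.0] * 20)) is None

    def test_single_position(self):
        totals = [0.0] * 20
        totals[7] = -12.0
        assert max_feature_span(self._map(totals)) == (7, 7)

    def test_interval_spans_qualifying_positions(self):
        totals = [0.0] * 20
        totals[10] = -15.0
        totals[14] = -11.0
        totals[12] = -3.0
        assert max_feature_span(self._map(totals)) == (10, 14)
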