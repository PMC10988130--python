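"""Pair labeling, feature computation, scoring, precision, and the network cut."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cofracnet as cfn
from cofracnet.errors import CalibrationError
from cofracnet.inference import (
    FP,
    TP,
    UNKNOWN,
    PairFeatures,
    ScoredInteraction,
)

NAN = np.nan


@pytest.fixture
def reference():
    return cfn.ReferenceComplexSet.from_complexes(
        {"C1": {"A", "B", "C"}, "C2": {"D", "E"}}
    )


class TestLabelPairs:
    def test_definitions(self, reference):
        labels = cfn.label_pairs(
            [("A", "B"), ("A", "D"), ("A", "Z")], reference
        )
        assert labels[("A", "B")] == TP  # within one complex
        assert labels[("A", "D")] == FP  # spans two disjoint complexes
        assert labels[("A", "Z")] == UNKNOWN  # Z not referenced

    def test_protein_in_two_complexes_pairs_are_tp(self):
        ref = cfn.ReferenceComplexSet.from_complexes(
            {"C1": {"A", "B"}, "C2": {"B", "C"}}
        )
        labels = cfn.label_pairs([("A", "B"), ("B", "C"), ("A", "C")], ref)
        assert labels[("A", "B")] == TP and labels[("B", "C")] == TP
        assert labels[("A", "C")] == FP

    def test_empty_reference_rejected(self):
        with pytest.raises(CalibrationError):
            cfn.label_pairs([("A", "B")], cfn.ReferenceComplexSet(complexes={}))


class TestComputePairFeatures:
    x = np.arange(1, 41, dtype=float)

    def gaussian_profile(self, pid, a, c, w):
        y = a * np.exp(-0.5 * ((self.x - c) / w) ** 2)
        return cfn.ElutionProfile(pid, "cond", y)

    def test_identical_profiles(self):
        p = self.gaussian_profile("A", 10, 20, 2)
        q = self.gaussian_profile("B", 10, 20, 2)
        fits = cfn.fit_gaussians(p)
        f = cfn.compute_pair_features(p, q, fits, fits)
        assert f.pearson_raw == pytest.approx(1.0)
        assert f.euclidean_distance == pytest.approx(0.0, abs=1e-12)
        assert f.co_apex_distance == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_observation_windows_yield_no_cooccurrence(self):
        a = np.full(40, NAN)
        a[:10] = 1.0
        b = np.full(40, NAN)
        b[20:] = 1.0
        f = cfn.compute_pair_features(
            cfn.ElutionProfile("A", "c", a), cfn.ElutionProfile("B", "c", b)
        )
        assert f.n_cooccurring == 0
        assert np.isnan(f.pearson_raw)

    def test_co_apex_between_separated_peaks(self):
        p = self.gaussian_profile("A", 10, 10, 2)
        q = self.gaussian_profile("B", 10, 30, 2)
        f = cfn.compute_pair_features(
            p, q, cfn.fit_gaussians(p), cfn.fit_gaussians(q)
        )
        assert f.co_apex_distance == pytest.approx(20.0, abs=0.2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cfn.compute_pair_features(
                cfn.ElutionProfile("A", "c", np.ones(10)),
                cfn.ElutionProfile("B", "c", np.ones(12)),
            )

    def test_symmetric_in_pair_order(self):
        rng = np.random.default_rng(0)
        a = cfn.ElutionProfile("A", "c", rng.lognormal(0, 1, 40))
        b = cfn.ElutionProfile("B", "c", rng.lognormal(0, 1, 40))
        f1 = cfn.compute_pair_features(a, b)
        f2 = cfn.compute_pair_features(b, a)
        assert f1.pearson_raw == pytest.approx(f2.pearson_raw)
        assert f1.euclidean_distance == pytest.approx(f2.euclidean_distance)


def _const_features(value, extra=0.0):
    return PairFeatures(
        pearson_raw=value,
        pearson_cleaned=extra,
        euclidean_distance=extra,
        co_apex_distance=extra,
        n_cooccurring=10,
    )


class TestScorePairs:
    def test_identical_class_distributions_give_prior(self):
        # TP and FP pairs with identical feature multisets: the posterior
        # degenerates to the class prior
        features, labels = {}, {}
        vals = [0.1, 0.5, 0.9]
        for i, v in enumerate(vals):
            for cls, name in ((TP, f"t{i}"), (FP, f"f{i}")):
                p = (name, name + "x")
                features[p] = _const_features(v)
                labels[p] = cls
        ranked = cfn.score_pairs(features, labels, n_folds=1, seed=0)
        for si in ranked:
            assert si.score == pytest.approx(0.5, abs=1e-9)

    def test_well_separated_single_feature_posterior(self):
        rng = np.random.default_rng(1)
        features, labels = {}, {}
        for i in range(30):
            p = (f"t{i:02d}", f"t{i:02d}x")
            features[p] = _const_features(float(rng.normal(1.0, 0.1)))
            labels[p] = TP
            q = (f"f{i:02d}", f"f{i:02d}x")
            features[q] = _const_features(float(rng.normal(-1.0, 0.1)))
            labels[q] = FP
        probe = ("zz", "zzx")
        features[probe] = _const_features(1.0)
        labels[probe] = UNKNOWN
        ranked = cfn.score_pairs(features, labels, n_folds=1, seed=0)
        score = next(si.score for si in ranked if si.pair == probe)
        assert score > 0.99

    def test_ranking_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        features, labels = {}, {}
        for i in range(40):
            p = (f"p{i:02d}", f"p{i:02d}x")
            features[p] = _const_features(float(rng.normal()))
            labels[p] = TP if i % 2 else FP
        ranked1 = cfn.score_pairs(features, labels, n_folds=4, seed=3)
        shuffled_keys = list(features)
        rng.shuffle(shuffled_keys)
        features2 = {k: features[k] for k in shuffled_keys}
        labels2 = {k: labels[k] for k in shuffled_keys}
        ranked2 = cfn.score_pairs(features2, labels2, n_folds=4, seed=3)
        assert [s.pair for s in ranked1] == [s.pair for s in ranked2]
        assert [s.score for s in ranked1] == [s.score for s in ranked2]

    def test_no_labels_raises(self):
        with pytest.raises(CalibrationError):
            cfn.score_pairs({("a", "b"): _const_features(0.5)}, {("a", "b"): UNKNOWN})

    def test_complex_folds_require_enough_complexes(self, reference):
        features = {("A", "B"): _const_features(0.9), ("A", "D"): _const_features(0.1)}
        labels = {("A", "B"): TP, ("A", "D"): FP}
        with pytest.raises(CalibrationError, match="complex"):
            cfn.score_pairs(features, labels, n_folds=10, reference=reference)


def brute_force_precision(ranked):
    """Independent oracle: double loop over equal-or-higher-score pairs."""
    out = []
    for i, si in enumerate(ranked):
        tp = fp = 0
        for sj in ranked[: i + 1]:
            if sj.label == TP:
                tp += 1
            elif sj.label == FP:
                fp += 1
        out.append(tp / (tp + fp) if tp + fp else 1.0)
    return out


class TestPrecisionCurve:
    def test_worked_example(self):
        ranked = [
            ScoredInteraction(("a", "b"), 0.9, TP),
            ScoredInteraction(("c", "d"), 0.8, FP),
            ScoredInteraction(("e", "f"), 0.7, TP),
            ScoredInteraction(("g", "h"), 0.6, TP),
        ]
        out = cfn.precision_curve(ranked)
        assert [r.running_precision for r in out] == [1.0, 0.5, 2 / 3, 0.75]

    @pytest.mark.parametrize("label, expected", [(TP, 1.0), (FP, 0.0)])
    def test_single_class_rankings(self, label, expected):
        ranked = [
            ScoredInteraction((f"p{i}", f"q{i}"), 1.0 - i * 0.01, label)
            for i in range(10)
        ]
        out = cfn.precision_curve(ranked)
        assert all(r.running_precision == expected for r in out)

    def test_unsorted_input_rejected(self):
        ranked = [
            ScoredInteraction(("a", "b"), 0.5, TP),
            ScoredInteraction(("c", "d"), 0.9, FP),
        ]
        with pytest.raises(ValueError, match="sorted"):
            cfn.precision_curve(ranked)

    @given(
        st.lists(
            st.sampled_from([TP, FP, UNKNOWN]), min_size=1, max_size=200
        ),
        st.randoms(use_true_random=False),
    )
    def test_agrees_with_brute_force(self, labels, rnd):
        scores = sorted((rnd.random() for _ in labels), reverse=True)
        ranked = [
            ScoredInteraction((f"p{i:03d}", f"q{i:03d}"), s, lab)
            for i, (s, lab) in enumerate(zip(scores, labels))
        ]
        out = cfn.precision_curve(ranked)
        assert [r.running_precision for r in out] == brute_force_precision(ranked)


class TestBuildNetwork:
    def _ranked(self, labels, scores=None):
        scores = scores or [1 - 0.01 * i for i in range(len(labels))]
        ranked = [
            ScoredInteraction((f"p{i:03d}", f"q{i:03d}"), s, lab)
            for i, (s, lab) in enumerate(zip(scores, labels))
        ]
        return cfn.precision_curve(ranked)

    def test_largest_rank_meeting_threshold_is_kept(self):
        ranked = self._ranked([TP, FP, TP, TP])
        net = cfn.build_network(ranked, 0.5, "cond")
        # precision at rank 4 is 0.75 >= 0.5, so all four ranks are cut in;
        # the FP-labeled pair is excluded from the emitted edges
        assert net.n_edges == 3
        assert ("p001", "q001") not in net.edges

    def test_threshold_one_on_all_tp(self):
        ranked = self._ranked([TP] * 5)
        assert cfn.build_network(ranked, 1.0).n_edges == 5

    def test_empty_ranking_gives_empty_network(self):
        assert cfn.build_network([], 0.5).n_edges == 0

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_range_enforced(self, bad):
        with pytest.raises(ValueError):
            cfn.build_network(self._ranked([TP]), bad)

    @given(st.lists(st.sampled_from([TP, FP, UNKNOWN]), min_size=1, max_size=100))
    def test_raising_threshold_never_enlarges_edge_set(self, labels):
        ranked = self._ranked(labels)
        prev = None
        for thr in (0.2, 0.5, 0.8, 1.0):
            edges = cfn.build_network(ranked, thr).edges
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestOracleEquivalence:
    def test_noiseless_full_coverage_recovers_planted_network(self):
        """With no noise, full reference coverage and no decoys, planted pairs
        occupy the top ranks and the 50%-precision network is mostly planted."""
        # a scenario where the planted complexes are essentially the whole
        # structure (few free proteins, whose chance co-elutions are invisible
        # to a decoy-free reference)
        cfg = cfn.SyntheticConfig(
            n_proteins=64,
            n_complexes=12,
            complex_size_range=(4, 5),
            noise_cv=0.0,
            dropout_rate=0.0,
            reference_coverage=1.0,
            n_decoy_complexes=0,
            seed=5,
        )
        _, ds, truth = cfn.generate_cofractionation(cfg)
        reference = cfn.generate_reference(truth, coverage=1.0, n_decoys=0, seed=6)
        result = cfn.infer_network(ds, reference, n_folds=5, seed=5)
        true_pairs = truth.true_cocomplex_pairs["uninhibited"]
        top = [s.pair for s in result.ranked[: len(true_pairs) // 2]]
        assert np.mean([p in true_pairs for p in top]) > 0.9
        assert cfn.network_precision(result.network, true_pairs) >= 0.5
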