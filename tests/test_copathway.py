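import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import psdnet as ps
from psdnet.copathway import GoldStandardProteinPairs

from _oracles import gold_pairs_bruteforce, lls_bruteforce, wmi_bruteforce


class TestWeightedEntropy:
    def test_constant_profile_is_zero(self):
        assert ps.weighted_entropy(np.zeros(4), np.ones(4)) == 0.0

    def test_half_mass_gives_log2(self):
        assert ps.weighted_entropy(np.array([1, 1, 0, 0]), np.ones(4)) == pytest.approx(
            math.log(2)
        )

    def test_skewed_weights_hand_value(self):
        # present domain carries weight 1 of total 4 -> p = (0.25, 0.75)
        h = ps.weighted_entropy(np.array([1, 0]), np.array([1.0, 3.0]))
        assert h == pytest.approx(-(0.25 * math.log(0.25) + 0.75 * math.log(0.75)))


class TestWeightedJointEntropy:
    def test_duplicate_profile_adds_nothing(self):
        x = np.array([1, 0, 1, 0])
        w = np.array([1.0, 2.0, 3.0, 4.0])
        assert ps.weighted_joint_entropy(x, x, w) == pytest.approx(
            ps.weighted_entropy(x, w)
        )

    def test_constant_coordinate_collapses(self):
        y = np.array([1, 1, 0, 0])
        w = np.ones(4)
        assert ps.weighted_joint_entropy(np.zeros(4), y, w) == pytest.approx(
            ps.weighted_entropy(y, w)
        )

    def test_four_even_cells(self):
        x = np.array([1, 1, 0, 0])
        y = np.array([1, 0, 1, 0])
        assert ps.weighted_joint_entropy(x, y, np.ones(4)) == pytest.approx(
            2 * math.log(2)
        )


class TestWeightedMutualInformation:
    def test_identical_profiles_give_entropy(self):
        x = np.array([1, 0, 1])
        w = np.array([2.0, 1.0, 5.0])
        assert ps.weighted_mutual_information(x, x, w) == pytest.approx(
            ps.weighted_entropy(x, w)
        )

    def test_constant_profile_gives_zero(self):
        y = np.array([1, 0, 1])
        assert ps.weighted_mutual_information(np.zeros(3), y, np.ones(3)) == 0.0

    def test_weighted_independent_profiles(self):
        x = np.array([1, 1, 0, 0])
        y = np.array([1, 0, 1, 0])
        assert ps.weighted_mutual_information(x, y, np.ones(4)) == pytest.approx(
            0.0, abs=1e-12
        )

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.tuples(st.booleans(), st.booleans(),
                           st.floats(0.1, 10.0)), min_size=2, max_size=6)
    )
    def test_matches_bruteforce_and_is_symmetric(self, triples):
        """WMI equals the direct sum p*log(p/(px*py)) over the four joint
        states, and is symmetric and non-negative."""
        x = np.array([t[0] for t in triples], dtype=int)
        y = np.array([t[1] for t in triples], dtype=int)
        w = np.array([t[2] for t in triples])
        i_xy = ps.weighted_mutual_information(x, y, w)
        i_yx = ps.weighted_mutual_information(y, x, w)
        assert i_xy == pytest.approx(i_yx, abs=1e-12)
        assert i_xy >= -1e-12
        assert i_xy == pytest.approx(wmi_bruteforce(x, y, w), abs=1e-9)


class TestScoreAllPairs:
    def test_pair_count_and_order(self, toy_matrix):
        w = ps.compute_domain_weights(toy_matrix)
        pairs = ps.score_all_pairs(toy_matrix, w)
        assert len(pairs) == 3
        assert (pairs["wmi"].diff().dropna() <= 1e-12).all()
        assert (pairs["protein_a"] < pairs["protein_b"]).all()

    def test_identical_profiles_rank_first(self):
        m = ps.build_profile_matrix(
            [("A", "d1"), ("A", "d2"), ("B", "d1"), ("B", "d2"),
             ("C", "d3"), ("D", "d1"), ("D", "d3")]
        )
        w = ps.compute_domain_weights(m)
        pairs = ps.score_all_pairs(m, w)
        assert {pairs.iloc[0]["protein_a"], pairs.iloc[0]["protein_b"]} == {"A", "B"}
        # their WMI is the shared entropy, the maximum for those marginals
        wa = w.to_numpy()
        assert pairs.iloc[0]["wmi"] == pytest.approx(
            ps.weighted_entropy(m.loc["A"].to_numpy(), wa)
        )

    def test_deterministic(self, toy_matrix):
        w = ps.compute_domain_weights(toy_matrix)
        p1 = ps.score_all_pairs(toy_matrix, w)
        p2 = ps.score_all_pairs(toy_matrix, w)
        pd.testing.assert_frame_equal(p1, p2)

    def test_single_protein_errors(self):
        m = ps.build_profile_matrix([("P1", "d1")])
        w = ps.compute_domain_weights(m)
        with pytest.raises(ValueError, match="two proteins"):
            ps.score_all_pairs(m, w)


class TestGoldStandardPairs:
    def test_small_enumeration(self):
        gold = ps.build_gold_standard_pairs(
            {"f1": {"A", "B"}, "f2": {"B", "C"}}, ["A", "B", "C"]
        )
        assert gold.positives == {("A", "B"), ("B", "C")}
        assert gold.negatives == {("A", "C")}

    def test_single_pathway_has_no_negatives(self):
        gold = ps.build_gold_standard_pairs({"f1": {"A", "B", "C"}}, ["A", "B", "C"])
        assert gold.negatives == frozenset()

    def test_disjoint_singletons(self):
        gold = ps.build_gold_standard_pairs({"f1": {"A"}, "f2": {"B"}}, ["A", "B"])
        assert gold.positives == frozenset()
        assert gold.negatives == {("A", "B")}

    def test_unannotated_proteins_excluded(self):
        gold = ps.build_gold_standard_pairs({"f1": {"A", "B"}}, ["A", "B", "Z"])
        assert all("Z" not in p for p in gold.positives | gold.negatives)

    def test_matches_bruteforce(self, default_universe, default_result):
        gold = ps.build_gold_standard_pairs(
            default_universe.pathways, default_result.matrix.index
        )
        pos, neg = gold_pairs_bruteforce(
            default_universe.pathways, default_result.matrix.index
        )
        assert gold.positives == pos and gold.negatives == neg


def _pairs_frame(keys):
    return pd.DataFrame(
        {
            "protein_a": [k[0] for k in keys],
            "protein_b": [k[1] for k in keys],
            "wmi": np.linspace(1.0, 0.0, len(keys)),
        }
    )


class TestCalibrateLls:
    def test_hand_lls_with_unit_prior(self):
        """A bin holding 3 positives and 1 negative against prior odds 1
        scores ln 3 (its mirror bin scores -ln 3)."""
        keys = [(f"P{i}", f"Q{i}") for i in range(8)]
        pos = frozenset(keys[:3] + keys[4:5])
        neg = frozenset(keys[3:4] + keys[5:8])
        gold = GoldStandardProteinPairs(pos, neg)
        net = ps.calibrate_lls(_pairs_frame(keys), gold, bin_size=4)
        lls = net.edges["lls"].to_numpy()
        assert lls[:4] == pytest.approx(math.log(3))
        assert lls[4:] == pytest.approx(-math.log(3))

    def test_prior_composition_bin_scores_zero(self):
        keys = [(f"P{i}", f"Q{i}") for i in range(8)]
        pos = frozenset(keys[0:1] + keys[4:5])
        neg = frozenset(keys[1:4] + keys[5:8])
        gold = GoldStandardProteinPairs(pos, neg)
        net = ps.calibrate_lls(_pairs_frame(keys), gold, bin_size=4)
        assert net.edges["lls"].to_numpy() == pytest.approx(0.0)

    def test_one_sided_bin_merges_forward(self):
        """A bin with positives only absorbs the next bin before scoring."""
        keys = [(f"P{i}", f"Q{i}") for i in range(8)]
        pos = frozenset(keys[:4])
        neg = frozenset(keys[4:])
        gold = GoldStandardProteinPairs(pos, neg)
        net = ps.calibrate_lls(_pairs_frame(keys), gold, bin_size=4)
        # single merged bin covering everything -> posterior = prior
        assert net.edges["lls"].to_numpy() == pytest.approx(0.0)

    def test_degenerate_prior_errors(self):
        keys = [(f"P{i}", f"Q{i}") for i in range(4)]
        gold = GoldStandardProteinPairs(frozenset(keys), frozenset())
        with pytest.raises(ValueError, match="degenerate prior"):
            ps.calibrate_lls(_pairs_frame(keys), gold, bin_size=2)

    def test_matches_bruteforce_on_tiny_universe(self, tiny_universe):
        m = ps.build_profile_matrix(tiny_universe.annotations)
        w = ps.compute_domain_weights(m)
        pairs = ps.score_all_pairs(m, w)
        gold = ps.build_gold_standard_pairs(tiny_universe.pathways, m.index)
        net = ps.calibrate_lls(pairs, gold, bin_size=7)
        keys = list(zip(pairs["protein_a"], pairs["protein_b"]))
        expected = lls_bruteforce(keys, gold.positives, gold.negatives, 7)
        for (a, b, lls) in net.edges.itertuples(index=False):
            assert lls == pytest.approx(expected[(a, b)], abs=1e-9)

    def test_permuted_gold_labels_center_lls_at_zero(self, default_universe):
        """With gold labels shuffled independently of WMI rank, the mean
        per-bin LLS is statistically indistinguishable from zero."""
        rng = np.random.default_rng(11)
        u = default_universe
        m = ps.build_profile_matrix(u.annotations)
        w = ps.compute_domain_weights(m)
        pairs = ps.score_all_pairs(m, w)
        gold = ps.build_gold_standard_pairs(u.pathways, m.index)
        labels = [1] * len(gold.positives) + [0] * len(gold.negatives)
        members = sorted(gold.positives | gold.negatives)
        means = []
        for _ in range(20):
            perm = rng.permutation(labels)
            pos = frozenset(k for k, l in zip(members, perm) if l)
            neg = frozenset(k for k, l in zip(members, perm) if not l)
            net = ps.calibrate_lls(pairs, GoldStandardProteinPairs(pos, neg), 1000)
            means.append(float(net.edges["lls"].mean()))
        means = np.array(means)
        se = means.std(ddof=1) / math.sqrt(len(means))
        # ln(K/(n-K)) of a binomial count carries a known O(1/n) Jensen
        # bias of (2p-1)/(2 n p (1-p)); center the null on it
        p = len(gold.positives) / len(members)
        n_per_bin = len(members) / np.ceil(len(pairs) / 1000)
        bias = (2 * p - 1) / (2 * n_per_bin * p * (1 - p))
        assert abs(means.mean() - bias) < 3 * se + 1e-4


class TestFilterPositiveLls:
    def test_strict_positivity(self):
        edges = pd.DataFrame(
            {"protein_a": ["A", "A", "B"], "protein_b": ["B", "C", "C"],
             "lls": [1.2, 0.0, -0.5]}
        )
        net = ps.filter_positive_lls(ps.CoPathwayNetwork(edges=edges))
        assert len(net.edges) == 1
        assert set(net.proteins) == {"A", "B"}

    def test_all_negative_warns_and_empties(self):
        edges = pd.DataFrame(
            {"protein_a": ["A"], "protein_b": ["B"], "lls": [-1.0]}
        )
        with pytest.warns(UserWarning, match="no edges"):
            net = ps.filter_positive_lls(ps.CoPathwayNetwork(edges=edges))
        assert len(net.edges) == 0

    def test_retained_set_is_exactly_positive(self, default_universe):
        u = default_universe
        m = ps.build_profile_matrix(u.annotations)
        w = ps.compute_domain_weights(m)
        pairs = ps.score_all_pairs(m, w)
        gold = ps.build_gold_standard_pairs(u.pathways, m.index)
        net = ps.calibrate_lls(pairs, gold, 1000)
        kept = ps.filter_positive_lls(net)
        assert len(kept.edges) == int((net.edges["lls"] > 0).sum())
        assert (kept.edges["lls"] > 0).all()


class TestRankingRecapitulatesCoPathway:
    def test_top_pairs_beat_base_rate(self, default_universe, default_result):
        """Top-ranked WMI pairs are enriched for co-pathway gold positives
        well above the base rate (the network is predictive of shared
        pathway membership)."""
        gold = ps.build_gold_standard_pairs(
            default_universe.pathways, default_result.matrix.index
        )
        pairs = default_result.pairs
        keys = list(zip(pairs["protein_a"], pairs["protein_b"]))
        is_pos = np.array([k in gold.positives for k in keys])
        assert is_pos[:1000].mean() > 2 * is_pos.mean()
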