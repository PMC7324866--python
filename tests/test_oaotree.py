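import numpy as np
import pytest

from eegmpm import (
    ConfigurationError,
    InsufficientDataError,
    PairwiseBank,
    build_tree,
    classify,
    train_pairwise,
)
from eegmpm.mpm import MPMModel, degenerate_model
from eegmpm.oaotree import TreeLeaf, TreeNode, iter_leaves, tree_from_dict, tree_to_dict


def gaussian_classes(rng, means, n=40, sd=0.15):
    """Well-separated Gaussian blobs in the 'mapped' space."""
    Z, y = [], []
    for label, mu in enumerate(means):
        Z.append(rng.normal(mu, sd, size=(n, len(mu))))
        y.extend([label] * n)
    return np.vstack(Z), np.array(y)


def synthetic_bank(alphas: dict[tuple[int, int], float]) -> PairwiseBank:
    """Bank with prescribed alpha per pair (hyperplanes irrelevant)."""
    classes = tuple(sorted({c for pair in alphas for c in pair}))
    models = {}
    for (i, j), a in alphas.items():
        obj = np.sqrt(1.0 / a - 1.0)
        models[(i, j)] = MPMModel(
            w=np.ones(2), b=0.0, alpha=a, gamma=1.0 / obj if obj else np.inf,
            class_pos=i, class_neg=j,
        )
    return PairwiseBank(models, classes)


class TestTrainPairwise:
    def test_pair_counts(self, rng):
        for m, expected in ((2, 1), (3, 3), (5, 10)):
            means = [np.eye(m)[k] * 3 for k in range(m)]
            Z, y = gaussian_classes(rng, means, n=10)
            bank = train_pairwise(Z, y)
            assert len(bank.models) == expected

    def test_order_invariance(self, rng):
        Z, y = gaussian_classes(rng, [[0, 0], [3, 0], [0, 3]], n=15)
        perm = rng.permutation(len(y))
        a = train_pairwise(Z, y)
        b = train_pairwise(Z[perm], y[perm])
        for pair in a.models:
            assert np.allclose(a.models[pair].w, b.models[pair].w, atol=1e-10)
            assert a.models[pair].alpha == pytest.approx(b.models[pair].alpha)

    def test_small_class_errors_with_name(self, rng):
        Z = np.vstack([np.zeros((5, 2)), np.ones((1, 2))])
        y = np.array([0] * 5 + [3])
        with pytest.raises(InsufficientDataError, match="class 3"):
            train_pairwise(Z, y)

    def test_coincident_means_become_degenerate_alpha_zero(self, rng):
        Z = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(0, 1, (20, 2)),
                       rng.normal(5, 0.1, (20, 2))])
        Z[20:40] = Z[:20]  # classes 0 and 1 identical
        y = np.array([0] * 20 + [1] * 20 + [2] * 20)
        bank = train_pairwise(Z, y)
        assert bank.models[(0, 1)].degenerate
        assert bank.models[(0, 1)].alpha == 0.0
        assert not bank.models[(0, 2)].degenerate


class TestBuildTree:
    def test_two_classes_single_node(self):
        bank = synthetic_bank({(0, 1): 0.8})
        tree = build_tree(bank)
        assert tree.root.pair == (0, 1)
        assert all(isinstance(c, TreeLeaf) for c in tree.root.children.values())

    def test_three_class_hand_trace(self):
        # root = max-alpha pair (1,2); on "not 1" the winner is 2 and the
        # best remaining pair involving 2 is (2,3); on "not 2" it is (1,3)
        bank = synthetic_bank({(1, 2): 0.9, (1, 3): 0.5, (2, 3): 0.7})
        tree = build_tree(bank, "winner_restricted")
        assert tree.root.pair == (1, 2)
        assert tree.root.children[1].pair == (2, 3)
        assert tree.root.children[2].pair == (1, 3)

    def test_root_is_global_max_alpha(self, rng):
        alphas = {}
        classes = range(5)
        vals = iter(rng.permutation(10) / 10.0 + 0.01)
        from itertools import combinations

        for pair in combinations(classes, 2):
            alphas[pair] = float(next(vals)) * 0.9
        bank = synthetic_bank(alphas)
        tree = build_tree(bank)
        best = max(alphas, key=lambda p: (alphas[p], [-c for c in p]))
        assert alphas[tree.root.pair] == max(alphas.values())

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_structure_invariants(self, rng, m):
        means = [np.eye(m)[k] * 4 for k in range(m)]
        Z, y = gaussian_classes(rng, means, n=12)
        tree = build_tree(train_pairwise(Z, y))
        assert tree.n_leaves() == m
        assert set(tree.path_lengths()) == {m - 1}
        leaf_labels = sorted(leaf.label for leaf in iter_leaves(tree.root))
        # every class appears as a leaf at least once
        assert set(leaf_labels) == set(range(m))

    def test_candidate_sets_shrink_by_one(self, rng):
        Z, y = gaussian_classes(rng, [np.eye(4)[k] * 4 for k in range(4)], n=10)
        tree = build_tree(train_pairwise(Z, y))

        def walk(node):
            if isinstance(node, TreeLeaf):
                return
            assert set(node.pair) <= set(node.candidates)
            for excluded, child in node.children.items():
                if isinstance(child, TreeNode):
                    assert set(child.candidates) == set(node.candidates) - {excluded}
                walk(child)

        walk(tree.root)

    def test_global_max_rule_differs_when_it_should(self):
        # winner-restricted must pick a pair involving the winner even when a
        # higher-alpha pair exists elsewhere in the candidate set
        bank = synthetic_bank({(1, 2): 0.9, (3, 4): 0.85, (1, 3): 0.3,
                               (1, 4): 0.2, (2, 3): 0.4, (2, 4): 0.1})
        wr = build_tree(bank, "winner_restricted")
        gm = build_tree(bank, "global_max")
        assert wr.root.pair == gm.root.pair == (1, 2)
        assert wr.root.children[1].pair == (2, 3)  # must involve winner 2
        assert gm.root.children[1].pair == (3, 4)  # unrestricted max

    def test_bad_child_rule(self):
        with pytest.raises(ConfigurationError):
            build_tree(synthetic_bank({(0, 1): 0.5}), "nonsense")


class TestClassify:
    def test_two_class_reduces_to_single_decision(self, rng):
        Z, y = gaussian_classes(rng, [[0.0, 0.0], [4.0, 0.0]], n=20)
        tree = build_tree(train_pairwise(Z, y))
        label, n_dec = classify(tree, np.array([4.0, 0.1]), return_n_decisions=True)
        assert label == 1 and n_dec == 1

    def test_class_means_recovered_three_class(self, rng):
        means = [[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]]
        Z, y = gaussian_classes(rng, means, n=30, sd=0.5)
        tree = build_tree(train_pairwise(Z, y))
        for label, mu in enumerate(means):
            assert classify(tree, np.array(mu)) == label

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_exactly_m_minus_1_decisions(self, rng, m):
        means = [np.eye(m)[k] * 4 for k in range(m)]
        Z, y = gaussian_classes(rng, means, n=10)
        tree = build_tree(train_pairwise(Z, y))
        for z in rng.standard_normal((20, m)):
            label, n_dec = classify(tree, z, return_n_decisions=True)
            assert n_dec == m - 1
            assert label in range(m)  # no rejection possible

    def test_tree_never_beats_voting_by_much_less(self, rng):
        # sanity: on overlapping classes the exclusion tree stays within 0.05
        # of majority-vote one-against-one accuracy
        means = [[0.0, 0.0], [1.5, 0.0], [0.0, 1.5]]
        Z, y = gaussian_classes(rng, means, n=60, sd=0.8)
        bank = train_pairwise(Z, y)
        tree = build_tree(bank)
        from eegmpm.mpm import mpm_decide

        test_Z, test_y = gaussian_classes(rng, means, n=60, sd=0.8)
        tree_pred = np.array([classify(tree, z) for z in test_Z])

        def vote(z):
            counts = {}
            for model in bank.models.values():
                w = mpm_decide(model, z)
                counts[w] = counts.get(w, 0) + 1
            top = max(counts.values())
            winners = sorted(c for c, n in counts.items() if n == top)
            return winners[0]  # ties resolved lexicographically

        vote_pred = np.array([vote(z) for z in test_Z])
        acc_tree = np.mean(tree_pred == test_y)
        acc_vote = np.mean(vote_pred == test_y)
        assert acc_tree >= acc_vote - 0.05


def test_tree_serialization_roundtrip(rng):
    Z, y = gaussian_classes(rng, [np.eye(3)[k] * 4 for k in range(3)], n=15)
    bank = train_pairwise(Z, y)
    tree = build_tree(bank)
    back = tree_from_dict(tree_to_dict(tree), bank)
    for z in rng.standard_normal((30, 3)):
        assert classify(back, z) == classify(tree, z)


def test_incomplete_bank_rejected():
    with pytest.raises(ConfigurationError):
        PairwiseBank(
            {(0, 1): degenerate_model(np.zeros(2), np.zeros(2), 0, 1)},
            (0, 1, 2),
        )
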