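import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from bmpscreen.equivalence import (
    EquivalenceClustering,
    build_feature_vectors,
    cluster_equivalence,
    correlate_profiles,
    global_equivalence,
    sequence_distance_matrix,
)


def interactions_frame(ic_map, context="ctx"):
    rows = [
        dict(context_id=context, ligand_a=a, ligand_b=b, summary_ic=v)
        for (a, b), v in ic_map.items()
    ]
    return pd.DataFrame(rows)


def full_ic_map(ligands, default=0.0, **overrides):
    m = {}
    for i, a in enumerate(ligands):
        for b in ligands[i:]:
            m[(a, b)] = default
    m.update({tuple(sorted(k)): v for k, v in overrides.items()})
    return m


class TestFeatureVectors:
    def test_vector_length_single_context(self):
        ligands = [f"L{i}" for i in range(10)]
        inter = interactions_frame(full_ic_map(ligands))
        rls = {l: 1.0 for l in ligands}
        F = build_feature_vectors(rls, inter, contexts=["ctx"])
        assert F.shape == (10, 11)  # 9 pair ICs + self IC + doubled RLS

    def test_vector_length_seven_contexts(self):
        ligands = [f"L{i}" for i in range(10)]
        frames, rls = [], {}
        for c in range(7):
            frames.append(interactions_frame(full_ic_map(ligands), context=f"c{c}"))
            rls.update({(f"c{c}", l): 1.0 for l in ligands})
        F = build_feature_vectors(pd.Series(rls), pd.concat(frames),
                                  contexts=[f"c{c}" for c in range(7)])
        assert F.shape == (10, 77)

    def test_rls_doubling_calibrates_distance(self):
        # identical ICs, RLS differing by 0.5 -> Euclidean distance exactly 1
        inter = interactions_frame(full_ic_map(["A", "B"]))
        F = build_feature_vectors({"A": 1.0, "B": 0.5}, inter, contexts=["ctx"])
        d = np.linalg.norm(F.loc["A"] - F.loc["B"])
        assert d == pytest.approx(1.0, abs=1e-12)

    def test_missing_pair_is_error(self):
        inter = interactions_frame({("A", "A"): 0.0, ("B", "B"): 0.0})
        with pytest.raises(ValueError, match="missing interaction"):
            build_feature_vectors({"A": 1.0, "B": 1.0}, inter, contexts=["ctx"])

    def test_missing_rls_is_error(self):
        inter = interactions_frame(full_ic_map(["A", "B"]))
        with pytest.raises(ValueError, match="missing RLS"):
            build_feature_vectors({"A": 1.0}, inter, contexts=["ctx"])


def constant_categories(ligands, value="saturated_additive"):
    return {(a, b): value for a in ligands for b in ligands}


class TestClusterEquivalence:
    def test_identical_vectors_single_group(self):
        F = pd.DataFrame(np.zeros((4, 5)), index=list("ABCD"))
        emap = cluster_equivalence(F, categories=constant_categories("ABCD"))
        assert emap.groups == [["A", "B", "C", "D"]]

    def test_distance_above_threshold_separates(self):
        F = pd.DataFrame([[0.0], [1.2]], index=["A", "B"])
        emap = cluster_equivalence(F, categories=constant_categories("AB"))
        assert len(emap.groups) == 2

    def test_distance_exactly_one_separates(self):
        # merges happen strictly below the cut
        F = pd.DataFrame([[0.0], [1.0]], index=["A", "B"])
        emap = cluster_equivalence(F, categories=constant_categories("AB"))
        assert len(emap.groups) == 2

    def test_distance_just_below_one_merges(self):
        F = pd.DataFrame([[0.0], [0.999]], index=["A", "B"])
        emap = cluster_equivalence(F, categories=constant_categories("AB"))
        assert len(emap.groups) == 1

    def test_planted_partition_recovered(self, rng):
        centers = {"g1": 0.0, "g2": 3.0, "g3": 6.0}
        names, rows = [], []
        for g, c in centers.items():
            for i in range(3):
                names.append(f"{g}_{i}")
                rows.append(c + rng.normal(0, 0.05, 6))
        F = pd.DataFrame(rows, index=names)
        emap = cluster_equivalence(F, categories=constant_categories(names))
        groups = {frozenset(g) for g in emap.groups}
        expected = {frozenset(f"{g}_{i}" for i in range(3)) for g in centers}
        assert groups == expected

    def test_monochromaticity_splits_mixed_group(self):
        # A and B are metrically close but disagree on their interaction
        # category with outside ligand C -> must not share a group
        F = pd.DataFrame([[0.0], [0.1], [5.0]], index=["A", "B", "C"])
        cats = constant_categories("ABC")
        cats[("A", "C")] = "suppressive"
        cats[("C", "A")] = "suppressive"
        emap = cluster_equivalence(F, categories=cats)
        labels = emap.labels
        assert labels["A"] != labels["B"]

    def test_single_ligand_trivial_group(self):
        F = pd.DataFrame([[1.0, 2.0]], index=["only"])
        emap = cluster_equivalence(F, categories={})
        assert emap.groups == [["only"]]

    def test_invariant_to_input_order(self, rng):
        F = pd.DataFrame(rng.normal(0, 2, (6, 4)), index=list("ABCDEF"))
        cats = constant_categories("ABCDEF")
        g1 = cluster_equivalence(F, categories=cats).groups
        perm = list("DFABEC")
        g2 = cluster_equivalence(F.loc[perm], categories=cats).groups
        assert {frozenset(g) for g in g1} == {frozenset(g) for g in g2}

    def test_groups_partition_ligands(self, rng):
        F = pd.DataFrame(rng.normal(0, 1.5, (8, 3)), index=[f"L{i}" for i in range(8)])
        emap = cluster_equivalence(F, categories=constant_categories(F.index))
        flat = [l for g in emap.groups for l in g]
        assert sorted(flat) == sorted(F.index)


class TestGlobalEquivalence:
    def test_identical_vectors_merge(self):
        F = pd.DataFrame(np.ones((3, 14)), index=list("ABC"))
        assert len(global_equivalence(F).groups) == 1

    def test_per_context_distance_three_over_seven_contexts(self):
        # distance 3 in each of 7 contexts -> global 3*sqrt(7) = 7.94 > 7
        blocks = [np.array([[0.0], [3.0]]) for _ in range(7)]
        F = pd.DataFrame(np.hstack(blocks), index=["A", "B"])
        d = np.linalg.norm(F.loc["A"] - F.loc["B"])
        assert d == pytest.approx(3 * np.sqrt(7))
        assert len(global_equivalence(F, threshold=7.0).groups) == 2

    def test_planted_five_groups_across_contexts(self, rng):
        centers = np.arange(5) * 4.0
        names, rows = [], []
        for gi, c in enumerate(centers):
            for i in range(2):
                names.append(f"g{gi}_{i}")
                rows.append(np.full(21, c) + rng.normal(0, 0.1, 21))  # 7 ctx x 3 feats
        F = pd.DataFrame(rows, index=names)
        emap = global_equivalence(F, threshold=7.0)
        assert len(emap.groups) == 5


class TestSequenceDistance:
    def test_identical_sequences_zero_distance(self):
        dm, _ = sequence_distance_matrix([("a", "MKT"), ("b", "MKT")])
        assert dm.loc["a", "b"] == 0.0

    def test_hand_computed_blosum50_distance(self):
        # AAA vs RRR, no gaps: s_ij = 3*(-2) = -6, s_ii = 15, s_jj = 21
        dm, _ = sequence_distance_matrix([("x", "AAA"), ("y", "RRR")])
        assert dm.loc["x", "y"] == pytest.approx(1 - (-6) / 15)

    def test_symmetry_and_zero_diagonal(self, rng):
        alpha = "ACDEFGHIKLMNPQRSTVWY"
        seqs = [("s%d" % i, "".join(rng.choice(list(alpha), 12))) for i in range(4)]
        dm, Z = sequence_distance_matrix(seqs)
        assert np.allclose(dm.to_numpy(), dm.to_numpy().T)
        assert np.allclose(np.diag(dm.to_numpy()), 0.0)
        assert Z.shape == (3, 4)  # average-linkage tree over 4 leaves

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            sequence_distance_matrix([("a", "MK1"), ("b", "MKT")])

    def test_unaligned_sequences_are_aligned_first(self):
        # unequal lengths trigger the progressive aligner; related sequences
        # should come out closer than unrelated ones
        seqs = [
            ("a", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
            ("b", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEV"),
            ("c", "GGGGWWWWPPPPGGGGWWWWPPPPGGGG"),
        ]
        dm, _ = sequence_distance_matrix(seqs)
        assert dm.loc["a", "b"] < dm.loc["a", "c"]


class TestCorrelateProfiles:
    def make(self, rng, n=6):
        names = [f"L{i}" for i in range(n)]
        d1 = squareform(rng.uniform(0.1, 2.0, n * (n - 1) // 2))
        return pd.DataFrame(d1, index=names, columns=names), names

    def test_equal_matrices_perfect_correlation(self, rng):
        dm, _ = self.make(rng)
        assert correlate_profiles(dm, dm)["r"] == pytest.approx(1.0)

    def test_negated_matrices_anticorrelated(self, rng):
        dm, names = self.make(rng)
        neg = pd.DataFrame(-dm.to_numpy() + 5.0, index=names, columns=names)
        np.fill_diagonal(neg.values, 0.0)
        assert correlate_profiles(dm, neg)["r"] == pytest.approx(-1.0)

    def test_matches_brute_force_pearson(self, rng):
        dm1, names = self.make(rng)
        dm2, _ = self.make(rng)
        r = correlate_profiles(dm1, dm2)["r"]
        x = squareform(dm1.to_numpy(), checks=False)
        y = squareform(dm2.to_numpy(), checks=False)
        assert r == pytest.approx(pearsonr(x, y)[0])

    def test_constant_input_flagged(self):
        names = ["a", "b", "c"]
        const = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=names, columns=names)
        out = correlate_profiles(const, const)
        assert out["constant_input"]

    def test_subset_sweep_reports_maximum(self, rng):
        dm, names = self.make(rng, n=5)
        feats = {f"c{i}": pd.DataFrame(rng.normal(0, 1, (5, 4)), index=names)
                 for i in range(3)}
        out = correlate_profiles(dm, dm, n_subsets=8, feature_by_context=feats, seed=0)
        assert out["max_subset_r"] >= max(r for _, r in out["subsets"]) - 1e-12
        assert len(out["subsets"]) <= 8
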