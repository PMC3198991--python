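import io

import numpy as np
import pytest
from skbio import TreeNode

from xenoscan.phylo import (
    PhyloError,
    bootstrap_supports,
    distance_matrix,
    is_monophyletic,
    neighbor_joining,
)
from xenoscan.seqio import AlignedSet
from xenoscan.simulate import simulate_tree


def _aln(rows):
    return AlignedSet(records=tuple(rows))


def _tree(newick):
    t = TreeNode.read(io.StringIO(newick))
    t.assign_supports()
    return t


def _additive_matrix(tree):
    """Path-length matrix of a tree (the oracle for NJ exactness)."""
    from xenoscan.phylo import DistanceMatrix

    dm = tree.tip_tip_distances()
    return DistanceMatrix(labels=list(dm.ids), data=dm.data.copy())


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        dm = distance_matrix(_aln([("a", "MKTA"), ("b", "MKTA"), ("c", "MKTA")]))
        assert np.allclose(dm.data, 0.0)

    def test_p_and_poisson_closed_form(self):
        aln = _aln([("a", "AAAA"), ("b", "AAVV"), ("c", "AAAA")])
        p = distance_matrix(aln, "p_distance")
        assert p[("a", "b")] == pytest.approx(0.5)
        c = distance_matrix(aln, "poisson_corrected")
        assert c[("a", "b")] == pytest.approx(-np.log(0.5))

    def test_gapped_columns_excluded(self):
        aln = _aln([("a", "MK-A"), ("b", "MKVA"), ("c", "MKVA")])
        assert distance_matrix(aln)[("a", "b")] == 0.0

    def test_saturation_capped_and_flagged(self):
        aln = _aln([("a", "A" * 20), ("b", "V" * 20), ("c", "A" * 20)])
        with pytest.warns(UserWarning, match="saturation"):
            dm = distance_matrix(aln, "poisson_corrected")
        assert dm[("a", "b")] == pytest.approx(-np.log(0.05))
        assert frozenset(("a", "b")) in dm.saturated

    def test_permutation_equivariant(self):
        rows = [("a", "MKTAYIAK"), ("b", "MKTVYIAK"), ("c", "MQTAYIPK")]
        d1 = distance_matrix(_aln(rows))
        d2 = distance_matrix(_aln(rows[::-1]))
        for x in "abc":
            for y in "abc":
                if x != y:
                    assert d1[(x, y)] == d2[(x, y)]

    def test_simulated_divergence_recovered(self, reference):
        from xenoscan.fingerprint import RhodopsinClass
        from xenoscan.simulate import FamilySpec, evolve_family

        spec = FamilySpec(
            n_taxa={RhodopsinClass.PROTON_PUMP: 10},
            divergence=0.2,
            class_separation=0.0,
            indel_rate=0.0,
            seed=17,
        )
        records, truth = evolve_family(spec)
        dm = distance_matrix(truth.alignment, "poisson_corrected")
        true_dm = truth.tree.tip_tip_distances()
        n_sites = truth.alignment.n_columns
        checked = 0
        for i, a in enumerate(true_dm.ids):
            for b in list(true_dm.ids)[i + 1 :]:
                t = true_dm[a, b]
                # Poisson correction for a 20-state uniform-replacement chain
                # underestimates slightly; allow 3 SE of the p-estimate
                p_exp = 0.95 * (1 - np.exp(-t / 0.95))
                se = np.sqrt(p_exp * (1 - p_exp) / n_sites)
                d_lo = -np.log(1 - max(p_exp - 3 * se, 0.01))
                d_hi = -np.log(1 - min(p_exp + 3 * se, 0.94))
                assert d_lo <= dm[(a, b)] <= d_hi
                checked += 1
        assert checked > 10


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        from xenoscan.phylo import DistanceMatrix

        dm = DistanceMatrix(
            labels=["a", "b", "c"],
            data=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        # three-point formulas: la=(3+4-5)/2=1, lb=(3+5-4)/2=2, lc=(4+5-3)/2=3
        assert lengths == {"a": pytest.approx(1.0), "b": pytest.approx(2.0), "c": pytest.approx(3.0)}

    def test_four_taxon_additive_exact(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> hand-computed path lengths
        from xenoscan.phylo import DistanceMatrix

        d = {
            ("a", "b"): 3,
            ("a", "c"): 5,
            ("a", "d"): 6,
            ("b", "c"): 6,
            ("b", "d"): 7,
            ("c", "d"): 7,
        }
        labels = ["a", "b", "c", "d"]
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            mat[i, j] = mat[j, i] = v
        tree = neighbor_joining(DistanceMatrix(labels=labels, data=mat))
        expected = _tree("((a:1,b:2):1,(c:3,d:4):0);")
        assert tree.compare_rfd(expected) == 0.0
        got = tree.tip_tip_distances()
        for (x, y), v in d.items():
            assert got[x, y] == pytest.approx(v, abs=1e-9)

    def test_random_additive_matrices_recovered(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 9))
            true = simulate_tree(n, seed=seed + 1000)
            dm = _additive_matrix(true)
            rec = neighbor_joining(dm)
            assert rec.compare_rfd(true) == 0.0
            got = rec.tip_tip_distances()
            want = true.tip_tip_distances()
            for a in dm.labels:
                for b in dm.labels:
                    assert got[a, b] == pytest.approx(want[a, b], abs=1e-9)

    def test_agrees_with_skbio_on_random_matrices(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        from xenoscan.phylo import DistanceMatrix

        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            labels = [f"t{i}" for i in range(n)]
            tree = simulate_tree(n, seed=int(rng.integers(2**31)))
            dm = _additive_matrix(tree)
            noise = rng.uniform(0, 0.01, size=(len(dm.labels),) * 2)
            noisy = dm.data + noise + noise.T
            noisy = (noisy + noisy.T) / 2  # exact float symmetry
            np.fill_diagonal(noisy, 0.0)
            ours = neighbor_joining(DistanceMatrix(labels=dm.labels, data=noisy))
            theirs = sk_nj(SkDM(noisy, dm.labels))
            assert ours.compare_rfd(theirs) == 0.0

    def test_too_few_taxa(self):
        from xenoscan.phylo import DistanceMatrix

        with pytest.raises(PhyloError):
            neighbor_joining(
                DistanceMatrix(labels=["a", "b"], data=np.array([[0, 1], [1, 0]], float))
            )


class TestBootstrap:
    def _planted_alignment(self, rng, n_per=5, n_cols=120):
        # two clades with distinct column states, light noise
        rows = []
        base1 = rng.choice(list("ACDEF"), n_cols)
        base2 = rng.choice(list("VWYKR"), n_cols)
        for g, base in enumerate((base1, base2)):
            for i in range(n_per):
                row = base.copy()
                flip = rng.choice(n_cols, 5, replace=False)
                row[flip] = [
                    "ACDEFGHIKLMNPQRSTVWY"[j] for j in rng.integers(0, 20, 5)
                ]
                rows.append((f"g{g}_{i}", "".join(row)))
        return AlignedSet(records=tuple(rows))

    def test_separating_split_strongly_supported(self, rng):
        aln = self._planted_alignment(rng)
        tree = bootstrap_supports(aln, n_reps=100, seed=3)
        clade = {rid for rid, _ in aln.records if rid.startswith("g0_")}
        mono, support = is_monophyletic(tree, clade)
        assert mono and support >= 95

    def test_single_rep_supports_binary(self, rng):
        aln = self._planted_alignment(rng)
        tree = bootstrap_supports(aln, n_reps=1, seed=5)
        sups = {n.support for n in tree.non_tips() if getattr(n, "support", None) is not None}
        assert sups <= {0.0, 100.0}

    def test_same_seed_reproducible(self, rng):
        aln = self._planted_alignment(rng)
        t1 = bootstrap_supports(aln, n_reps=30, seed=11)
        t2 = bootstrap_supports(aln, n_reps=30, seed=11)
        s1 = sorted(n.support for n in t1.non_tips() if n.support is not None)
        s2 = sorted(n.support for n in t2.non_tips() if n.support is not None)
        assert s1 == s2

    def test_leaf_order_invariant(self, rng):
        aln = self._planted_alignment(rng)
        shuffled = AlignedSet(records=tuple(reversed(aln.records)))
        t1 = bootstrap_supports(aln, n_reps=25, seed=13)
        t2 = bootstrap_supports(shuffled, n_reps=25, seed=13)
        assert t1.compare_rfd(t2) == 0.0
        s1 = sorted(n.support for n in t1.non_tips() if n.support is not None)
        s2 = sorted(n.support for n in t2.non_tips() if n.support is not None)
        assert s1 == s2

    def test_short_alignment_rejected(self):
        aln = _aln([("a", "M"), ("b", "K"), ("c", "V")])
        with pytest.raises(PhyloError):
            bootstrap_supports(aln, n_reps=10, seed=1)


class TestMonophyly:
    def test_clade_found(self):
        tree = _tree("((a:1,b:1):1,(c:1,d:1):1);")
        mono, _ = is_monophyletic(tree, {"a", "b"})
        assert mono

    def test_split_pair_not_clade(self):
        tree = _tree("((a:1,c:1):1,(b:1,d:1):1);")
        mono, _ = is_monophyletic(tree, {"a", "b"})
        assert not mono

    def test_support_returned(self):
        tree = _tree("((a:1,b:1)98:1,(c:1,d:1)77:1,e:1);")
        mono, support = is_monophyletic(tree, {"a", "b"})
        assert mono and support == 98.0

    def test_improper_subset_rejected(self):
        tree = _tree("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(PhyloError):
            is_monophyletic(tree, {"a", "b", "c", "d"})
        with pytest.raises(PhyloError):
            is_monophyletic(tree, set())
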