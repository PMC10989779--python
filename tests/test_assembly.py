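import dendropy
import numpy as np
import pandas as pd
import pytest

from qmpflow import assembly, synthio

# four-tip fixture with printed branch lengths:
#   A, B sisters (0.1 each below a node at height 0.1 + 0.4 to root)
#   C at 0.3 from the AB/C ancestor, D basal at 0.8
FIXTURE_NEWICK = "(((A:0.1,B:0.1):0.4,C:0.3):0.3,D:0.8);"
# patristic distances: d(A,B)=0.2, d(A,C)=0.8, d(B,C)=0.8,
#                      d(A,D)=1.6, d(B,D)=1.6, d(C,D)=1.4


@pytest.fixture(scope="module")
def fixture_tree():
    return dendropy.Tree.get(data=FIXTURE_NEWICK, schema="newick")


class TestBetaMntd:
    def test_identical_communities_zero(self, fixture_tree):
        val = assembly.beta_mntd([1, 2, 0, 1], [1, 2, 0, 1], fixture_tree,
                                 ["A", "B", "C", "D"])
        assert val == 0.0

    def test_hand_computed_two_taxon_communities(self, fixture_tree):
        # community i = {A, B} equal weights; community j = {C, D} equal
        # nearest-taxon: A->C 0.8, B->C 0.8 ; C->A/B 0.8, D->C? D in j.
        # from i: 0.5*0.8 + 0.5*0.8 = 0.8 ; from j: C->{A,B} 0.8, D->{A,B} 1.6
        # -> 0.5*0.8 + 0.5*1.6 = 1.2 ; bMNTD = 0.5*(0.8 + 1.2) = 1.0
        val = assembly.beta_mntd([1, 1, 0, 0], [0, 0, 1, 1], fixture_tree,
                                 ["A", "B", "C", "D"])
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_unweighted_equals_weighted_for_even_abundances(self, fixture_tree):
        taxa = ["A", "B", "C", "D"]
        w = assembly.beta_mntd([2, 2, 0, 0], [0, 0, 3, 3], fixture_tree, taxa)
        u = assembly.beta_mntd([2, 2, 0, 0], [0, 0, 3, 3], fixture_tree, taxa,
                               abundance_weighted=False)
        assert w == pytest.approx(u)

    def test_linear_in_branch_lengths(self, fixture_tree):
        doubled = dendropy.Tree.get(
            data="(((A:0.2,B:0.2):0.8,C:0.6):0.6,D:1.6);", schema="newick"
        )
        taxa = ["A", "B", "C", "D"]
        v1 = assembly.beta_mntd([1, 0, 2, 0], [0, 3, 0, 1], fixture_tree, taxa)
        v2 = assembly.beta_mntd([1, 0, 2, 0], [0, 3, 0, 1], doubled, taxa)
        assert v2 == pytest.approx(2 * v1)

    def test_missing_tip_rejected(self, fixture_tree):
        with pytest.raises(ValueError, match="absent"):
            assembly.beta_mntd([1, 1], [1, 1], fixture_tree, ["A", "Zz"])


class TestBetaNti:
    def test_deterministic_under_seed(self, fixture_tree):
        taxa = ["A", "B", "C", "D"]
        d = assembly.tip_distance_matrix(fixture_tree, taxa)
        v1 = assembly.beta_nti([5, 1, 0, 0], [0, 0, 3, 2], d, n_null=999, seed=13)
        v2 = assembly.beta_nti([5, 1, 0, 0], [0, 0, 3, 2], d, n_null=999, seed=13)
        assert v1 == v2

    def test_star_tree_null_invariant(self):
        star = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick")
        d = assembly.tip_distance_matrix(star, ["A", "B", "C", "D"])
        assert assembly.beta_nti([4, 0, 1, 0], [0, 2, 0, 5], d, n_null=99, seed=0) == 0.0

    def test_minimum_null_size_enforced(self, fixture_tree):
        d = assembly.tip_distance_matrix(fixture_tree, ["A", "B", "C", "D"])
        with pytest.raises(ValueError):
            assembly.beta_nti([1, 0, 0, 1], [0, 1, 1, 0], d, n_null=50)

    def test_matrix_agrees_with_scalar_distribution(self, fixture_tree):
        """All-pairs z-scores fall where independent per-pair nulls put them."""
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(20)]
        tree = synthio.simulate_tree(taxa, rng)
        d = assembly.tip_distance_matrix(tree, taxa)
        abund = rng.multinomial(500, rng.dirichlet(np.ones(20)), size=6).astype(float)
        zmat = assembly.beta_nti_matrix(abund, d, n_null=499, seed=1)
        z_scalar = assembly.beta_nti(abund[0], abund[1], d, n_null=499, seed=2)
        assert abs(zmat[0, 1] - z_scalar) < 0.6  # same null, different draws


class TestRcBray:
    def test_identical_communities_vs_diffuse_pool_strongly_negative(self):
        rng = np.random.default_rng(1)
        pool_mat = rng.multinomial(1000, rng.dirichlet(np.ones(25)), size=30).astype(float)
        pool = assembly.SpeciesPool.from_matrix(pool_mat)
        comm = rng.multinomial(1000, rng.dirichlet(np.ones(25)))
        hits = sum(
            assembly.rc_bray(comm, comm, pool, n_null=199, seed=s) <= -0.95
            for s in range(20)
        )
        assert hits >= 19

    def test_degenerate_single_taxon_pool_is_zero(self):
        pool = assembly.SpeciesPool(np.array([1.0]), np.array([1.0]))
        val = assembly.rc_bray([10.0], [7.0], pool, n_null=99, seed=0)
        assert val == 0.0

    def test_pool_missing_taxon_rejected(self):
        pool = assembly.SpeciesPool(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            assembly.rc_bray([1.0, 5.0], [2.0, 0.0], pool, n_null=99)

    def test_bounded(self):
        rng = np.random.default_rng(2)
        pool = assembly.SpeciesPool.from_matrix(
            rng.multinomial(500, rng.dirichlet(np.ones(10)), size=20).astype(float)
        )
        ci = rng.multinomial(500, rng.dirichlet(np.ones(10)))
        cj = rng.multinomial(500, rng.dirichlet(np.ones(10)))
        val = assembly.rc_bray(ci, cj, pool, n_null=99, seed=3)
        assert -1.0 <= val <= 1.0


class TestClassifyProcess:
    @pytest.mark.parametrize(
        "b, rc, expected",
        [
            (-3.0, None, "heterogeneous_selection"),
            (3.0, None, "homogeneous_selection"),
            (1.0, 0.99, "dispersal_limitation"),
            (1.0, -0.99, "homogenizing_dispersal"),
            (1.0, 0.5, "undominated"),
            (-2.0, None, "heterogeneous_selection"),  # boundary joins selection
            (2.0, None, "homogeneous_selection"),
            (0.0, 0.95, "undominated"),  # boundary RC is undominated
            (0.0, -0.95, "undominated"),
        ],
    )
    def test_threshold_table(self, b, rc, expected):
        assert assembly.classify_process(b, rc) == expected

    def test_stegen_convention_swaps_selection(self):
        assert assembly.classify_process(-3.0, None, convention="stegen") == (
            "homogeneous_selection"
        )
        assert assembly.classify_process(3.0, None, convention="stegen") == (
            "heterogeneous_selection"
        )

    def test_missing_rc_rejected_inside_band(self):
        with pytest.raises(ValueError):
            assembly.classify_process(1.0, None)


class TestSummarize:
    def test_all_selection_is_fully_deterministic(self):
        df = pd.DataFrame({"process": ["homogeneous_selection"] * 5})
        out = assembly.summarize_processes(df)
        assert out.deterministic.iloc[0] == 1.0

    def test_fractions_partition(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"process": rng.choice(assembly.PROCESSES, 60)})
        out = assembly.summarize_processes(df)
        total = out[list(assembly.PROCESSES)].sum(axis=1).iloc[0]
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_pair_order_invariance(self):
        df = pd.DataFrame(
            {
                "sample_i": ["a", "b"],
                "sample_j": ["b", "c"],
                "process": ["undominated", "dispersal_limitation"],
            }
        )
        flipped = df.rename(columns={"sample_i": "sample_j", "sample_j": "sample_i"})
        pd.testing.assert_frame_equal(
            assembly.summarize_processes(df), assembly.summarize_processes(flipped)
        )


def test_phylogenetically_clustered_communities_show_more_selection():
    """Communities drawn from tree-clustered taxa pools are classified as
    selection more often than neutrally assembled controls."""
    rng = np.random.default_rng(5)
    p = 40
    taxa = [f"t{i}" for i in range(p)]
    tree = synthio.simulate_tree(taxa, rng)
    d = assembly.tip_distance_matrix(tree, taxa)
    order = np.argsort(d.sum(axis=0))  # crude tree layout: peripheral -> central

    def communities(clustered, n=10):
        out = np.zeros((n, p))
        for i in range(n):
            if clustered:
                block = order[:8] if i % 2 == 0 else order[-8:]
                idx = rng.choice(block, 6, replace=False)
            else:
                idx = rng.choice(p, 6, replace=False)
            out[i, idx] = rng.multinomial(300, np.ones(6) / 6)
        return out

    res_c = assembly.pairwise_assembly(
        pd.DataFrame(communities(True)), d, n_null=99, seed=0
    )
    res_n = assembly.pairwise_assembly(
        pd.DataFrame(communities(False)), d, n_null=99, seed=0
    )
    frac_c = assembly.summarize_processes(res_c).deterministic.iloc[0]
    frac_n = assembly.summarize_processes(res_n).deterministic.iloc[0]
    assert frac_c > frac_n
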