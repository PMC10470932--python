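import networkx as nx
import numpy as np
import pytest
from scipy import stats

from circnea.core_io import AssociationMatrix, DiseaseDAG, ExpressionTable
from circnea.similarity import (
    SemanticParams,
    build_bundle,
    disease_contribution,
    dss1,
    dss2,
    expression_similarity,
    gip_bandwidth,
    gip_kernel,
    jaccard,
    semantic_value,
)


def _random_dag(n_nodes: int, seed: int) -> DiseaseDAG:
    """Random DAG built over a fixed topological order (edges child->parent
    always point to earlier nodes, so acyclicity holds by construction)."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        for j in range(i):
            if rng.random() < 0.4:
                edges.append((nodes[i], nodes[j]))
    return DiseaseDAG(nodes, edges)


def _contribution_oracle(dag: DiseaseDAG, d: str, mu: float) -> dict[str, float]:
    """mu^(shortest ancestor-path length): with the max-over-children rule
    the best contribution path is the shortest child->parent path from d."""
    g = nx.DiGraph(dag.edges)
    g.add_nodes_from(dag.nodes)
    lengths = nx.single_source_shortest_path_length(g, d)
    return {e: mu ** lengths[e] for e in dag.ancestors(d)}


class TestDiseaseContribution:
    def test_self_contribution_is_one(self, diamond_dag):
        assert disease_contribution(diamond_dag, "d")["d"] == 1.0

    def test_single_chain_step(self):
        dag = DiseaseDAG(["d", "a"], [("d", "a")])
        assert disease_contribution(dag, "d")["a"] == 0.5

    def test_diamond_max_over_paths(self, diamond_dag):
        contrib = disease_contribution(diamond_dag, "d")
        oracle = _contribution_oracle(diamond_dag, "d", 0.5)
        assert contrib == oracle
        assert contrib["r"] == 0.25

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_shortest_path_oracle_on_random_dags(self, seed):
        dag = _random_dag(8, seed)
        params = SemanticParams(mu_semantic=0.5)
        for d in dag.nodes:
            assert disease_contribution(dag, d, params) == _contribution_oracle(dag, d, 0.5)

    def test_unknown_disease_rejected(self, diamond_dag):
        with pytest.raises(KeyError):
            disease_contribution(diamond_dag, "zzz")


class TestSemanticValue:
    def test_chain_values(self):
        iso = DiseaseDAG(["x"], [])
        assert semantic_value(iso, "x") == 1.0
        chain1 = DiseaseDAG(["d", "a"], [("d", "a")])
        assert semantic_value(chain1, "d") == 1.5
        chain2 = DiseaseDAG(["d", "a", "b"], [("d", "a"), ("a", "b")])
        assert semantic_value(chain2, "d") == 1.75


class TestDss1:
    def test_diagonal_is_one(self, diamond_dag):
        mat = dss1(diamond_dag, ["d", "a", "b", "r"])
        assert np.allclose(np.diag(mat), 1.0)

    def test_disjoint_dags_share_nothing(self):
        dag = DiseaseDAG(["a", "b", "x", "y"], [("a", "b"), ("x", "y")])
        mat = dss1(dag, ["a", "x"])
        assert mat[0, 1] == 0.0

    def test_two_leaves_sharing_one_parent(self):
        dag = DiseaseDAG(["l1", "l2", "p"], [("l1", "p"), ("l2", "p")])
        mat = dss1(dag, ["l1", "l2"])
        assert mat[0, 1] == pytest.approx((0.5 + 0.5) / (1.5 + 1.5))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_small_dags(self, seed):
        dag = _random_dag(8, seed + 50)
        ids = list(dag.nodes)
        mat = dss1(dag, ids)
        for i, di in enumerate(ids):
            ci = _contribution_oracle(dag, di, 0.5)
            for j, dj in enumerate(ids):
                cj = _contribution_oracle(dag, dj, 0.5)
                shared = sorted(set(ci) & set(cj))
                num = sum(ci[e] + cj[e] for e in shared)
                den = sum(ci.values()) + sum(cj.values())
                assert mat[i, j] == pytest.approx(num / den, abs=1e-14)

    def test_mu_one_reduces_to_shared_ancestor_fraction(self):
        # with mu=1 every ancestor contributes 1, so DSS1 is
        # 2|Ni n Nj| / (|Ni| + |Nj|)
        dag = _random_dag(8, 99)
        ids = list(dag.nodes)
        mat = dss1(dag, ids, SemanticParams(mu_semantic=1.0))
        for i, di in enumerate(ids):
            for j, dj in enumerate(ids):
                ni, nj = dag.ancestors(di), dag.ancestors(dj)
                assert mat[i, j] == pytest.approx(2 * len(ni & nj) / (len(ni) + len(nj)))

    def test_missing_disease_gets_zero_row(self, diamond_dag):
        mat = dss1(diamond_dag, ["d", "not_in_dag"])
        assert mat[1, :].sum() == 0 and mat[:, 1].sum() == 0


class TestDss2:
    # chain family: a -> p, b -> p, p -> r; hand-derived expected values
    # (natural log information content, mu = 0.5, max-normalised)
    @pytest.fixture()
    def chain_family(self):
        return DiseaseDAG(["a", "b", "p", "r"], [("a", "p"), ("b", "p"), ("p", "r")])

    def test_matches_hand_computed_oracle(self, chain_family):
        mat = dss2(chain_family, ["a", "b", "p", "r"])
        assert mat[0, 1] == pytest.approx(0.17185550924272538, abs=1e-12)
        assert mat[0, 2] == pytest.approx(0.1850751637998581, abs=1e-12)
        assert mat[0, 0] == pytest.approx(1.0)  # the matrix max is (a, a)

    def test_universal_ancestor_contributes_nothing(self):
        # r is in every DAG: -log(num/num_total) = -log(1) = 0, so two
        # diseases sharing only r have similarity 0
        dag = DiseaseDAG(["x", "y", "r"], [("x", "r"), ("y", "r")])
        mat = dss2(dag, ["x", "y"])
        assert mat[0, 1] == 0.0

    def test_disjoint_dags_zero(self):
        dag = DiseaseDAG(["a", "b", "x", "y"], [("a", "b"), ("x", "y")])
        mat = dss2(dag, ["a", "x"])
        assert mat[0, 1] == 0.0

    def test_literal_mode_uses_own_closure_size(self, chain_family):
        lit = dss2(chain_family, ["a", "b"], SemanticParams(dss2_mode="literal"))
        # literal contribution of every shared e is -log(|N_d|/4), constant
        n_shared = 2  # {p, r}
        ca = -np.log(3 / 4)
        raw_ab = n_shared * (ca + ca) / 3.5
        raw_aa = 3 * (ca + ca) / 3.5
        assert lit[0, 1] == pytest.approx(raw_ab / raw_aa)


class TestGip:
    def test_one_hot_profiles_bandwidth_one(self):
        assert gip_bandwidth(np.eye(4)) == 1.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="GIP undefined"):
            gip_kernel(np.zeros((3, 3), dtype=int), "disease")

    def test_one_hot_columns_closed_form(self):
        # two unit one-hot disease columns differing in 2 positions:
        # mu_bar = 1, so GD(0,1) = exp(-2)
        am = np.array([[1, 0], [0, 1]])
        gd = gip_kernel(am, "disease")
        assert gd[0, 1] == pytest.approx(np.exp(-2.0))
        assert gd[0, 0] == 1.0

    def test_identical_profiles_similarity_one(self):
        am = np.array([[1, 1], [0, 0], [1, 1]])
        gd = gip_kernel(am, "disease")
        assert gd[0, 1] == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        am = (rng.random((10, 7)) < 0.4).astype(int)
        am[0, 0] = 1  # ensure nonzero
        for axis, profiles in (("disease", am.T), ("circRNA", am)):
            k = gip_kernel(am, axis)
            mu_bar = np.mean([v @ v for v in profiles.astype(float)])
            for i in range(len(profiles)):
                for j in range(len(profiles)):
                    d2 = float(np.sum((profiles[i] - profiles[j]) ** 2))
                    expect = 1.0 if i == j else np.exp(-d2 / mu_bar)
                    assert k[i, j] == pytest.approx(expect, abs=1e-12)

    def test_literal_mode_multiplies_by_mean_norm(self):
        am = np.array([[1, 0], [0, 1]])
        gd = gip_kernel(am, "disease", literal=True)
        assert gd[0, 1] == pytest.approx(np.exp(-1.0 * 2.0))

    def test_monotone_in_profile_distance(self):
        am = np.zeros((6, 4), dtype=int)
        am[0, 0] = am[1, 0] = 1          # d0, d1 distance 0 apart from d0
        am[2, 1] = 1                      # d1 vs d2 differ more
        gc = gip_kernel(am.T, "disease")  # use columns as profiles
        # farther profiles must never score higher
        d = lambda i, j: np.sum((am.T[:, i] - am.T[:, j]) ** 2)
        assert (d(0, 1) <= d(0, 2)) == (gc[0, 1] >= gc[0, 2])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        am = (rng.random((8, 6)) < 0.5).astype(int)
        am[0, 0] = 1
        perm = rng.permutation(6)
        gd = gip_kernel(am, "disease")
        gd_p = gip_kernel(am[:, perm], "disease")
        assert np.allclose(gd_p, gd[np.ix_(perm, perm)])


class TestExpressionSimilarity:
    def test_identical_profiles(self):
        expr = ExpressionTable(["a", "b"], np.array([[1.0, 2.0, 3.0]] * 2))
        assert expression_similarity(expr)[0, 1] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.array([1.0, 5.0, 2.0, 9.0, 4.0])
        expr = ExpressionTable(["a", "b"], np.vstack([x, -x]))
        assert expression_similarity(expr)[0, 1] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(7)
        profs = rng.normal(size=(15, 32))
        expr = ExpressionTable([f"c{i}" for i in range(15)], profs)
        se = expression_similarity(expr)
        ranks = np.apply_along_axis(stats.rankdata, 1, profs)
        oracle = np.corrcoef(ranks)
        assert np.abs(se - oracle).max() < 1e-10

    def test_constant_profile_zeroed_with_warning(self):
        profs = np.array([[1.0, 1.0, 1.0], [0.0, 2.0, 5.0], [5.0, 1.0, 2.0]])
        expr = ExpressionTable(["a", "b", "c"], profs)
        with pytest.warns(UserWarning, match="constant"):
            se = expression_similarity(expr)
        assert se[0, 1] == 0.0 and se[0, 0] == 1.0

    def test_literal_mode_matches_printed_formula(self):
        rng = np.random.default_rng(3)
        profs = rng.normal(size=(4, 6))
        expr = ExpressionTable(list("abcd"), profs)
        lit = expression_similarity(expr, mode="literal")
        srt = -np.sort(-profs, axis=1)
        k = 4
        d = srt[0] - srt[2]
        assert lit[0, 2] == pytest.approx(1 - 6 * np.sum(d**2) / (k * (k - 1)))

    def test_single_dimension_rejected(self):
        with pytest.raises(ValueError):
            expression_similarity(ExpressionTable(["a"], np.ones((1, 1))))


class TestJaccard:
    def test_set_enumeration_cases(self):
        #      d0 d1 d2
        # c0    1  1  0
        # c1    1  0  0
        # c2    0  0  0
        am = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 0]])
        jc = jaccard(am, "circRNA")
        assert jc[0, 1] == pytest.approx(1 / 2)   # {d0,d1} vs {d0}
        assert jc[0, 2] == 0.0                    # one side empty
        assert jc[2, 2] == 0.0                    # both empty -> 0
        jd = jaccard(am, "disease")
        assert jd[0, 1] == pytest.approx(1 / 2)   # {c0,c1} vs {c0}
        assert jd[0, 2] == 0.0

    def test_one_of_three_overlap(self):
        am = np.array([[1, 1], [1, 0], [0, 1]])
        jd = jaccard(am, "disease")
        assert jd[0, 1] == pytest.approx(1 / 3)

    def test_identical_nonempty_sets(self):
        am = np.array([[1, 1], [1, 1]])
        assert jaccard(am, "disease")[0, 1] == pytest.approx(1.0)


class TestBundleInvariants:
    @pytest.mark.parametrize("seed", range(3))
    def test_symmetry_bounds_and_diagonals(self, seed):
        rng = np.random.default_rng(seed)
        m, n = int(rng.integers(8, 50)), int(rng.integers(5, 30))
        am_mat = (rng.random((m, n)) < 0.2).astype(int)
        am_mat[0, 0] = 1
        am = AssociationMatrix([f"c{i}" for i in range(m)], [f"d{j}" for j in range(n)], am_mat)
        dag = _random_dag(n, seed)
        dag = DiseaseDAG([f"d{j}" for j in range(n)],
                         [(f"d{int(c[1:])}", f"d{int(p[1:])}") for c, p in dag.edges])
        expr = ExpressionTable([f"c{i}" for i in range(m)], rng.normal(size=(m, 32)))
        b = build_bundle(am, dag, expr)
        for name in ("DSS1", "DSS2", "GD", "JD", "GC", "SE", "JC"):
            mat = getattr(b, name)
            assert np.abs(mat - mat.T).max() <= 1e-10, name
        for name in ("GD", "GC", "JD", "JC", "DSS1", "DSS2"):
            mat = getattr(b, name)
            assert mat.min() >= 0.0 and mat.max() <= 1.0 + 1e-12, name
        assert np.abs(b.SE).max() <= 1.0 + 1e-12
        for name in ("DSS1", "GD", "GC", "SE"):
            assert np.allclose(np.diag(getattr(b, name)), 1.0), name
        # Jaccard diagonal is 1 wherever the association set is non-empty
        nonempty = am_mat.sum(axis=0) > 0
        assert np.allclose(np.diag(b.JD)[nonempty], 1.0)
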