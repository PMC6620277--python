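"""Association measures, Hoeffding's D, graphical lasso, network extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcnsl_immune import (
    ExpressionMatrix,
    extract_network,
    graphical_lasso,
    hoeffding_d,
    network_from_expression,
    pairwise_association,
)
from pcnsl_immune.exceptions import ValidationError


def expr_from_rows(rows, names=None):
    names = names or [f"V{i}-001" for i in range(len(rows))]
    arr = np.abs(np.asarray(rows, dtype=float))
    return ExpressionMatrix(
        pd.DataFrame(arr, index=names, columns=[f"s{i}" for i in range(arr.shape[1])])
    )


class TestPairwiseAssociation:
    def test_perfect_linear_relation(self):
        x = np.arange(1.0, 11.0)
        em = expr_from_rows([x, 2 * x + 1])
        cm = pairwise_association(em)
        for m in ("pearson", "spearman", "kendall"):
            assert cm.matrix(m).iloc[0, 1] == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.arange(1.0, 12.0)  # positive, strictly increasing
        em = expr_from_rows([x, x**3])
        cm = pairwise_association(em)
        assert cm.matrix("spearman").iloc[0, 1] == pytest.approx(1.0)
        assert cm.matrix("pearson").iloc[0, 1] < 1.0

    def test_kendall_matches_pair_count_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(size=8)
        y = rng.uniform(size=8)
        em = expr_from_rows([x, y])
        tau = pairwise_association(em).matrix("kendall").iloc[0, 1]
        # O(n^2) concordant/discordant count (no ties with continuous draws)
        conc = disc = 0
        for i in range(8):
            for j in range(i + 1, 8):
                s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
                conc += s > 0
                disc += s < 0
        assert tau == pytest.approx((conc - disc) / (8 * 7 / 2))

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        em = expr_from_rows(rng.uniform(size=(4, 15)))
        cm = pairwise_association(em, methods=("pearson", "spearman", "kendall", "hoeffding"),
                                  n_permutations=20)
        for m in cm.values:
            mat = cm.matrix(m).to_numpy()
            np.testing.assert_array_equal(mat, mat.T)

    def test_zero_variance_flagged_not_zero(self):
        em = expr_from_rows([[1, 1, 1, 1], [1, 2, 3, 4]], names=["FLAT-001", "OK-001"])
        with pytest.warns(UserWarning, match="FLAT-001"):
            cm = pairwise_association(em)
        assert np.isnan(cm.matrix("pearson").loc["FLAT-001", "OK-001"])
        assert cm.undefined_variants == ["FLAT-001"]

    def test_unknown_method(self):
        em = expr_from_rows([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValidationError):
            pairwise_association(em, methods=("pearson", "banana"))


class TestHoeffding:
    def test_perfect_monotone_scaled_to_one(self):
        x = np.arange(1.0, 21.0)
        d, scaled, _ = hoeffding_d(x, x, n_permutations=0)
        assert scaled == pytest.approx(1.0, abs=1e-12)
        assert d == pytest.approx(1 / 30, abs=1e-12)

    def test_u_statistic_oracle(self):
        # independent direct computation from the phi kernel
        def phi(a, b):
            return 1.0 if a < b else (0.5 if a == b else 0.0)

        rng = np.random.default_rng(14)
        x = rng.uniform(size=12)
        y = rng.uniform(size=12)
        n = 12
        r = stats.rankdata(x)
        s = stats.rankdata(y)
        q = np.array(
            [sum(phi(x[j], x[i]) * phi(y[j], y[i]) for j in range(n) if j != i) + 1
             for i in range(n)]
        )  # Q_i = 1 + #(both strictly less); continuous draws have no ties
        d1 = np.sum((q - 1) * (q - 2))
        d2 = np.sum((r - 1) * (r - 2) * (s - 1) * (s - 2))
        d3 = np.sum((r - 2) * (s - 2) * (q - 1))
        expected = 30 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / (
            n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
        )
        _, scaled, _ = hoeffding_d(x, y, n_permutations=0)
        assert scaled == pytest.approx(expected, abs=1e-12)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(15)
        vals = [
            hoeffding_d(rng.uniform(size=50), rng.uniform(size=50), n_permutations=0)[1]
            for _ in range(500)
        ]
        assert abs(np.mean(vals)) < 0.01

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(16)
        x = rng.uniform(1, 2, size=25)
        y = rng.uniform(1, 2, size=25)
        d1 = hoeffding_d(x, y, n_permutations=0)[1]
        d2 = hoeffding_d(np.exp(x), y**3, n_permutations=0)[1]
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_dependence_detected_by_permutation_p(self):
        x = np.arange(30.0)
        y = (x - 15.0) ** 2  # non-monotone deterministic dependence
        _, scaled, p = hoeffding_d(x, y, n_permutations=200, seed=1)
        assert scaled > 0.1
        assert p < 0.05

    def test_minimum_n(self):
        with pytest.raises(ValidationError):
            hoeffding_d([1, 2, 3, 4], [1, 2, 3, 4])

    def test_permutation_p_uniform_under_null(self):
        rng = np.random.default_rng(17)
        pvals = [
            hoeffding_d(rng.uniform(size=20), rng.uniform(size=20),
                        n_permutations=99, seed=int(rng.integers(2**31)))[2]
            for _ in range(200)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestGraphicalLasso:
    def test_rho_zero_equals_inverse(self):
        rng = np.random.default_rng(18)
        s = np.cov(rng.standard_normal((3, 300)))
        net = graphical_lasso(s, rho=0.0)
        np.testing.assert_allclose(net.precision.to_numpy(), np.linalg.inv(s), atol=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_large_rho_gives_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((5, 80))
        s = np.corrcoef(a)
        rho = np.abs(s - np.eye(5)).max() + 0.01
        net = graphical_lasso(s, rho=rho)
        prec = net.precision.to_numpy()
        off = prec - np.diag(np.diag(prec))
        assert np.abs(off).max() < 1e-8
        assert len(net.edges) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_two_by_two_closed_form(self, seed):
        rng = np.random.default_rng(40 + seed)
        a, b = rng.uniform(0.5, 2, size=2)
        c = rng.uniform(-0.9, 0.9) * np.sqrt(a * b)
        rho = rng.uniform(0.01, 0.3)
        s = np.array([[a, c], [c, b]])
        net = graphical_lasso(s, rho=rho, tol=1e-10)
        w12 = np.sign(c) * max(abs(c) - rho, 0.0)
        expected = np.linalg.inv(np.array([[a, w12], [w12, b]]))
        np.testing.assert_allclose(net.precision.to_numpy(), expected, atol=1e-8)

    def test_objective_monotone_non_increasing(self):
        rng = np.random.default_rng(19)
        s = np.cov(rng.standard_normal((6, 100)))
        net = graphical_lasso(s, rho=0.05, mode="cd")
        diffs = np.diff(net.objective_path)
        assert (diffs <= 1e-10).all()

    def test_edge_set_nested_in_penalty(self):
        rng = np.random.default_rng(20)
        for _ in range(3):
            s = np.corrcoef(rng.standard_normal((6, 60)))
            e_small = {frozenset((r.source, r.target)) for _, r in
                       graphical_lasso(s, rho=0.05).edges.iterrows()}
            e_large = {frozenset((r.source, r.target)) for _, r in
                       graphical_lasso(s, rho=0.25).edges.iterrows()}
            assert e_large <= e_small

    def test_non_psd_rejected(self):
        s = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValidationError):
            graphical_lasso(s, rho=0.1)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            graphical_lasso(np.array([[1.0, 0.5], [0.2, 1.0]]), rho=0.1)


class TestExtractNetwork:
    def test_diagonal_precision_no_edges(self):
        prec = pd.DataFrame(np.diag([1.0, 2.0, 3.0]), index=list("abc"), columns=list("abc"))
        edges, degrees, hubs = extract_network(prec)
        assert len(edges) == 0
        assert (degrees == 0).all()
        assert hubs == []

    def test_star_graph_single_hub(self):
        # center connected to 4 spokes -> one node of degree 4
        p = np.eye(5) * 2.0
        for i in range(1, 5):
            p[0, i] = p[i, 0] = -0.4
        prec = pd.DataFrame(p, index=[f"n{i}" for i in range(5)], columns=[f"n{i}" for i in range(5)])
        edges, degrees, hubs = extract_network(prec)
        assert len(edges) == 4
        assert hubs == ["n0"]
        assert degrees["n0"] == 4

    def test_chain_structure_recovery(self):
        # tridiagonal truth: recovered support contains the chain and no
        # strong spurious edge
        rng = np.random.default_rng(21)
        p = 6
        prec_true = np.eye(p) * 1.5
        for i in range(p - 1):
            prec_true[i, i + 1] = prec_true[i + 1, i] = -0.55
        cov_true = np.linalg.inv(prec_true)
        x = rng.multivariate_normal(np.zeros(p), cov_true, size=500)
        s = np.cov(x.T)
        net = graphical_lasso(s, rho=0.02)
        found = {frozenset((r.source, r.target)) for _, r in net.edges.iterrows()}
        chain = {frozenset((f"v{i}", f"v{i+1}")) for i in range(p - 1)}
        assert chain <= found
        strong_spurious = [
            r for _, r in net.edges.iterrows()
            if frozenset((r.source, r.target)) not in chain and abs(r.partial_r) > 0.2
        ]
        assert strong_spurious == []


class TestNetworkFromExpression:
    def test_zero_variance_excluded(self):
        rng = np.random.default_rng(22)
        rows = np.abs(rng.standard_normal((4, 40)))
        rows[2] = 1.0
        em = ExpressionMatrix(
            pd.DataFrame(rows, index=["A-001", "B-001", "FLAT-001", "C-001"],
                         columns=[f"s{i}" for i in range(40)])
        )
        with pytest.warns(UserWarning, match="FLAT-001"):
            net = network_from_expression(em, rho=0.2)
        assert "FLAT-001" not in net.variant_ids

    def test_ebic_rho_recorded(self, small_cohort):
        cohort, _ = small_cohort
        net = network_from_expression(cohort.expression)
        assert net.rho in (0.02, 0.05, 0.1, 0.2, 0.4)
        assert net.precision.shape[0] == cohort.expression.n_variants
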