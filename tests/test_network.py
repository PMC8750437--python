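import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phasenet import SimulationConfig, make_ground_truth, simulate_expression
from phasenet.datasets import cml_hub_sign_patterns
from phasenet.network import (
    ConsensusNetwork,
    GeneNetwork,
    classify_hub_behavior,
    compare_prediction_quality,
    consensus_network,
    covariance_test,
    degree_distributions,
    degree_preserving_randomize,
    extract_hubs,
    fit_gene_model,
    infer_network,
    lars_path,
    make_partitions,
    predict_expression,
    resample_ensemble,
)


def cd_lasso_oracle(X, y, alpha, max_iter=20000, tol=1e-12):
    """Plain cyclic coordinate descent for (1/2n)||y - Xb||^2 + a||b||_1.

    Written from the subgradient conditions, independent of the LARS path
    implementation under test.
    """
    n, p = X.shape
    beta = np.zeros(p)
    r = y.copy()
    col_sq = (X**2).sum(axis=0)
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            if col_sq[j] == 0:
                continue
            rho = X[:, j] @ r + col_sq[j] * beta[j]
            new = np.sign(rho) * max(abs(rho) - n * alpha, 0.0) / col_sq[j]
            d = new - beta[j]
            if d != 0.0:
                r -= X[:, j] * d
                beta[j] = new
                delta = max(delta, abs(d))
        if delta < tol:
            break
    return beta


def standardized_problem(rng, n=50, p=10, signal=3):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros(p)
    beta[:signal] = rng.uniform(0.5, 2, signal) * rng.choice([-1, 1], signal)
    y = X @ beta + rng.standard_normal(n)
    return X, y - y.mean()


class TestLarsPath:
    def test_single_predictor_reaches_ols(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        x = (x - x.mean()) / x.std()
        y = 2.0 * x
        path = lars_path(x[:, None], y)
        ols = (x @ y) / (x @ x)
        assert path.coefs[0, -1] == pytest.approx(ols, rel=1e-10)
        assert path.alphas[-1] == pytest.approx(0.0, abs=1e-12)

    def test_knots_match_coordinate_descent_oracle(self):
        """Coefficients at every interior path knot solve the lasso problem at
        that penalty (200 random instances)."""
        rng = np.random.default_rng(2)
        worst = 0.0
        for _ in range(200):
            X, y = standardized_problem(rng)
            path = lars_path(X, y)
            for k in range(1, path.n_knots):
                ref = cd_lasso_oracle(X, y, path.alphas[k])
                worst = max(worst, np.abs(path.coefs[:, k] - ref).max())
        assert worst < 1e-6

    def test_orthogonal_response_has_trivial_path(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 5))
        X = (X - X.mean(0)) / X.std(0)
        # project noise out of the span of X
        y = rng.standard_normal(40)
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]
        y -= y.mean()
        path = lars_path(X, y)
        assert path.alphas[0] < 1e-10

    def test_constant_response_empty_path(self):
        X = np.random.default_rng(4).standard_normal((10, 3))
        path = lars_path(X, np.ones(10))
        assert path.n_knots == 1
        assert (path.coefs == 0).all()


class TestCovarianceTest:
    def test_direct_formula_on_tiny_instance(self):
        """T equals a from-scratch evaluation of the defining difference of
        fitted inner products on a fixed tiny problem."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((6, 2))
        X = (X - X.mean(0)) / X.std(0)
        y = 1.5 * X[:, 0] + rng.standard_normal(6) * 0.5
        y -= y.mean()
        sigma_sq = 0.8
        path = lars_path(X, y)
        tests = {t.predictor: t for t in covariance_test(path, X, y, sigma_sq)}
        for t in tests.values():
            k = t.entry_knot
            alpha_next = path.alphas[k + 1]
            full = y @ (X @ path.coefs[:, k + 1])
            active_before = np.flatnonzero(path.coefs[:, k] != 0)
            if len(active_before):
                beta_r = cd_lasso_oracle(X[:, active_before], y, alpha_next)
                restricted = y @ (X[:, active_before] @ beta_r)
            else:
                restricted = 0.0
            expected = max((full - restricted) / sigma_sq, 0.0)
            assert t.T == pytest.approx(expected, abs=1e-8)
            assert t.p == pytest.approx(np.exp(-expected), rel=1e-10)

    def test_null_first_knot_exponential(self):
        """Under a global null the first-entry statistic is ~ Exp(1)."""
        Ts = []
        for rep in range(500):
            rng = np.random.default_rng(10_000 + rep)
            X = rng.standard_normal((100, 10))
            X = (X - X.mean(0)) / X.std(0)
            y = rng.standard_normal(100)
            y -= y.mean()
            path = lars_path(X, y)
            first = min(covariance_test(path, X, y, 1.0),
                        key=lambda t: t.entry_knot)
            Ts.append(first.T)
        assert np.mean(Ts) == pytest.approx(1.0, abs=0.15)

    def test_strong_signal_is_significant(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(20_000 + rep)
            X = rng.standard_normal((60, 8))
            X = (X - X.mean(0)) / X.std(0)
            y = 5.0 * X[:, 0] + rng.standard_normal(60)
            y -= y.mean()
            path = lars_path(X, y)
            tests = {t.predictor: t for t in covariance_test(path, X, y, 1.0)}
            hits += int(tests[0].p < 0.001)
        assert hits >= 99

    def test_invalid_sigma_rejected(self):
        rng = np.random.default_rng(6)
        X, y = standardized_problem(rng, n=20, p=4)
        path = lars_path(X, y)
        with pytest.raises(ValueError):
            covariance_test(path, X, y, 0.0)


class TestGeneModel:
    @staticmethod
    def _frame(values):
        return pd.DataFrame(
            values,
            index=[f"G{i:03d}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        )

    def test_noise_free_single_regulator(self):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((10, 30))
        vals[0] = 1.0 * vals[1]
        links = fit_gene_model(self._frame(vals), "G000")
        assert list(links["regulator"]) == ["G001"]
        assert links["weight"].iloc[0] > 0

    def test_pure_noise_target_selects_nothing(self):
        clean = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            vals = rng.standard_normal((30, 65))
            links = fit_gene_model(self._frame(vals), "G000")
            clean += int(len(links) == 0)
        assert clean >= 19  # >= 95% of seeds

    def test_two_regulators_recovered_with_signs(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            vals = rng.standard_normal((30, 65))
            vals[0] = vals[1] - vals[2] + 0.2 * rng.standard_normal(65)
            links = fit_gene_model(self._frame(vals), "G000")
            got = {(r.regulator, np.sign(r.weight)) for r in links.itertuples()}
            ok += int({("G001", 1.0), ("G002", -1.0)} <= got)
        assert ok >= 18  # >= 90% of seeds

    def test_target_never_its_own_predictor(self, small_data):
        matrix, _ = small_data
        links = fit_gene_model(matrix.iloc[:, :65], "G0005")
        assert "G0005" not in set(links["regulator"])


class TestInferNetwork:
    def test_no_self_loops_and_q_cutoff(self, small_data):
        matrix, _ = small_data
        net = infer_network(matrix.iloc[:, :65])
        assert not (net.edges["regulator"] == net.edges["target"]).any()
        assert (net.edges["q"] <= 0.01 + 1e-12).all()

    def test_empty_gene_set(self, small_data):
        matrix, _ = small_data
        net = infer_network(matrix.iloc[:, :65], gene_set=[])
        assert len(net.edges) == 0

    def test_mini_consensus_recovers_planted_network(self, small_truth, small_data):
        """A 20-network consensus on the 60-gene fixture recovers the planted
        edges with high recall; remaining false edges are reversals of true
        edges (direction is not identifiable from covariance alone)."""
        matrix, _ = small_data
        ens = resample_ensemble(matrix, n_networks=20, seed=11)
        cons = consensus_network(ens, min_support=18)
        true, pred = small_truth.edge_set, cons.edge_set
        tp = len(true & pred)
        assert tp / len(true) >= 0.8
        assert tp / len(pred) >= 0.6
        false = pred - true
        reversals = {(a, b) for a, b in false if (b, a) in true}
        assert len(reversals) >= 0.9 * len(false)


class TestResampling:
    def test_partition_sizes_and_disjointness(self):
        ids = [f"s{i}" for i in range(87)]
        train, test, seeds = make_partitions(ids, 25, 0.75, seed=3)
        for tr, te in zip(train, test):
            assert len(tr) == 65 and len(te) == 22
            assert set(tr) | set(te) == set(ids)
            assert set(tr).isdisjoint(te)

    def test_seed_reproducibility(self):
        ids = [f"s{i}" for i in range(40)]
        t1 = make_partitions(ids, 5, 0.75, seed=9)
        t2 = make_partitions(ids, 5, 0.75, seed=9)
        assert t1 == t2

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_partitions([f"s{i}" for i in range(4)], 3, 0.5, seed=0)


class TestPrediction:
    def test_noise_free_expression_predicted_perfectly(self):
        """Zero noise makes every linked gene's held-out prediction exact
        (which gene serves as the predictor is not identifiable: all phase
        profiles are collinear in the group-mean space)."""
        cfg = SimulationConfig(
            n_genes=30, n_hubs=3, out_degree_range=(3, 4), noise_sd=0.0, seed=15
        )
        gt = make_ground_truth(cfg)
        matrix, _ = simulate_expression(gt, cfg)
        train, test, _ = make_partitions(list(matrix.columns), 1, 0.75, seed=15)
        net = infer_network(matrix[train[0]])
        assert set(gt.edges["target"]) <= set(net.edges["target"])
        pred = predict_expression(net, matrix[test[0]])
        r = pred["r"].dropna()
        assert len(r) > 0
        assert (r.abs() > 0.999).all()

    def test_permuted_test_labels_destroy_prediction(self, small_truth, small_data):
        matrix, _ = small_data
        net = infer_network(matrix.iloc[:, :65])
        test = matrix.iloc[:, 65:]
        rng = np.random.default_rng(17)
        shuffled = test.copy()
        shuffled.iloc[:] = test.to_numpy()[:, rng.permutation(test.shape[1])]
        # permute each gene's test values independently to break covariation
        for i in range(shuffled.shape[0]):
            shuffled.iloc[i] = rng.permutation(shuffled.iloc[i].to_numpy())
        r = predict_expression(net, shuffled)["r"].dropna()
        assert abs(r.median()) < 0.35

    def test_unconnected_genes_excluded(self, small_data):
        matrix, _ = small_data
        net = infer_network(matrix.iloc[:, :65])
        pred = predict_expression(net, matrix.iloc[:, 65:])
        no_in = pred["n_predictors"] == 0
        assert pred.loc[no_in, "r"].isna().all()


def _toy_network(edge_rows):
    edges = pd.DataFrame(edge_rows, columns=["regulator", "target", "weight",
                                             "T", "p", "q"])
    genes = sorted(set(edges["regulator"]) | set(edges["target"]))
    mean = pd.Series(0.0, index=genes)
    sd = pd.Series(1.0, index=genes)
    return GeneNetwork(genes, edges, mean, sd)


class TestRandomization:
    def test_degree_sequences_preserved(self, small_data):
        matrix, _ = small_data
        net = infer_network(matrix.iloc[:, :65])
        for rnd in degree_preserving_randomize(net, n_instances=5, seed=1):
            pd.testing.assert_series_equal(rnd.out_degrees(), net.out_degrees())
            pd.testing.assert_series_equal(rnd.in_degrees(), net.in_degrees())
            assert not (rnd.edges["regulator"] == rnd.edges["target"]).any()
            assert not rnd.edges.duplicated(["regulator", "target"]).any()

    def test_single_edge_unchanged(self):
        net = _toy_network([("a", "b", 1.0, 5.0, 0.01, 0.01)])
        out = degree_preserving_randomize(net, n_instances=3, seed=2)
        for rnd in out:
            assert list(rnd.edges[["regulator", "target"]].itertuples(index=False,
                                                                     name=None)) \
                == [("a", "b")]

    def test_toy_graph_outputs_are_valid_rewirings(self):
        net = _toy_network(
            [
                ("a", "b", 1.0, 5, 0.01, 0.01),
                ("c", "d", -1.0, 5, 0.01, 0.01),
                ("e", "f", 0.5, 5, 0.01, 0.01),
                ("g", "h", 2.0, 5, 0.01, 0.01),
            ]
        )
        regs = sorted(net.edges["regulator"])
        tgts = sorted(net.edges["target"])
        weights = sorted(net.edges["weight"])
        for rnd in degree_preserving_randomize(net, n_instances=20, seed=3):
            assert sorted(rnd.edges["regulator"]) == regs
            assert sorted(rnd.edges["target"]) == tgts
            assert sorted(rnd.edges["weight"]) == weights
            assert not (rnd.edges["regulator"] == rnd.edges["target"]).any()
            assert not rnd.edges.duplicated(["regulator", "target"]).any()

    def test_weights_travel_with_edges(self):
        net = _toy_network(
            [("a", "b", 1.25, 5, 0.01, 0.01), ("c", "d", -0.75, 5, 0.01, 0.01)]
        )
        for rnd in degree_preserving_randomize(net, n_instances=10, seed=5):
            by_reg = rnd.edges.set_index("regulator")["weight"]
            assert by_reg["a"] == 1.25 and by_reg["c"] == -0.75


class TestPredictionComparison:
    def test_identical_inputs_uninformative(self):
        rng = np.random.default_rng(19)
        r = rng.uniform(0.1, 0.9, 200)
        out = compare_prediction_quality(r, r)
        assert 0.4 < out["utest_p"] < 0.6

    def test_planted_networks_beat_random(self, small_data):
        matrix, _ = small_data
        net = infer_network(matrix.iloc[:, :65])
        test = matrix.iloc[:, 65:]
        real = predict_expression(net, test)["r"].dropna().to_numpy()
        rand = np.concatenate(
            [
                predict_expression(rnd, test)["r"].dropna().to_numpy()
                for rnd in degree_preserving_randomize(net, 10, seed=7)
            ]
        )
        out = compare_prediction_quality(real, rand)
        assert out["median_real"] > out["median_random"]
        assert out["utest_p"] < 0.01

    def test_constant_identical_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_prediction_quality(np.zeros(10), np.zeros(10))


class TestConsensus:
    @staticmethod
    def _mock_ensemble(edge_lists):
        from phasenet.network import NetworkEnsemble

        nets = [_toy_network(rows) for rows in edge_lists]
        genes = sorted({g for n in nets for g in n.genes})
        for n in nets:
            n.genes = genes
        return NetworkEnsemble(nets, [[]] * len(nets), [[]] * len(nets),
                               list(range(len(nets))))

    def test_support_thresholding(self):
        always = ("a", "b", 1.0, 5, 0.001, 0.005)
        sometimes = ("c", "d", 1.0, 5, 0.001, 0.005)
        lists = []
        for i in range(100):
            rows = [always]
            if i < 89:
                rows.append(sometimes)
            lists.append(rows)
        cons = consensus_network(self._mock_ensemble(lists), min_support=90)
        assert cons.edge_set == {("a", "b")}
        assert cons.edges.loc[0, "support"] == 100

    def test_support_counts_match_brute_force(self, small_data):
        matrix, _ = small_data
        ens = resample_ensemble(matrix, n_networks=10, seed=13)
        cons = consensus_network(ens, min_support=1)
        for row in cons.edges.itertuples():
            tally = sum(
                ((net.edges["regulator"] == row.regulator)
                 & (net.edges["target"] == row.target)).any()
                for net in ens.networks
            )
            assert tally == row.support

    def test_empty_ensemble(self):
        from phasenet.network import NetworkEnsemble

        cons = consensus_network(NetworkEnsemble([], [], [], []), min_support=90)
        assert len(cons.edges) == 0


class TestHubs:
    @staticmethod
    def _consensus_from(rows, genes):
        edges = pd.DataFrame(rows, columns=["regulator", "target", "support",
                                            "mean_weight", "mean_q"])
        return ConsensusNetwork(edges, 100, 90, genes)

    def test_min_out_two_is_superset_of_three(self):
        rows = [("h1", f"t{i}", 95, 1.0, 0.005) for i in range(4)]
        rows += [("h2", f"u{i}", 95, 1.0, 0.005) for i in range(2)]
        genes = sorted({r[0] for r in rows} | {r[1] for r in rows})
        cons = self._consensus_from(rows, genes)
        three = set(extract_hubs(cons, min_out=3)["gene"])
        two = set(extract_hubs(cons, min_out=2)["gene"])
        assert three <= two
        assert three == {"h1"} and two == {"h1", "h2"}

    def test_sorted_by_out_degree_then_id(self):
        rows = [("b", f"t{i}", 95, 1.0, 0.005) for i in range(3)]
        rows += [("a", f"u{i}", 95, 1.0, 0.005) for i in range(3)]
        rows += [("c", f"v{i}", 95, 1.0, 0.005) for i in range(5)]
        genes = sorted({r[0] for r in rows} | {r[1] for r in rows})
        hubs = extract_hubs(self._consensus_from(rows, genes), min_out=3)
        assert list(hubs["gene"]) == ["c", "a", "b"]

    def test_empty_consensus_gives_no_hubs(self):
        cons = self._consensus_from([], ["a", "b"])
        assert len(extract_hubs(cons, min_out=3)) == 0


class TestBehaviorClassification:
    def test_all_published_patterns_reproduced(self):
        """The sign-pattern rule assigns each of the 24 published hub genes to
        its reported phase-behavior group."""
        table = cml_hub_sign_patterns()
        assert len(table) == 24
        for row in table.itertuples():
            got = classify_hub_behavior((row.s1, row.s2, row.s3))
            assert got == row.group, row.gene

    @pytest.mark.parametrize(
        "pattern,expected",
        [
            (("-", "-", "-"), "toward_blast_down"),
            (("+", "=", "+"), "accelerated_distinct"),
            (("=", "+", "+"), "toward_blast_up"),
            (("-", "+", "-"), "accelerated_distinct"),
            (("=", "=", "="), "unclassified"),
        ],
    )
    def test_representative_patterns(self, pattern, expected):
        assert classify_hub_behavior(pattern) == expected

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            classify_hub_behavior(("x", "=", "+"))


class TestDegreeDistributions:
    def test_histograms_sum_to_gene_count(self, small_data):
        matrix, _ = small_data
        net = infer_network(matrix.iloc[:, :65])
        dist = degree_distributions(net)
        assert sum(dist["out_degree_hist"].values()) == len(net.genes)
        assert sum(dist["in_degree_hist"].values()) == len(net.genes)
        assert dist["n_no_incoming"] == dist["in_degree_hist"].get(0, 0)

    def test_empty_network_all_zero(self):
        net = GeneNetwork(
            ["a", "b"],
            pd.DataFrame(columns=["regulator", "target", "weight", "T", "p", "q"]),
            pd.Series(0.0, index=["a", "b"]),
            pd.Series(1.0, index=["a", "b"]),
        )
        dist = degree_distributions(net)
        assert dist["out_degree_hist"] == {0: 2}
        assert dist["n_no_incoming"] == 2
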