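import numpy as np
import pytest

import diseaseflow as df
from diseaseflow.errors import DiseaseFlowError, UnknownIDError
from diseaseflow.walk import expected_total_visits

from conftest import small_fixture


class TestTransitionModel:
    def test_toy_degrees_and_absorption(self, path2):
        tm = df.build_transition_model(path2)
        assert np.allclose(tm.strengths, [2.0, 2.0])
        assert np.allclose(tm.Q.toarray(), [[0, 0.5], [0.5, 0]])
        assert np.allclose(tm.a, [0.5, 0.5])
        assert np.allclose(tm.start_distribution("D1"), [1.0, 0.0])

    def test_isolated_attached_protein_absorbs_immediately(self):
        net = df.build_network([], {"D1": {"P9"}})
        tm = df.build_transition_model(net)
        assert tm.Q.nnz == 0
        assert tm.a[0] == 1.0

    def test_large_beta_drives_absorption_to_one(self):
        net = df.build_network([("P1", "P2")], {"D1": {"P1"}, "D2": {"P2"}},
                               beta=1e9)
        tm = df.build_transition_model(net)
        assert np.all(tm.a > 1 - 1e-8)

    def test_rows_plus_absorption_sum_to_one(self, planted):
        net, _ = planted
        tm = df.build_transition_model(net)
        sums = np.asarray(tm.Q.sum(axis=1)).ravel() + tm.a
        assert np.abs(sums - 1).max() < 1e-12

    def test_unpruned_network_rejected(self):
        net = df.build_network([("P1", "P2"), ("X", "Y")], {"D1": {"P1"}})
        with pytest.raises(DiseaseFlowError, match="prune"):
            df.build_transition_model(net)


class TestWeightVectors:
    def test_path2_closed_form(self, path2):
        tm = df.build_transition_model(path2)
        w1 = df.compute_weight_vector(tm, "D1").w
        w2 = df.compute_weight_vector(tm, "D2").w
        assert np.abs(w1 - [4 / 3, 2 / 3]).max() < 1e-12
        assert np.abs(w2 - [2 / 3, 4 / 3]).max() < 1e-12

    def test_catalog_closed_forms(self, catalog):
        for name, entry in catalog.items():
            net = entry["network"]
            tm = df.build_transition_model(net)
            W = df.compute_all_weight_vectors(tm)
            for d, expected in entry["weights"].items():
                got = W[net.diseases.index(d)]
                for p, v in expected.items():
                    assert abs(got[net.protein_index(p)] - v) < 1e-12, (name, d, p)

    def test_single_attachment_gives_one_visit(self):
        net = df.build_network([], {"D1": {"P1"}})
        tm = df.build_transition_model(net)
        assert df.compute_weight_vector(tm, "D1").w[0] == pytest.approx(1.0, abs=1e-15)

    def test_identical_gene_sets_give_identical_vectors(self):
        net = df.build_network(
            [("P1", "P2"), ("P2", "P3")],
            {"D1": {"P1", "P3"}, "D2": {"P1", "P3"}, "D3": {"P2"}},
        )
        tm = df.build_transition_model(net)
        W = df.compute_all_weight_vectors(tm)
        assert np.array_equal(W[0], W[1])

    def test_batch_matches_per_disease_solves(self, planted):
        net, _ = planted
        tm = df.build_transition_model(net)
        W = df.compute_all_weight_vectors(tm)
        for d in net.diseases:
            row = df.compute_weight_vector(tm, d).w
            assert np.abs(W[net.diseases.index(d)] - row).max() < 1e-12

    def test_unknown_disease_rejected(self, path2):
        tm = df.build_transition_model(path2)
        with pytest.raises(UnknownIDError):
            df.compute_weight_vector(tm, "D99")

    def test_conservation_every_walk_absorbed_once(self):
        for seed in range(5):
            net, _ = small_fixture(seed)
            net, _ = df.prune_unreachable(net)
            tm = df.build_transition_model(net)
            W = df.compute_all_weight_vectors(tm)
            assert np.abs(W @ tm.a - 1.0).max() < 1e-10

    def test_total_visits_monotone_decreasing_in_beta(self):
        net, _ = small_fixture(7)
        totals = []
        for beta in (0.5, 1.0, 2.0, 4.0):
            nb = df.build_network(list(net.ppi_edges),
                                  {d: set(g) for d, g in net.associations.items()},
                                  beta=beta)
            nb, _ = df.prune_unreachable(nb)
            tm = df.build_transition_model(nb)
            W = df.compute_all_weight_vectors(tm)
            totals.append(W.sum())
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))


class TestMonteCarloOracle:
    def test_path2_within_three_stderr(self, path2):
        emp = df.simulate_walks(path2, "D1", n_walks=200000, seed=11)
        assert emp.n_truncated == 0
        exact = np.array([4 / 3, 2 / 3])
        assert np.all(np.abs(emp.w - exact) <= 3 * emp.se + 1e-12)

    def test_zero_walks_returns_zero_vector_with_warning(self, path2):
        with pytest.warns(UserWarning):
            emp = df.simulate_walks(path2, "D1", n_walks=0, seed=0)
        assert np.all(emp.w == 0)

    def test_immediate_absorption_is_exact(self):
        net = df.build_network([], {"D1": {"P1"}})
        emp = df.simulate_walks(net, "D1", n_walks=500, seed=3)
        assert np.all(emp.w == 1.0)
        assert np.all(emp.se == 0.0)

    def test_random_networks_agree_within_four_stderr(self):
        """Analytic vs empirical weights on random planted networks."""
        n_entries = n_ok = 0
        for seed in (1, 2, 3):
            net, _ = small_fixture(seed)
            net, _ = df.prune_unreachable(net)
            tm = df.build_transition_model(net)
            disease = net.diseases[seed % len(net.diseases)]
            exact = df.compute_weight_vector(tm, disease).w
            emp = df.simulate_walks(net, disease, n_walks=20000, seed=100 + seed)
            assert emp.n_truncated == 0
            tol = 4 * emp.se + 1e-9
            n_entries += exact.size
            n_ok += int(np.sum(np.abs(emp.w - exact) <= tol))
        assert n_ok / n_entries >= 0.99


def test_expected_total_visits_matches_row_sums(path2):
    tm = df.build_transition_model(path2)
    # fundamental-matrix row sums, tiny enough to invert densely
    N = np.linalg.inv(np.eye(2) - tm.Q.toarray())
    assert np.abs(expected_total_visits(tm) - N.sum(axis=1)).max() < 1e-12
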