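import numpy as np
import pytest

import diseaseflow as df
from diseaseflow.errors import ParameterError
from diseaseflow.whatif import rescore_frozen

from conftest import small_fixture


def build_model(seed, K=2, **overrides):
    net, _ = small_fixture(seed, **overrides)
    model = df.FlowModel.from_network(net)
    model.fit_clusters(K=K, seed=seed)
    return model


class TestApplyEdit:
    def test_noop_keeps_network_identical(self, path2):
        edited = df.apply_edit(path2, "D1", {"P1"})
        assert edited == path2

    def test_new_disease_adds_attachment(self, path2):
        edited = df.apply_edit(path2, "D3", {"P1"})
        assert "D3" in edited.diseases
        tm = df.build_transition_model(edited)
        assert tm.strengths[edited.protein_index("P1")] == 3.0

    def test_empty_gene_list_rejected(self, path2):
        with pytest.raises(ParameterError):
            df.apply_edit(path2, "D1", set())

    def test_unknown_gene_added_as_isolated_protein(self, path2):
        edited = df.apply_edit(path2, "D3", {"PX"})
        assert "PX" in edited.proteins

    def test_replacement_can_orphan_and_prune_a_component(self):
        net = df.build_network(
            [("A", "B"), ("X", "Y")], {"D1": {"A"}, "D2": {"X"}}
        )
        edited = df.apply_edit(net, "D2", {"A"})
        assert "X" not in edited.proteins and "Y" not in edited.proteins


class TestApproxWhatIf:
    def test_noop_equals_base_with_zero_bounds(self):
        model = build_model(0)
        d = model.diseases[0]
        edited = df.apply_edit(model.net, d, set(model.net.associations[d]))
        res = df.approx_whatif(model, edited, d)
        assert res.exact_available
        qi = model.diseases.index(d)
        for e, c, b in res.approx_correlations:
            assert b == 0.0
            assert abs(c - model.C[qi, model.diseases.index(e)]) < 1e-12
        base_row = model.clusters.membership_row(d)
        for cid, p, b in res.approx_memberships:
            assert b == 0.0
            k = model.clusters.cluster_ids.index(cid)
            assert abs(p - base_row[k]) < 1e-9

    def test_new_disease_in_untouched_component_is_exact(self, catalog):
        net = catalog["two-components"]["network"]
        model = df.FlowModel.from_network(net)
        edited = df.apply_edit(net, "D9", {"P3"})
        res = df.approx_whatif(model, edited, "D9")
        corr_exact, _ = rescore_frozen(model, edited, "D9")
        for e, c, b in res.approx_correlations:
            assert b >= 0.0
            # D1/D2 live in the other component: truly unchanged vectors
            if e in ("D1", "D2"):
                assert abs(c - corr_exact[e]) < 1e-12

    def test_base_model_not_mutated(self):
        model = build_model(1)
        W_before = model.W.copy()
        P_before = model.clusters.P.copy()
        edited = df.apply_edit(model.net, "DNEW", {model.net.proteins[0]})
        df.approx_whatif(model, edited, "DNEW")
        assert np.array_equal(model.W, W_before)
        assert np.array_equal(model.clusters.P, P_before)


class TestErrorBoundSoundness:
    def random_edit(self, rng, model):
        if rng.random() < 0.5:
            disease = model.diseases[int(rng.integers(len(model.diseases)))]
        else:
            disease = "DNEW"
        k = int(rng.integers(1, 4))
        genes = set(rng.choice(model.net.proteins, size=k, replace=False).tolist())
        if rng.random() < 0.3:
            genes.add("PNEW")
        return disease, genes

    @pytest.mark.parametrize("master_seed", [101, 202, 303])
    def test_bounds_cover_true_errors_on_random_edits(self, master_seed):
        """Central guarantee: bound >= |approx - exact| for every reported
        correlation and membership, over random association edits."""
        rng = np.random.default_rng(master_seed)
        models = {}
        for _ in range(34):
            fixture_seed = int(rng.integers(50))
            if fixture_seed not in models:
                models[fixture_seed] = build_model(fixture_seed)
            model = models[fixture_seed]
            disease, genes = self.random_edit(rng, model)
            edited = df.apply_edit(model.net, disease, genes)
            res = df.approx_whatif(model, edited, disease)
            if res.exact_available:
                continue  # no-op: answered exactly from the base model
            corr_exact, memb_exact = rescore_frozen(model, edited, disease)
            for e, c, b in res.approx_correlations:
                assert 0.0 <= b <= 1.0
                assert abs(c - corr_exact[e]) <= b + 1e-12
            for cid, p, b in res.approx_memberships:
                assert 0.0 <= b <= 1.0
                assert abs(p - memb_exact[cid]) <= b + 1e-12

    def test_diversion_mass_monotone_in_edit_size(self):
        """Adding attachments at more proteins never shrinks the diverted
        probability mass driving the bound (addition-only edits)."""
        from diseaseflow.whatif import _EditFrame, _visit_delta_bounds

        model = build_model(5)
        base_genes = set(model.net.associations[model.diseases[0]])
        untouched = [p for p in model.net.proteins if p not in base_genes]
        prev = None
        for extra in range(1, 4):
            genes = base_genes | set(untouched[:extra])
            edited = df.apply_edit(model.net, model.diseases[0], genes)
            frame = _EditFrame(model, edited, model.diseases[0])
            # compare the diversion mass sum_p w_p |s0/s1 - 1| per disease
            old = model.net.associations[model.diseases[0]]
            changed = sorted(old ^ genes)
            s0 = model.tm.strengths
            idx1 = {p: i for i, p in enumerate(edited.proteins)}
            mass = np.zeros(len(model.diseases))
            for di in range(len(model.diseases)):
                if model.diseases[di] == model.diseases[0]:
                    continue
                for p in changed:
                    i0 = model.net.protein_index(p)
                    mass[di] += model.W[di, i0] * abs(
                        s0[i0] / frame.tm1.strengths[idx1[p]] - 1.0)
            if prev is not None:
                assert np.all(mass >= prev - 1e-12)
            prev = mass


class TestExactWhatIf:
    def test_noop_reproduces_weight_matrix(self):
        model = build_model(2)
        d = model.diseases[0]
        edited = df.apply_edit(model.net, d, set(model.net.associations[d]))
        exact = df.exact_whatif(edited)
        assert np.abs(exact.W - model.W).max() < 1e-12

    def test_added_disease_keeps_conservation(self, path2):
        edited = df.apply_edit(path2, "D3", {"P1"})
        exact = df.exact_whatif(edited)
        assert exact.W.shape == (3, 2)
        tm = df.build_transition_model(edited)
        assert np.abs(exact.W @ tm.a - 1.0).max() < 1e-10
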