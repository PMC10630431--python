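"""Niche-phenotype association, FDR control, architecture summarisation."""

import numpy as np
import pandas as pd
import pytest

from nichescape import (
    apply_marker_exclusions,
    associations,
    cell_niche_weights,
    eligible_contexts,
    fdr_filter,
    niche_contribution,
    phenotype_clusters,
    qvalues,
    rho_matrix,
    robust_cell_types,
    spearman_association,
    summarize_architecture,
)


class TestEligibility:
    def test_pure_cells_make_only_their_niche_eligible(self):
        alpha = np.tile([1.0, 0, 0, 0], (5, 1))
        assert eligible_contexts(alpha) == [("niche", 0)]

    def test_half_half_cell_opens_the_interface(self):
        alpha = np.array([[0.5, 0.5, 0, 0]])
        ctxs = eligible_contexts(alpha)
        assert ("interface", 0, 1) in ctxs  # product 0.25 > 1/8
        assert ("niche", 0) not in ctxs  # 0.5 not strictly > 1/2

    def test_products_at_or_below_threshold_are_ineligible(self):
        alpha = np.array([[0.6, 0.2, 0.2, 0.0]])
        ctxs = eligible_contexts(alpha)
        # products 0.12, 0.12, 0.04 all <= 1/8
        assert all(c[0] != "interface" for c in ctxs)
        assert ("niche", 0) in ctxs


class TestSpearman:
    def test_monotone_is_one(self):
        rho, p = spearman_association([1, 2, 3, 4, 5], [0.1, 0.2, 0.3, 0.4, 0.5])
        assert rho == 1.0 and p == 0.0

    def test_printed_rank_instance(self):
        # ranks (1..5) vs (2,1,4,3,5): ρ = 1 − 6·4/(5·24) = 0.8
        rho, p = spearman_association([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_reversed_monotone(self):
        rho, _ = spearman_association([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == -1.0

    def test_constant_vector_recorded_as_null(self):
        rho, p = spearman_association([1.0, 1.0, 1.0, 1.0], [0.1, 0.2, 0.3, 0.4])
        assert rho == 0.0 and p == 1.0

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            spearman_association([1, 2, 3], [1, 2, 3])


class TestQValues:
    def test_all_ones_no_discoveries(self):
        q = qvalues(np.ones(200))
        assert (q >= 0.99).all()

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=150) ** 2
        np.testing.assert_allclose(qvalues(p, method="bh"), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_qvalue_no_larger_than_bh(self, rng):
        p = np.concatenate([rng.uniform(size=300), rng.uniform(size=50) * 1e-4])
        assert (qvalues(p) <= qvalues(p, method="bh") + 1e-12).all()

    def test_threshold_logic(self):
        # a strong correlation with q above the cut is still rejected
        assoc = pd.DataFrame(
            {
                "cell_type": ["A"] * 3,
                "marker": ["m1", "m2", "m3"],
                "context": [("niche", 0)] * 3,
                "context_label": ["n1"] * 3,
                "rho": [0.9, 0.9, 0.2],
                "p": [0.5, 1e-9, 1e-9],
                "n": [50] * 3,
            }
        )
        with pytest.warns(UserWarning, match="Benjamini"):
            disc = fdr_filter(assoc, q_max=0.01, rho_min=0.3)
        assert list(disc["marker"]) == ["m2"]  # m1 fails q, m3 fails rho


@pytest.fixture(scope="module")
def discoveries(synth_table, dense_bank):
    table, truth = synth_table
    weights = cell_niche_weights(table, dense_bank.B, r=25.0)
    assoc = associations(table, weights)
    return assoc, fdr_filter(assoc, q_max=0.01, rho_min=0.3), truth


class TestEndToEnd:
    def test_planted_associations_recovered(self, discoveries):
        assoc, disc, truth = discoveries
        hits = 0
        for _, row in truth.iterrows():
            found = disc[
                (disc["cell_type"] == row["cell_type"])
                & (disc["marker"] == row["marker"])
                & (disc["context"] == row["context"])
            ]
            hits += int(len(found) > 0)
        assert hits == len(truth)

    def test_null_marker_yields_no_discovery(self, discoveries):
        _, disc, _ = discoveries
        assert (disc["marker"] != "m_null").all()

    def test_rank_based_invariance_to_monotone_transform(self, synth_table, dense_bank):
        table, _ = synth_table
        weights = cell_niche_weights(table, dense_bank.B, r=25.0)
        a1 = associations(table, weights, markers=["m_tls"])
        warped = table.subset(np.ones(table.n_cells, dtype=bool))
        warped.cells["m_tls"] = np.exp(3.0 * warped.cells["m_tls"])  # strictly monotone
        a2 = associations(warped, weights, markers=["m_tls"])
        np.testing.assert_allclose(a1["rho"], a2["rho"], atol=1e-12)


class TestExclusions:
    @pytest.fixture
    def assoc(self):
        return pd.DataFrame(
            {
                "cell_type": ["Treg", "Treg", "NK"],
                "marker": ["Keratin6", "p53", "p53"],
                "context": [("niche", 0), ("interface", 0, 2), ("niche", 3)],
                "context_label": ["cancer", "cancerxinflammatory", "TLS"],
                "rho": [0.5, 0.6, 0.4],
                "p": [1e-5, 1e-6, 1e-4],
            }
        )

    def test_exclusion_drops_niche_and_its_interfaces(self, assoc):
        out = apply_marker_exclusions(
            assoc, [{"marker": "Keratin6", "niche": "cancer"}, {"marker": "p53", "niche": "cancer"}]
        )
        assert list(out["marker"]) == ["p53"]
        assert list(out["context_label"]) == ["TLS"]

    def test_empty_list_is_identity(self, assoc):
        pd.testing.assert_frame_equal(apply_marker_exclusions(assoc, []), assoc)

    def test_unknown_marker_warns(self, assoc):
        with pytest.warns(UserWarning, match="unknown marker"):
            out = apply_marker_exclusions(assoc, [{"marker": "nope", "niche": "cancer"}])
        assert len(out) == len(assoc)


class TestArchitecture:
    def make(self, rows):
        return pd.DataFrame(
            rows, columns=["cell_type", "marker", "context", "context_label", "rho", "q"]
        )

    def test_interface_with_larger_rho_wins(self):
        disc = self.make(
            [
                ("T", "m", ("niche", 0), "A", 0.5, 1e-3),
                ("T", "m", ("interface", 0, 1), "AxB", 0.6, 1e-3),
            ]
        )
        table = summarize_architecture(disc).table
        assert list(table["context_label"]) == ["AxB"]

    def test_niche_with_larger_rho_removes_interface(self):
        disc = self.make(
            [
                ("T", "m", ("niche", 0), "A", 0.45, 1e-3),
                ("T", "m", ("interface", 0, 1), "AxB", 0.4, 1e-3),
            ]
        )
        table = summarize_architecture(disc).table
        assert list(table["context_label"]) == ["A"]

    def test_single_context_retained(self):
        disc = self.make([("T", "m", ("niche", 2), "C", 0.5, 1e-3)])
        assert len(summarize_architecture(disc).table) == 1

    def test_tie_keeps_niche(self):
        disc = self.make(
            [
                ("T", "m", ("niche", 0), "A", 0.5, 1e-3),
                ("T", "m", ("interface", 0, 1), "AxB", 0.5, 1e-3),
            ]
        )
        with pytest.warns(UserWarning, match="tie"):
            table = summarize_architecture(disc).table
        assert list(table["context_label"]) == ["A"]

    def test_unrelated_contexts_untouched(self):
        disc = self.make(
            [
                ("T", "m", ("niche", 0), "A", 0.5, 1e-3),
                ("T", "m", ("interface", 1, 2), "BxC", 0.9, 1e-3),
            ]
        )
        assert len(summarize_architecture(disc).table) == 2


class TestRobustPresence:
    def test_mean_over_sd_rule(self):
        comp = np.zeros((200, 2))
        comp[:, 0] = np.random.default_rng(0).normal(5, 0.8, size=200).clip(0)  # reported
        comp[:, 1] = np.random.default_rng(1).normal(1, 2.0, size=200).clip(0)  # too noisy?
        alpha = np.random.default_rng(2).dirichlet(np.ones(3), size=200)

        class C:
            pass

        c = C()
        c.comp = comp
        c.cell_types = ["steady", "noisy"]
        out = robust_cell_types(c, alpha, 0, top_fraction=0.05)
        assert "steady" in out

    def test_all_zero_not_reported(self):
        class C:
            comp = np.zeros((100, 1))
            cell_types = ["empty"]

        assert robust_cell_types(C, np.ones((100, 1)), 0) == []

    def test_constant_positive_reported(self):
        class C:
            comp = np.ones((100, 1))
            cell_types = ["flat"]

        assert robust_cell_types(C, np.ones((100, 1)), 0) == ["flat"]


class TestContribution:
    def test_sum_of_squares(self):
        mat = pd.DataFrame([[0.3, -0.4], [0.0, 0.0]], index=["a", "b"])
        out = niche_contribution(mat)
        assert out["a"] == pytest.approx(0.25)
        assert out["b"] == 0.0

    def test_matrix_includes_zeros_for_untested(self):
        assoc = pd.DataFrame(
            {
                "cell_type": ["T", "T"],
                "marker": ["m1", "m2"],
                "context": [("niche", 0), ("niche", 1)],
                "context_label": ["A", "B"],
                "rho": [0.5, 0.2],
            }
        )
        mat = rho_matrix(assoc)
        assert mat.loc["A", "T:m2"] == 0.0


class TestPhenotypeClusters:
    def test_niche_coded_markers_predict_their_niche(self, rng):
        n, p = 300, 3
        member = rng.integers(0, p, size=n)
        alpha = np.full((n, p), 0.1)
        alpha[np.arange(n), member] = 0.8
        alpha /= alpha.sum(axis=1, keepdims=True)
        markers = pd.DataFrame(
            {f"mk{i}": (member == i).astype(float) + rng.normal(0, 0.05, n) for i in range(p)}
        )
        res = phenotype_clusters(markers, alpha, k=p)
        best = res.cluster_metrics.groupby("niche")[["sensitivity", "specificity"]].max()
        assert (best["sensitivity"] > 0.95).all()
        assert (best["specificity"] > 0.95).all()
        assert all(a > 0.95 for a in res.predictor_auc.values())

    def test_random_markers_near_chance(self, rng):
        n = 400
        alpha = rng.dirichlet(np.ones(3) * 0.3, size=n)
        markers = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"m{i}" for i in range(5)])
        res = phenotype_clusters(markers, alpha, k=5)
        for auc in res.predictor_auc.values():
            if not np.isnan(auc):
                assert abs(auc - 0.5) < 0.12

    def test_singleton_clusters_limit(self, rng):
        n = 30
        alpha = np.tile([0.6, 0.2, 0.2], (n, 1))
        markers = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        res = phenotype_clusters(markers, alpha, k=n)
        grp = res.cluster_metrics[res.cluster_metrics["niche"] == "niche_1"]
        assert (grp["sensitivity"] <= 1 / n + 1e-9).all()  # prevalent niche, one cell each

    def test_k_exceeding_cells_errors(self, rng):
        with pytest.raises(ValueError):
            phenotype_clusters(pd.DataFrame(rng.normal(size=(5, 2))), np.ones((5, 1)), k=10)
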