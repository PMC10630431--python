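"""Cross-scale analysis: incidence maps, macro simplex, dissection, containment."""

import numpy as np
import pandas as pd
import pytest

from nichescape import (
    build_incidence,
    default_niche_bank,
    dissect_endpoint,
    init_field,
    macro_simplex_fit,
    niche_prevalence,
    project_composition,
    simplex_containment_check,
    simulate_tissue,
)


class TestIncidence:
    def test_two_fine_types_merge_into_one_shared(self):
        im = build_incidence(
            [("Tumor", "Epithelial cells"), ("keratin-positive tumor", "Epithelial cells")],
            ["Tumor", "keratin-positive tumor", "CD8T"],
            ["Epithelial cells", "CD8T"],
            shared_names={"Epithelial cells": "Cancer"},
            unmatched="drop",
        )
        # the coarser CyTOF column absorbs both MIBI tumor types
        assert "Cancer" in im.projector_a.columns
        assert im.projector_a.loc["Tumor", "Cancer"] == 1
        assert im.projector_a.loc["keratin-positive tumor", "Cancer"] == 1

    def test_bijective_vocabulary_is_relabelling(self):
        im = build_incidence([("A", "a"), ("B", "b")], ["A", "B"], ["a", "b"])
        X = pd.DataFrame([[0.3, 0.7]], columns=["A", "B"])
        Y = project_composition(X, im.projector_a)
        np.testing.assert_allclose(Y.to_numpy(), [[0.3, 0.7]])

    def test_unmatched_other_pools(self):
        im = build_incidence([("A", "a")], ["A", "Z"], ["a"], unmatched="other")
        X = pd.DataFrame([[0.6, 0.4]], columns=["A", "Z"])
        Y = project_composition(X, im.projector_a)
        assert Y.iloc[0].sum() == pytest.approx(1.0)
        assert Y.loc[0, "other"] == pytest.approx(0.4)

    def test_unknown_type_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            build_incidence([("A", "zzz")], ["A"], ["a"])

    def test_projection_preserves_row_sums(self):
        im = build_incidence(
            [("A", "a"), ("B", "a"), ("C", "c")], ["A", "B", "C"], ["a", "c"]
        )
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.dirichlet(np.ones(3), size=8), columns=["A", "B", "C"])
        Y = project_composition(X, im.projector_a)
        np.testing.assert_allclose(Y.sum(axis=1), 1.0, atol=1e-12)

    def test_projection_dimension_mismatch(self):
        im = build_incidence([("A", "a")], ["A"], ["a"])
        with pytest.raises(ValueError):
            project_composition(pd.DataFrame([[1.0]], columns=["B"]), im.projector_a)


def planted_macro(rng, n=60, noise=0.0):
    bank = default_niche_bank()
    B = bank.B / bank.B.sum(axis=0, keepdims=True)  # proportions per niche
    theta = rng.dirichlet(np.ones(4) * 0.5, size=n)
    theta[:4] = np.eye(4)  # endpoint samples present
    C = theta @ B.T + rng.normal(scale=noise, size=(n, B.shape[0]))
    return pd.DataFrame(C, columns=bank.cell_types), theta, B


class TestMacroFit:
    def test_recovers_planted_theta(self, rng):
        C, theta, _ = planted_macro(rng)
        model = macro_simplex_fit(C, 4, restarts=10, seed=0)
        # match fitted endpoints to planted ones by best correlation of θ
        got = model.theta.to_numpy()
        perm = [int(np.argmax([np.corrcoef(theta[:, j], got[:, k])[0, 1] for k in range(4)])) for j in range(4)]
        assert sorted(perm) == [0, 1, 2, 3]
        np.testing.assert_allclose(got[:, perm], theta, atol=0.02)

    def test_endpoint_sample_is_one_hot(self, rng):
        C, theta, _ = planted_macro(rng)
        model = macro_simplex_fit(C, 4, restarts=10, seed=0)
        got = model.theta.to_numpy()[:4]
        assert (got.max(axis=1) > 0.98).all()

    def test_theta_rows_on_simplex(self, rng):
        C, _, _ = planted_macro(rng, noise=0.01)
        model = macro_simplex_fit(C, 4, restarts=5, seed=0)
        t = model.theta.to_numpy()
        assert (t >= 0).all()
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-9)

    def test_needs_enough_samples(self, rng):
        C, _, _ = planted_macro(rng)
        with pytest.raises(ValueError):
            macro_simplex_fit(C.iloc[:3], 4)


class TestDissect:
    def test_gamma_renormalisation_arithmetic(self, rng):
        C, _, _ = planted_macro(rng)
        model = macro_simplex_fit(C, 4, restarts=5, seed=0)
        model.theta.iloc[0] = [0.2, 0.2, 0.5, 0.1]
        C_d, discarded = dissect_endpoint(model, 2)
        theta = np.array([0.2, 0.2, 0.1]) / 0.5
        b = model.endpoints.to_numpy() - model.mean.to_numpy()[:, None]
        expected = (
            np.delete(b, 2, axis=1) @ theta
            + model.residual.iloc[0].to_numpy()
            + model.mean.to_numpy()
        )
        np.testing.assert_allclose(C_d.iloc[0].to_numpy(), expected, atol=1e-12)
        assert not discarded.iloc[0]

    def test_zero_weight_dissection_is_identity(self, rng):
        C, _, _ = planted_macro(rng)
        model = macro_simplex_fit(C, 4, restarts=5, seed=0)
        pure = model.theta.to_numpy()[:, 2] < 1e-9
        assert pure.any()
        C_d, _ = dissect_endpoint(model, 2)
        np.testing.assert_allclose(
            C_d.to_numpy()[pure], C.to_numpy()[pure], atol=1e-6
        )

    def test_dominant_endpoint_discarded(self, rng):
        C, _, _ = planted_macro(rng)
        model = macro_simplex_fit(C, 4, restarts=5, seed=0)
        model.theta.iloc[0] = [0.1, 0.2, 0.6, 0.1]
        C_d, discarded = dissect_endpoint(model, 2, max_weight=0.5)
        assert discarded.iloc[0]
        assert C_d.iloc[0].isna().all()

    def test_refit_recovers_gamma(self, rng):
        # dissecting then refitting θ on the remaining endpoints gives γ
        C, theta, B = planted_macro(rng)
        model = macro_simplex_fit(C, 4, restarts=10, seed=0)
        C_d, discarded = dissect_endpoint(model, 1)
        keep = ~discarded
        rest = np.delete(model.endpoints.to_numpy(), 1, axis=1)
        chk = simplex_containment_check(C_d[keep], rest, tol=1e-6)
        th = model.theta.to_numpy()[keep.to_numpy()]
        gamma = np.delete(th, 1, axis=1) / (th.sum(axis=1) - th[:, 1])[:, None]
        got = chk[[f"theta_{k}" for k in (1, 2, 3)]].to_numpy()
        np.testing.assert_allclose(got, gamma, atol=1e-5)


class TestContainment:
    def test_exact_mixture_residual_zero(self, rng):
        C, theta, B = planted_macro(rng)
        chk = simplex_containment_check(C, B, tol=1e-9)
        assert chk["contained"].all()
        np.testing.assert_allclose(chk["residual"], 0.0, atol=1e-9)

    @staticmethod
    def brute_force_distance(B, c, step=0.005):
        """Distance from c to the simplex spanned by B's columns (dense grid)."""
        g = np.arange(0, 1 + step / 2, step)
        a1, a2 = np.meshgrid(g, g, indexing="ij")
        keep = a1 + a2 <= 1 + 1e-12
        alpha = np.column_stack([a1[keep], a2[keep], 1 - a1[keep] - a2[keep]])
        d = np.linalg.norm(B @ alpha.T - c[:, None], axis=0)
        return d.min()

    def test_outside_point_distance_matches_grid_oracle(self, rng):
        brute_force_distance = self.brute_force_distance
        B = rng.uniform(0, 1, size=(3, 3))
        c = B.mean(axis=1) + np.array([0.8, -0.2, 0.1])
        chk = simplex_containment_check(pd.DataFrame([c]), B, tol=1e-9)
        assert chk["residual"].iloc[0] > 0
        assert chk["residual"].iloc[0] == pytest.approx(
            brute_force_distance(B, c), abs=1e-2
        )

    def test_zero_tolerance_only_exact(self, rng):
        C, _, B = planted_macro(rng, noise=1e-3)
        chk = simplex_containment_check(C, B, tol=0.0)
        assert not chk["contained"].all()

    def test_spatial_means_of_simulated_fields_lie_in_simplex(self, bank):
        # the macroscopic composition C = B·<α> of any tissue built from
        # the niches must fall inside the niche simplex
        for seed in (0, 1):
            field = simulate_tissue(init_field(4, 0.2, seed=seed))
            theta = niche_prevalence(field)
            C = pd.DataFrame([bank.B @ theta], columns=bank.cell_types)
            chk = simplex_containment_check(C, bank.B, tol=1e-9)
            assert chk["contained"].iloc[0]
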