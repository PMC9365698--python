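"""Tests for the mass-action connectivity model."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import fsolve

from cytolink.interactome import InteractionNetwork
from cytolink.kinetics import (
    CellGeometry,
    ModelConfig,
    bound_density,
    cell_pair_affinity,
    counts_to_density,
    integrate_doublets,
    kd_to_2d,
    merge_subtypes,
    model_interaction_scores,
    perturb_protein,
    rank_and_compare,
)


class TestDensity:
    def test_zero_copies(self):
        assert counts_to_density(0.0, 5.0) == 0.0

    def test_hand_evaluation(self):
        assert counts_to_density(10_000, 5.0) == pytest.approx(10_000 / (4 * np.pi * 25))
        assert counts_to_density(10_000, 5.0) == pytest.approx(31.83, abs=0.01)

    def test_radius_scaling(self):
        assert counts_to_density(100, 10.0) == pytest.approx(counts_to_density(100, 5.0) / 4)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            counts_to_density(1.0, 0.0)
        with pytest.raises(ValueError):
            counts_to_density(-1.0, 1.0)


class TestMergeSubtypes:
    def test_identity_single_subtype(self):
        expr = pd.DataFrame({"P": [7.0]}, index=["sub"])
        table = pd.DataFrame({"subtype": ["sub"], "parent": ["par"], "proportion": [1.0]})
        assert merge_subtypes(expr, table).loc["par", "P"] == pytest.approx(7.0)

    def test_even_split(self):
        expr = pd.DataFrame({"P": [10.0, 30.0]}, index=["a", "b"])
        table = pd.DataFrame(
            {"subtype": ["a", "b"], "parent": ["par"] * 2, "proportion": [0.5, 0.5]}
        )
        assert merge_subtypes(expr, table).loc["par", "P"] == pytest.approx(20.0)

    def test_renormalization_warns(self):
        expr = pd.DataFrame({"P": [10.0, 30.0]}, index=["a", "b"])
        table = pd.DataFrame(
            {"subtype": ["a", "b"], "parent": ["par"] * 2, "proportion": [0.4, 0.4]}
        )
        with pytest.warns(UserWarning):
            merged = merge_subtypes(expr, table)
        assert merged.loc["par", "P"] == pytest.approx(20.0)


class TestBoundDensity:
    def test_kd_conversion_scale(self, model_config):
        # 1 uM at h = 0.01 um is ~6 molecules/um^2
        assert kd_to_2d(1e-6, model_config) == pytest.approx(6.022, abs=0.01)

    def test_half_saturation(self, model_config):
        k2d = kd_to_2d(1e-6, model_config)
        b = bound_density(10.0, k2d, 1e-6, model_config)
        # symmetrized average: forward term is exactly rho_rec / 2
        fwd = 10.0 * k2d / (k2d + k2d)
        rev = k2d * 10.0 / (k2d + 10.0)
        assert b == pytest.approx(0.5 * (fwd + rev))
        # pure role assignment identity, checked directly on one term
        assert fwd == pytest.approx(10.0 / 2)

    def test_saturation_limit(self, model_config):
        # receptor side saturates to rho_rec in the forward assignment
        fwd = 10.0 * 1e9 / (kd_to_2d(1e-6, model_config) + 1e9)
        assert fwd == pytest.approx(10.0, rel=1e-6)
        # the symmetrized value is bounded by the larger saturation plateau
        b = bound_density(10.0, 1e9, 1e-6, model_config)
        assert b >= fwd / 2

    def test_no_binding_limit(self, model_config):
        assert bound_density(10.0, 10.0, 1e6, model_config) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_kd(self, model_config):
        with pytest.raises(ValueError):
            bound_density(1.0, 1.0, -1e-6, model_config)


class TestCellPairAffinity:
    def test_no_shared_edges_zero(self, toy_network, model_config):
        dens = pd.DataFrame({"A": [0.0, 0.0], "B": [0.0, 0.0], "C": [0.0, 0.0]}, index=["X", "Y"])
        aff = cell_pair_affinity(dens, toy_network, model_config)
        assert (aff.to_numpy() == 0).all()

    def test_single_edge_single_term(self, model_config):
        net = InteractionNetwork(
            edges=pd.DataFrame({"protein_a": ["A"], "protein_b": ["B"], "kd_molar": [1e-6]})
        )
        dens = pd.DataFrame({"A": [5.0, 0.0], "B": [0.0, 8.0]}, index=["X", "Y"])
        aff = cell_pair_affinity(dens, net, model_config)
        expected = bound_density(5.0, 8.0, 1e-6, model_config)
        assert aff.loc["X", "Y"] == pytest.approx(expected)
        assert aff.loc["X", "X"] == 0.0

    def test_adding_edge_never_decreases(self, model_config, rng):
        dens = pd.DataFrame(
            rng.uniform(0, 50, size=(3, 4)), index=["X", "Y", "Z"], columns=list("ABCD")
        )
        net1 = InteractionNetwork(
            edges=pd.DataFrame({"protein_a": ["A"], "protein_b": ["B"], "kd_molar": [1e-6]})
        )
        net2 = InteractionNetwork(
            edges=pd.DataFrame(
                {"protein_a": ["A", "C"], "protein_b": ["B", "D"], "kd_molar": [1e-6, 1e-5]}
            )
        )
        a1 = cell_pair_affinity(dens, net1, model_config)
        a2 = cell_pair_affinity(dens, net2, model_config)
        assert (a2.to_numpy() >= a1.to_numpy() - 1e-12).all()

    def test_symmetry(self, toy_network, model_config, rng):
        dens = pd.DataFrame(
            rng.uniform(0, 50, size=(3, 3)), index=["X", "Y", "Z"], columns=list("ABC")
        )
        aff = cell_pair_affinity(dens, toy_network, model_config)
        np.testing.assert_allclose(aff.to_numpy(), aff.to_numpy().T)

    def test_monotone_in_density_and_kd(self, model_config):
        net = InteractionNetwork(
            edges=pd.DataFrame({"protein_a": ["A"], "protein_b": ["B"], "kd_molar": [1e-6]})
        )
        dens = pd.DataFrame({"A": [5.0, 1.0], "B": [2.0, 8.0]}, index=["X", "Y"])
        base = cell_pair_affinity(dens, net, model_config).loc["X", "Y"]
        denser = dens.copy()
        denser.loc["X", "A"] *= 2
        assert cell_pair_affinity(denser, net, model_config).loc["X", "Y"] > base
        weaker = InteractionNetwork(
            edges=pd.DataFrame({"protein_a": ["A"], "protein_b": ["B"], "kd_molar": [1e-5]})
        )
        assert cell_pair_affinity(dens, weaker, model_config).loc["X", "Y"] < base


def two_type_fixed_point(t1, t2, kc, koff11, koff12, koff22):
    """Algebraic oracle for the 2-type equilibrium (solved numerically)."""

    def eqs(v):
        d11, d12, d22 = v
        f1 = t1 - d12 - 2 * d11
        f2 = t2 - d12 - 2 * d22
        return [
            0.5 * kc * f1 * f1 - koff11 * d11,
            kc * f1 * f2 - koff12 * d12,
            0.5 * kc * f2 * f2 - koff22 * d22,
        ]

    sol = fsolve(eqs, [t1 / 10, min(t1, t2) / 10, t2 / 10], full_output=False, xtol=1e-13)
    return np.asarray(sol)


class TestIntegrateDoublets:
    def _geometry(self, freqs):
        types = [f"c{i}" for i in range(len(freqs))]
        return CellGeometry(
            table=pd.DataFrame(
                {"radius_um": [5.0] * len(freqs), "blood_frequency": freqs},
                index=pd.Index(types, name="cell_type"),
            )
        )

    def test_uniform_affinity_product_structure(self, model_config):
        types = ["c0", "c1", "c2"]
        aff = pd.DataFrame(1.0, index=types, columns=types)
        geo = self._geometry([0.5, 0.3, 0.2])
        state = integrate_doublets(aff, geo, model_config)
        f = state.free
        d = state.doublets
        ratio_off = model_config.collision_rate / (
            model_config.dissociation_scale / 1.0
        )
        for i in range(3):
            for j in range(3):
                expected = ratio_off * f[i] * f[j] * (0.5 if i == j else 1.0)
                assert d[i, j] == pytest.approx(expected, rel=1e-6)

    def test_no_binding_limit(self):
        cfg = ModelConfig(dissociation_scale=1e12)
        types = ["c0", "c1"]
        aff = pd.DataFrame(1.0, index=types, columns=types)
        geo = self._geometry([0.6, 0.4])
        state = integrate_doublets(aff, geo, cfg)
        assert np.max(state.doublets) < 1e-10
        np.testing.assert_allclose(state.free, [0.6, 0.4], atol=1e-9)

    def test_two_type_matches_algebraic_oracle(self, model_config):
        aff = pd.DataFrame(
            [[2.0, 5.0], [5.0, 0.5]], index=["c0", "c1"], columns=["c0", "c1"]
        )
        geo = self._geometry([0.6, 0.4])
        state = integrate_doublets(aff, geo, model_config)
        kappa, kc = model_config.dissociation_scale, model_config.collision_rate
        d11, d12, d22 = two_type_fixed_point(
            0.6, 0.4, kc, kappa / 2.0, kappa / 5.0, kappa / 0.5
        )
        assert state.doublets[0, 0] == pytest.approx(d11, rel=1e-6)
        assert state.doublets[0, 1] == pytest.approx(d12, rel=1e-6)
        assert state.doublets[1, 1] == pytest.approx(d22, rel=1e-6)

    def test_conservation_and_detailed_balance(self, model_config, rng):
        for _ in range(10):
            n = int(rng.integers(2, 5))
            a = rng.uniform(0.1, 10.0, size=(n, n))
            a = (a + a.T) / 2
            freqs = rng.dirichlet(np.ones(n))
            aff = pd.DataFrame(a, index=[f"c{i}" for i in range(n)], columns=[f"c{i}" for i in range(n)])
            state = integrate_doublets(aff, self._geometry(freqs), model_config)
            assert state.conservation_error() < 1e-6
            assert state.residual < 1e-6

    def test_kappa_kc_ratio_invariance(self):
        types = ["c0", "c1"]
        aff = pd.DataFrame([[1.0, 3.0], [3.0, 2.0]], index=types, columns=types)
        geo = self._geometry([0.5, 0.5])
        s1 = integrate_doublets(aff, geo, ModelConfig(collision_rate=1.0, dissociation_scale=2.0))
        s2 = integrate_doublets(aff, geo, ModelConfig(collision_rate=10.0, dissociation_scale=20.0))
        np.testing.assert_allclose(s1.doublets, s2.doublets, rtol=1e-6)

    def test_frequency_rescaling_invariance_of_scores(self, model_config):
        types = ["c0", "c1", "c2"]
        aff = pd.DataFrame(
            [[1.0, 3.0, 0.2], [3.0, 2.0, 1.0], [0.2, 1.0, 0.5]],
            index=types, columns=types,
        )
        base = model_interaction_scores(
            integrate_doublets(aff, self._geometry([0.5, 0.3, 0.2]), model_config)
        )
        # rescale all frequencies by 2x and the off-rates to compensate the
        # quadratic collision term so the configuration is geometrically similar
        scaled = model_interaction_scores(
            integrate_doublets(
                aff,
                self._geometry([1.0, 0.6, 0.4]),
                ModelConfig(collision_rate=0.5, dissociation_scale=1.0),
            )
        )
        np.testing.assert_allclose(base.to_numpy(), scaled.to_numpy(), rtol=1e-5)


class TestModelScores:
    def test_uniform_system_equal_scores(self, model_config):
        types = ["c0", "c1", "c2"]
        aff = pd.DataFrame(1.0, index=types, columns=types)
        geo = CellGeometry(
            table=pd.DataFrame(
                {"radius_um": [5.0] * 3, "blood_frequency": [1 / 3] * 3},
                index=pd.Index(types, name="cell_type"),
            )
        )
        scores = model_interaction_scores(integrate_doublets(aff, geo, model_config))
        np.testing.assert_allclose(scores.to_numpy(), scores.to_numpy()[0, 0], rtol=1e-6)

    def test_dominant_pair_scores_highest(self, model_config):
        types = ["c0", "c1", "c2"]
        a = np.full((3, 3), 0.1)
        a[0, 1] = a[1, 0] = 50.0
        aff = pd.DataFrame(a, index=types, columns=types)
        geo = CellGeometry(
            table=pd.DataFrame(
                {"radius_um": [5.0] * 3, "blood_frequency": [1 / 3] * 3},
                index=pd.Index(types, name="cell_type"),
            )
        )
        scores = model_interaction_scores(integrate_doublets(aff, geo, model_config))
        off_diag = scores.where(~np.eye(3, dtype=bool))
        assert scores.loc["c0", "c1"] == off_diag.max().max()

    def test_hand_evaluated_formula(self):
        from cytolink.kinetics import ODEState

        types = ["a", "b", "c"]
        d = np.array([[0.01, 0.02, 0.0], [0.02, 0.005, 0.01], [0.0, 0.01, 0.0]])
        init = np.array([0.5, 0.3, 0.2])
        state = ODEState(cell_types=types, free=init, doublets=d, initial=init)
        scores = model_interaction_scores(state)
        total = 2.0 * (0.01 + 0.02 + 0.0 + 0.005 + 0.01 + 0.0)
        frac = init / init.sum()
        assert scores.loc["a", "b"] == pytest.approx(0.02 / (frac[0] * frac[1] * total))
        assert scores.loc["a", "a"] == pytest.approx(2 * 0.01 / (frac[0] ** 2 * total))


class TestPerturb:
    def _system(self):
        net = InteractionNetwork(
            edges=pd.DataFrame(
                {
                    "protein_a": ["A", "B", "C"],
                    "protein_b": ["B", "C", "C"],
                    "kd_molar": [1e-6, 1e-5, 5e-6],
                }
            )
        )
        expr = pd.DataFrame(
            {
                "A": [1e4, 1e3, 0.0],
                "B": [0.0, 2e4, 1e3],
                "C": [1e3, 0.0, 2e4],
                "D": [1e4, 1e4, 1e4],
            },
            index=["X", "Y", "Z"],
        )
        geo = CellGeometry(
            table=pd.DataFrame(
                {"radius_um": [4.0, 5.0, 6.0], "blood_frequency": [0.5, 0.3, 0.2]},
                index=pd.Index(["X", "Y", "Z"], name="cell_type"),
            )
        )
        return expr, net, geo

    def test_unlinked_protein_no_change(self, model_config):
        expr, net, geo = self._system()
        delta = perturb_protein(expr, net, geo, "D", model_config)
        np.testing.assert_allclose(delta.to_numpy(), 0.0, atol=1e-9)

    def test_unknown_protein_error(self, model_config):
        expr, net, geo = self._system()
        with pytest.raises(KeyError):
            perturb_protein(expr, net, geo, "NOPE", model_config)

    def test_knockout_never_increases_affinity(self, model_config, rng):
        for _ in range(20):
            proteins = list("ABCD")
            expr = pd.DataFrame(
                rng.uniform(0, 2e4, size=(3, 4)), index=["X", "Y", "Z"], columns=proteins
            )
            edges = pd.DataFrame(
                {
                    "protein_a": ["A", "B", "A"],
                    "protein_b": ["B", "C", "D"],
                    "kd_molar": 10.0 ** rng.uniform(-8, -4, size=3),
                }
            )
            net = InteractionNetwork(edges=edges)
            radii = np.array([4.0, 5.0, 6.0])
            dens = expr.div(4 * np.pi * radii**2, axis=0)
            base = cell_pair_affinity(dens, net, model_config)
            ko = dens.copy()
            ko["B"] = 0.0
            after = cell_pair_affinity(ko, net, model_config)
            assert (after.to_numpy() <= base.to_numpy() + 1e-12).all()


class TestRankAndCompare:
    def _frames(self, rng, n_types=6, agree=True, scale=1.0):
        types = [f"c{i}" for i in range(n_types)]
        pred = rng.uniform(0, 1, size=(n_types, n_types))
        pred = (pred + pred.T) / 2
        if agree:
            meas = pred * scale + rng.normal(0, 0.01, size=pred.shape)
            meas = (meas + meas.T) / 2
        else:
            meas = rng.uniform(0, 1, size=pred.shape)
            meas = (meas + meas.T) / 2
        mk = lambda m: pd.DataFrame(m, index=types, columns=types)
        return mk(pred), mk(meas)

    def test_perfect_agreement_significant(self, rng):
        predicted, measured = {}, {}
        for p in ["p1", "p2", "p3"]:
            pr, me = self._frames(rng, agree=True)
            predicted[p], measured[p] = pr, me
        res = rank_and_compare(predicted, measured)
        ok = res[res.status == "ok"]
        assert (ok.p_bh < 0.05).all()
        assert (ok.t > 0).all()

    def test_null_calibration(self, rng):
        pvals = []
        for rep in range(100):
            pr, me = self._frames(rng, agree=False)
            res = rank_and_compare({"p": pr}, {"p": me})
            pvals.append(res.iloc[0].p)
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.0 <= frac < 0.15  # roughly uniform null

    def test_eligibility_rule(self, rng):
        predicted, measured = {}, {}
        for i, p in enumerate(["big1", "big2", "big3", "tiny"]):
            pr, me = self._frames(rng)
            if p == "tiny":
                pr = pr * 1e-6
            predicted[p], measured[p] = pr, me
        res = rank_and_compare(predicted, measured)
        assert res.loc[res.protein == "tiny", "status"].iloc[0] == "ineligible"
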