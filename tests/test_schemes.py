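"""Scheme construction, generator matrices, dwell densities, constants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import patchkin as pk


class TestGenerator:
    def test_spontaneous_scheme_generator_entries(self, s1_generator):
        q = s1_generator.q
        names = s1_generator.state_order
        i = {n: k for k, n in enumerate(names)}
        assert q[i["C"], i["C_prime"]] == 3900.0
        assert q[i["C_prime"], i["C"]] == 7600.0
        assert q[i["C_prime"], i["O_prime"]] == 10000.0
        assert q[i["O_prime"], i["C_prime"]] == 310.0
        assert np.allclose(np.diag(q), [-3900.0, -17600.0, -310.0])

    def test_blocker_rate_scales_with_concentration(self):
        s2 = pk.scheme_preset("S2", blocker="ACh", variant="free")
        g = pk.build_generator(s2, {"ACh": 30.0})
        i = {n: k for k, n in enumerate(g.state_order)}
        assert g.q[i["O_prime"], i["O_blocked"]] == pytest.approx(170.0 * 30.0)

    def test_missing_ligand_concentration_raises(self):
        s2 = pk.scheme_preset("S2", blocker="ACh", variant="free")
        with pytest.raises(pk.ConfigurationError, match="ACh"):
            pk.build_generator(s2)

    @pytest.mark.parametrize("preset,kwargs,conc", [
        ("S1", {}, {}),
        ("S2", {"blocker": "QX-222"}, {"QX-222": 60.0}),
        ("S3", {}, {"ACh": 10.0}),
        ("S4", {"ach_concentration_uM": 30.0}, {"ACh": 30.0, "QX-222": 10.0}),
        ("S5", {}, {}),
    ])
    def test_rows_sum_to_zero_and_offdiag_nonneg(self, preset, kwargs, conc):
        g = pk.build_generator(pk.scheme_preset(preset, **kwargs), conc)
        assert np.allclose(g.q.sum(axis=1), 0.0, atol=1e-9 * np.abs(g.q).max())
        off = g.q[~np.eye(g.q.shape[0], dtype=bool)]
        assert np.all(off >= 0)

    @given(
        rates=st.lists(st.floats(1.0, 1e5), min_size=4, max_size=4),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_random_linear_scheme_generator_is_conservative(self, rates):
        scheme = pk.KineticScheme(
            "rand",
            (pk.State("C", "shut"), pk.State("C2", "shut"),
             pk.State("O", "open")),
            (
                pk.Transition("C", "C2", "a", rates[0]),
                pk.Transition("C2", "C", "b", rates[1]),
                pk.Transition("C2", "O", "c", rates[2]),
                pk.Transition("O", "C2", "d", rates[3]),
            ),
        )
        g = pk.build_generator(scheme)
        assert np.allclose(g.q.sum(axis=1), 0.0, atol=1e-9 * max(rates))


class TestSchemeValidation:
    def test_disconnected_scheme_rejected(self):
        with pytest.raises(pk.SchemeError, match="unreachable"):
            pk.KineticScheme(
                "bad",
                (pk.State("C", "shut"), pk.State("O", "open"),
                 pk.State("X", "shut")),
                (pk.Transition("C", "O", "a", 1.0),
                 pk.Transition("O", "C", "b", 1.0)),
            )

    def test_duplicate_edge_rejected(self):
        with pytest.raises(pk.SchemeError, match="duplicate"):
            pk.KineticScheme(
                "bad",
                (pk.State("C", "shut"), pk.State("O", "open")),
                (pk.Transition("C", "O", "a", 1.0),
                 pk.Transition("C", "O", "a2", 2.0),
                 pk.Transition("O", "C", "b", 1.0)),
            )

    def test_single_class_rejected(self):
        with pytest.raises(pk.SchemeError, match="open and one shut"):
            pk.KineticScheme(
                "bad",
                (pk.State("C", "shut"), pk.State("C2", "shut")),
                (pk.Transition("C", "C2", "a", 1.0),
                 pk.Transition("C2", "C", "b", 1.0)),
            )

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        s2 = pk.scheme_preset("S2", blocker="QX-222", variant="free")
        path = tmp_path / "scheme.yaml"
        path.write_text(yaml.safe_dump(s2.to_dict()))
        loaded = pk.KineticScheme.from_dict(yaml.safe_load(path.read_text()))
        assert loaded.state_names == s2.state_names
        assert loaded.rates() == s2.rates()
        assert loaded.ligands == {"QX-222"}


class TestEquilibrium:
    def test_symmetric_two_state(self):
        scheme = pk.KineticScheme(
            "sym",
            (pk.State("C", "shut"), pk.State("O", "open")),
            (pk.Transition("C", "O", "f", 50.0),
             pk.Transition("O", "C", "b", 50.0)),
        )
        pi = pk.equilibrium_occupancy(pk.build_generator(scheme))
        assert np.allclose(pi, [0.5, 0.5])

    def test_spontaneous_open_occupancy_matches_detailed_balance(
        self, s1_generator
    ):
        # chain product 1 : 3900/7600 : (3900/7600)(10000/310), normalised
        w = np.array([1.0, 3900 / 7600, (3900 / 7600) * (10000 / 310)])
        pi = pk.equilibrium_occupancy(s1_generator)
        assert np.allclose(pi, w / w.sum(), rtol=1e-9)
        assert pi[2] == pytest.approx(0.916, abs=5e-4)

    def test_stationarity_residual(self, s1_generator):
        pi = pk.equilibrium_occupancy(s1_generator)
        assert np.allclose(pi @ s1_generator.q, 0.0, atol=1e-9)

    def test_state_permutation_permutes_occupancy(self, s1):
        perm_states = (s1.states[2], s1.states[0], s1.states[1])
        perm = pk.KineticScheme("S1p", perm_states, s1.transitions)
        pi = pk.equilibrium_occupancy(pk.build_generator(s1))
        pi_p = pk.equilibrium_occupancy(pk.build_generator(perm))
        assert np.allclose(pi_p, pi[[2, 0, 1]])


class TestDwellDensity:
    def test_single_open_state_single_component(self, s1_generator):
        comps = pk.dwell_components(s1_generator, "open")
        assert len(comps) == 1
        area, tau = comps[0]
        assert area == pytest.approx(1.0)
        assert tau == pytest.approx(1.0 / 310.0)

    def test_shut_class_eigenvalues(self, s1_generator):
        # closed form on [[-3900, 3900], [7600, -17600]]
        comps = pk.dwell_components(s1_generator, "shut")
        taus = sorted(t for _, t in comps)
        assert taus[0] == pytest.approx(1.0 / 19500.0, rel=1e-12)
        assert taus[1] == pytest.approx(1.0 / 2000.0, rel=1e-12)
        assert sum(a for a, _ in comps) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("cls", ["open", "shut"])
    def test_density_normalised_and_mean_consistent(self, s1_generator, cls):
        total, _ = quad(
            lambda t: pk.ideal_dwell_density(s1_generator, cls, t), 0, 0.1,
            limit=200,
        )
        assert total == pytest.approx(1.0, abs=1e-6)
        mean_quad, _ = quad(
            lambda t: t * pk.ideal_dwell_density(s1_generator, cls, t), 0, 0.1,
            limit=200,
        )
        assert mean_quad == pytest.approx(pk.mean_dwell(s1_generator, cls),
                                          rel=1e-6)

    def test_multi_open_scheme_component_count(self):
        g = pk.build_generator(pk.scheme_preset("S5"))
        comps = pk.dwell_components(g, "open")
        assert len(comps) == 3
        assert sum(a for a, _ in comps) == pytest.approx(1.0, abs=1e-9)


class TestDerivedConstants:
    def test_gating_equilibrium(self):
        dc = pk.derived_constants({"beta_1": 10000.0, "alpha_1": 310.0})
        assert dc.Theta[1] == pytest.approx(32.26, abs=5e-3)

    def test_block_dissociation(self):
        dc = pk.derived_constants({"k_plusB": 95.0, "k_minusB": 1400.0})
        assert dc.K_B["blocker"] == pytest.approx(14.74, abs=5e-3)

    def test_identity_ratio(self):
        dc = pk.derived_constants({"k_plus1_prime": 5.0,
                                   "k_minus1_prime": 5.0})
        assert dc.K_prime[1] == 1.0

    def test_missing_partner_raises(self):
        with pytest.raises(pk.SchemeError, match="alpha_2"):
            pk.derived_constants({"beta_2": 10.0})

    def test_zero_denominator_raises(self):
        with pytest.raises(pk.SchemeError, match="denominator"):
            pk.derived_constants({"beta_1": 10.0, "alpha_1": 0.0})
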