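"""Normal-form machinery: non-resonance arithmetic, the replacement rule, the
two coordinate transformations, emergent G terms and frequency shifts."""

import numpy as np
import pytest
import sympy as sp

import hypernf as H
from hypernf.normalform import (
    NormalFormError,
    PairingAmbiguityError,
    coupling_dh0,
    default_elimination_tol,
)
from hypernf.polycore import Monomial, Polynomial, gamma_symbol


def mono(exps, coeff=1):
    return Monomial.make(exps, coeff)


EXP_OMEGAS = np.array([1.0, 2.53, 1.56, 2.53])


class TestResidualAndDenominator:
    @pytest.mark.parametrize(
        "exps, target, omegas, expected",
        [
            # z_k² z̄_ℓ in node k: (d₁−d₂−1)ω_k + (d₃−d₄)ω_ℓ = ω_k − ω_ℓ
            ({0: (2, 0), 1: (0, 1)}, 0, [1.3, 0.7], 0.6),
            # the Hopf cubic z|z|² is structurally resonant for every ω
            ({0: (2, 1)}, 0, [1.234], 0.0),
            ({0: (2, 1)}, 0, [99.0], 0.0),
            # experimental triplet detuning ω₁ − ω₂ + ω₃ = 0.03
            ({0: (2, 0), 1: (0, 1), 2: (1, 0)}, 0, EXP_OMEGAS, 0.03),
        ],
    )
    def test_residual_values(self, exps, target, omegas, expected):
        assert H.nonres_residual(mono(exps), target, omegas) == pytest.approx(expected)

    def test_denominator_patterns(self):
        g = [gamma_symbol(k) for k in range(2)]
        # z w̄ on edge (k, ℓ): denominator γ̄_ℓ
        d = H.homological_denominator(mono({0: (1, 0), 1: (0, 1)}), 0, g)
        assert sp.simplify(d - sp.conjugate(g[1])) == 0
        # z² w̄: γ_k + γ̄_ℓ
        d = H.homological_denominator(mono({0: (2, 0), 1: (0, 1)}), 0, g)
        assert sp.simplify(d - g[0] - sp.conjugate(g[1])) == 0
        # the linear term z_k is structurally resonant: zero denominator at λ=0
        lam0 = [1j * 1.0, 1j * 2.0]
        assert H.homological_denominator(mono({0: (1, 0)}), 0, lam0) == 0

    def test_imaginary_part_identity_random(self):
        """Im of the homological denominator at λ = 0 equals the frequency
        residual, exactly, for 1000 random monomials."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = rng.integers(1, 5)
            omegas = rng.uniform(-3, 3, n)
            gammas = 1j * omegas  # λ = 0
            exps = {
                int(j): (int(rng.integers(0, 4)), int(rng.integers(0, 4)))
                for j in rng.choice(n, size=rng.integers(1, n + 1), replace=False)
            }
            m = mono(exps)
            target = int(rng.integers(0, n))
            den = H.homological_denominator(m, target, gammas)
            assert complex(den).imag == pytest.approx(
                H.nonres_residual(m, target, omegas), abs=1e-12
            )


class TestTildeCoupling:
    def test_replacement_rule_pattern(self, ring4):
        ht = H.tilde_coupling(ring4.coupling, 0, 1, ring4.omegas, 1e-6)
        g1, g2 = gamma_symbol(0), gamma_symbol(1)
        expect = Polynomial.monomial(
            {0: (1, 0), 1: (0, 1)}, 1 / sp.conjugate(g2)
        ) + Polynomial.monomial({0: (2, 0), 1: (0, 1)}, 1 / (g1 + sp.conjugate(g2)))
        assert ht.equals(expect)

    def test_equal_frequencies_still_nonresonant(self):
        # h = z w̄ has residual −ω_ℓ, nonzero even for ω_k = ω_ℓ
        h = H.CouplingFunction.from_string("z*conj(w)")
        dyn = [H.NodeDynamics(0.0, 1.5), H.NodeDynamics(0.0, 1.5)]
        net = H.NetworkSpec(np.array([[0, 1], [1, 0]], float), 0.1, dyn, h)
        ht = H.tilde_coupling(net.coupling, 0, 1, net.omegas, 1e-6)
        assert len(ht) == 1

    def test_structurally_resonant_monomial_raises(self):
        # z_k z̄_k z_ℓ z̄_ℓ: (d₁−d₂−1, d₃−d₄) = (−1·0…) gives residual −ω_k… pick
        # z_k² z̄_k z_ℓ z̄_ℓ which has zero residual for every ω
        h = H.CouplingFunction(
            Polynomial.monomial({0: (2, 1), 1: (1, 1)})
        )
        dyn = [H.NodeDynamics(0.01, 1.0), H.NodeDynamics(0.01, 2.0)]
        net = H.NetworkSpec(np.array([[0, 1], [1, 0]], float), 0.1, dyn, h)
        with pytest.raises(H.ResonantMonomialError):
            H.tilde_coupling(net.coupling, 0, 1, net.omegas, 1e-6)


class TestFirstTransform:
    def test_ring_structure(self, ring4):
        P = H.build_first_transform(ring4)
        g = [gamma_symbol(k) for k in range(4)]
        for k in range(4):
            assert len(P[k]) == 4  # two monomials per ring neighbour
            prev, nxt = (k - 1) % 4, (k + 1) % 4
            got = {m.exponents: sp.together(m.coeff) for m in P[k]}
            # denominators γ̄_{k±1} and γ_k + γ̄_{k±1}
            for other in (prev, nxt):
                lin = Monomial.make({k: (1, 0), other: (0, 1)}).exponents
                assert sp.simplify(got[lin] - 1 / sp.conjugate(g[other])) == 0
                quad = Monomial.make({k: (2, 0), other: (0, 1)}).exponents
                assert sp.simplify(got[quad] - 1 / (g[k] + sp.conjugate(g[other]))) == 0

    def test_empty_adjacency(self):
        dyn = [H.NodeDynamics(0.01, 1.0), H.NodeDynamics(0.01, 2.0)]
        net = H.NetworkSpec(
            np.zeros((2, 2)), 0.1, dyn, H.CouplingFunction.from_string("z*conj(w)")
        )
        assert all(p.is_zero for p in H.build_first_transform(net))

    def test_path3_summation_structure(self, path3):
        P = H.build_first_transform(path3)
        assert len(P[1]) == 4  # middle node: both neighbours
        assert len(P[0]) == 2 and len(P[2]) == 2  # leaves: one each

    def test_resonant_network_aggregated_error(self):
        # ω₂ = 0 makes the z w̄ monomial resonant (residual −ω_ℓ = 0)
        dyn = [H.NodeDynamics(0.01, 1.0), H.NodeDynamics(0.01, 0.0)]
        net = H.NetworkSpec(
            np.array([[0, 1], [1, 0]], float),
            0.1,
            dyn,
            H.CouplingFunction.from_string("z*conj(w)"),
        )
        with pytest.raises(NormalFormError, match="non-resonance"):
            H.build_first_transform(net)


class TestGTerms:
    def test_2G_1_23_contains_eta_monomial(self, ring4):
        g = H.compute_G(ring4, 0, 1, 2, kind=2)
        g1, g2 = gamma_symbol(0), gamma_symbol(1)
        c = g.poly.coeff_of({0: (2, 0), 1: (0, 1), 2: (1, 0)})
        assert sp.simplify(c - 1 / (g1 + sp.conjugate(g2))) == 0

    def test_forbidden_term(self, ring4):
        with pytest.raises(H.ForbiddenTermError):
            H.compute_G(ring4, 0, 1, 3, kind=2)  # ²G₁^{2,4}: no walk 1←2←4

    def test_min_degree_three(self, ring4):
        _, gts = H.assemble_order2(ring4, return_g_terms=True)
        assert min(g.poly.min_degree() for g in gts) >= 3

    def test_degree_bookkeeping(self, ring4):
        # a degree-d term of h and degree-d̃ term of h̃ combine to d + d̃ − 1
        g = H.compute_G(ring4, 0, 1, 2, kind=2)
        assert g.poly.max_degree() == 3 + 3 - 1


class TestAssembly:
    def test_interaction_term_count_ring(self, ring4):
        for node in range(4):
            assert H.count_interaction_terms(ring4, node) == 16

    def test_isolated_node_zero_field(self):
        dyn = [H.NodeDynamics(0.01, 1.0)]
        net = H.NetworkSpec(
            np.zeros((1, 1)), 0.1, dyn, H.CouplingFunction.from_string("z*conj(w)")
        )
        assert all(p.is_zero for p in H.assemble_order2(net))

    def test_path3_second_sum_reaches_distance_two(self, path3):
        _, gts = H.assemble_order2(path3, return_g_terms=True)
        # node 1's only route to node 3 is the ²G chain through node 2
        node1 = [g for g in gts if g.target == 0]
        assert all(g.kind == 2 for g in node1 if 2 in g.pair)
        assert any(g.pair == (1, 2) and g.kind == 2 for g in node1)


class TestSecondTransform:
    def test_alpha_zero_and_no_coupling_gives_trivial_Q(self):
        dyn = [H.NodeDynamics(0.01, 1.0), H.NodeDynamics(0.01, 2.2)]
        net = H.NetworkSpec(
            np.zeros((2, 2)), 0.0, dyn, H.CouplingFunction.from_string("z*conj(w)")
        )
        P = H.build_first_transform(net)
        Q = H.build_second_transform(net, H.residual_order1(net, P))
        assert all(q.is_zero for q in Q)

    def test_resonant_residual_monomial_raises(self, ring4):
        bad = [Polynomial.monomial({0: (2, 1)})] + [Polynomial.zero()] * 3
        with pytest.raises(H.ResonantMonomialError):
            H.build_second_transform(ring4, bad)


class TestCancellation:
    def test_ring4_order_alpha_cancels(self, ring4):
        assert H.verify_alpha1_cancellation(ring4).is_zero

    def test_path3_order_alpha_cancels(self, path3):
        assert H.verify_alpha1_cancellation(path3).is_zero

    @pytest.mark.parametrize("seed", range(5))
    def test_random_nonresonant_3node_networks_cancel(self, seed):
        rng = np.random.default_rng(100 + seed)
        h = H.CouplingFunction.from_string("z*conj(w) + z^2*conj(w)")
        while True:
            omegas = np.round(rng.uniform(0.5, 3.0, 3), 2)
            A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
            if rng.random() < 0.5:
                A[0, 2] = A[2, 0] = 1.0
            dyn = [H.NodeDynamics(0.01, w) for w in omegas]
            net = H.NetworkSpec(A, 0.05, dyn, h)
            try:
                H.build_first_transform(net)
                break
            except NormalFormError:
                continue
        assert H.verify_alpha1_cancellation(net).is_zero


class TestFrequencyShift:
    def test_zero_linear_part_keeps_omegas(self):
        w = np.array([1.0, 2.0])
        assert np.allclose(H.shift_frequencies(np.zeros((2, 2)), w, 0.05), w)
        assert np.allclose(H.shift_frequencies(np.ones((2, 2)), w, 0.0), w)

    def test_two_node_shift_matches_eigendecomposition(self):
        w = np.array([1.0, 2.0])
        dh0 = np.array([[0, 1], [1, 0]], complex)
        a = 0.01
        got = H.shift_frequencies(dh0, w, a)
        vals = np.linalg.eigvals(1j * np.diag(w) + a * dh0)
        assert sorted(got) == pytest.approx(sorted(vals.imag))
        # correction is O(α²) for distinct frequencies
        assert np.max(np.abs(got - w)) < 5 * a**2

    def test_degenerate_frequencies_demand_pairing(self):
        with pytest.raises(PairingAmbiguityError):
            H.shift_frequencies(np.ones((2, 2)), np.array([1.0, 1.0]), 0.01)

    def test_antilinear_linear_part_rejected(self):
        h = H.CouplingFunction.from_string("conj(w) + z^2*conj(w)")
        dyn = [H.NodeDynamics(0.01, 1.0), H.NodeDynamics(0.01, 2.0)]
        net = H.NetworkSpec(np.array([[0, 1], [1, 0]], float), 0.1, dyn, h)
        with pytest.raises(NormalFormError, match="antilinear"):
            coupling_dh0(net)


class TestOrchestration:
    def test_alpha_zero_identity(self):
        net = H.fixture("ring4", alpha=0.0)
        res = H.normal_form(net)
        # transformations exist but the equation carries no interaction at α=0
        assert res.metadata["sign_convention"] == "all-minus"
        assert all(len(p) > 0 for p in res.P)  # P is α-independent by design

    def test_ledger_complete_and_consistent(self, ring4_nf):
        tol = ring4_nf.metadata["filter_tol"]
        for e in ring4_nf.ledger:
            if e.action in ("eliminated", "eliminated-residual"):
                assert e.denominator is not None
                assert abs(e.residual) > ring4_nf.metadata["tol"]
            elif e.action == "retained-resonant":
                assert abs(e.residual) <= tol
            else:
                assert e.action == "discarded-fast"
                assert abs(e.residual) > tol

    def test_generic_frequencies_have_empty_resonant_set(self):
        net = H.fixture("ring4", omegas=(1.0, 2.71, 1.414, 3.33))
        res = H.normal_form(net)
        assert not [e for e in res.ledger if e.action == "retained-resonant"]

    def test_linear_part_shifts_frequencies_and_is_not_eliminated(self):
        h = H.CouplingFunction.from_string("w + z^2*conj(w)", linear_mode="shift")
        dyn = [H.NodeDynamics(0.01, 1.0), H.NodeDynamics(0.01, 2.2)]
        net = H.NetworkSpec(np.array([[0, 1], [1, 0]], float), 0.05, dyn, h)
        res = H.normal_form(net)
        assert not np.allclose(res.shifted_omegas, net.omegas)
        assert np.max(np.abs(res.shifted_omegas - net.omegas)) < 0.01  # O(α²)
        # only the nonlinear monomial was removed by the first transformation
        for k in range(2):
            assert all(m.degree >= 2 for m in res.P[k])

    def test_json_report_round_trip(self, ring4_nf):
        import json

        d = ring4_nf.to_json_dict()
        blob = json.dumps(d)
        back = json.loads(blob)
        assert back["n"] == 4
        assert back["metadata"]["sign_convention"] == "all-minus"
        assert len(back["ledger"]) == len(ring4_nf.ledger)

    def test_self_loop_rejected(self):
        dyn = [H.NodeDynamics(0.01, 1.0)]
        with pytest.raises(ValueError, match="[Ss]elf-loop"):
            H.NetworkSpec(
                np.ones((1, 1)), 0.1, dyn, H.CouplingFunction.from_string("z*conj(w)")
            )
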