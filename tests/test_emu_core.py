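import numpy as np
import pytest

from pepflux.emu_core import (
    EMU,
    CombinedEMU,
    CorrectionMatrix,
    correction_apply,
    emu_decompose,
    isotopomer_oracle,
    simulate_mdvs,
)
from pepflux.errors import DeadEMUError, UnreachableEMUError
from pepflux.mdv import mean_mass
from pepflux.model_io import parse_model
from pepflux.synthetic_data import sample_flux_profile

from conftest import toy1_profile


class TestDecomposition:
    def test_backward_trace_from_product(self, toy1):
        g = emu_decompose(toy1.network, [EMU("P", (1, 2))])
        internal = set(map(str, g.internal_emus()))
        leaves = set(map(str, g.substrates))
        assert {"P(1,2)", "C(1,2)"} <= internal
        assert leaves == {"A(1,2)", "A(2,3)"}

    def test_substrate_target_is_single_leaf(self, toy1):
        g = emu_decompose(toy1.network, [EMU("A", (1, 2, 3))])
        assert g.internal_emus() == [] and g.substrates == {EMU("A", (1, 2, 3))}
        assert g.graph.number_of_edges() == 0

    def test_condensation_creates_combined_node(self, toy1c):
        g = emu_decompose(toy1c.network, [EMU("E", (1, 2, 3))])
        combined = g.combined_nodes()
        assert len(combined) == 1
        assert combined[0].constituents == (EMU("C", (1, 2)), EMU("D", (1,)))

    def test_unreachable_target_raises(self):
        net = parse_model("[reactions]\nv1\tA (a) -> B (a)\t0\t0\t10\n")
        with pytest.raises(UnreachableEMUError, match="A"):
            emu_decompose(net, [EMU("B", (1,))])

    def test_size_stratification_is_respected(self, ecc1):
        g = emu_decompose(ecc1.network, sorted(set(ecc1.residue_map.values()), key=str))
        for e, prods in g.productions.items():
            for _fid, src in prods:
                if isinstance(src, CombinedEMU):
                    assert all(c.size < e.size for c in src.constituents)
                    assert src.size == e.size
                else:
                    assert src.size == e.size


class TestSimulation:
    def test_hand_traced_split_labeling(self, toy1, toy1_truth):
        """[1-13C] substrate: the B route carries the label into P, m=1 = v3."""
        g = emu_decompose(toy1.network, [EMU("P", (1, 2))])
        mdvs = simulate_mdvs(toy1.network, toy1_truth, g)
        assert np.allclose(mdvs[EMU("P", (1, 2))], [0.4, 0.6, 0.0], atol=1e-12)

    def test_unlabeled_substrate_gives_delta_mdvs(self, toy1):
        net = parse_model(toy1.model_text)
        net.substrate_labeling["A"] = {1: 0.0, 2: 0.0, 3: 0.0}
        g = emu_decompose(net, [EMU("P", (1, 2)), EMU("B", (1, 2, 3))])
        mdvs = simulate_mdvs(net, toy1_profile(0.3), g)
        for v in mdvs.values():
            assert v[0] == pytest.approx(1.0, abs=1e-12)

    def test_mixture_substrate_labeling(self, toy1):
        """50/50 unlabeled / fully labeled substrate is not positional: it is
        pinned through explicit substrate EMU MDVs and propagates as the
        two-component mixture computed by hand."""
        net = parse_model(toy1.model_text)
        net.substrate_labeling.clear()
        for pos in [(1,), (2,), (3,), (1, 2), (1, 3), (2, 3), (1, 2, 3)]:
            mix = np.zeros(len(pos) + 1)
            mix[0] = 0.5
            mix[-1] += 0.5
            net.substrate_emu_mdvs[("A", pos)] = mix
        g = emu_decompose(net, [EMU("P", (1, 2))])
        mdvs = simulate_mdvs(net, toy1_profile(0.6), g)
        # both routes deliver a 2-carbon fragment that is all-or-nothing labeled
        assert np.allclose(mdvs[EMU("P", (1, 2))], [0.5, 0.0, 0.5], atol=1e-12)

    def test_flux_scaling_invariance(self, toy1, toy1_truth):
        g = emu_decompose(toy1.network, [EMU("P", (1, 2)), EMU("B", (1, 3))])
        a = simulate_mdvs(toy1.network, toy1_truth, g)
        scaled = {k: 3.7 * v for k, v in toy1_truth.items()}
        b = simulate_mdvs(toy1.network, scaled, g)
        for e in a:
            assert np.allclose(a[e], b[e], atol=1e-12)

    def test_dead_emu_flagged(self, toy1):
        v = {"upt": 1.0, "v1": 0.0, "v2": 1.0, "v3": 0.0, "v4": 1.0, "co2_ex": 1.0}
        g = emu_decompose(toy1.network, [EMU("B", (1, 2, 3))])
        with pytest.raises(DeadEMUError, match="B"):
            simulate_mdvs(toy1.network, v, g)

    def test_mean_mass_conservation_at_converging_pool(self, toy1, toy1_truth):
        """Mean mass of C equals the flux-weighted mean mass of its producers."""
        net = toy1.network
        g = emu_decompose(net, [EMU("C", (1, 2)), EMU("B", (1, 2))])
        mdvs = simulate_mdvs(net, toy1_truth, g)
        m_c = mean_mass(mdvs[EMU("C", (1, 2))])
        m_from_v2 = mean_mass(net.substrate_emu_mdv("A", (2, 3)))
        m_from_v3 = mean_mass(mdvs[EMU("B", (1, 2))])
        v2, v3 = toy1_truth["v2"], toy1_truth["v3"]
        assert m_c == pytest.approx((v2 * m_from_v2 + v3 * m_from_v3) / (v2 + v3), abs=1e-12)


class TestIsotopomerOracle:
    def test_linear_pathway_conserves_substrate_mdv(self):
        net = parse_model(
            "[reactions]\n"
            "upt\t=> A\t0\t0\t10\n"
            "v1\tA (ab) -> B (ab)\t0\t0\t10\n"
            "v2\tB (ab) -> P (ba)\t0\t0\t10\n"
            "[substrate_labeling]\nA\t1\t0.7\nA\t2\t0.2\n"
            "[measured_fluxes]\nupt\t1.0\n"
        )
        v = {"upt": 1.0, "v1": 1.0, "v2": 1.0}
        orc = isotopomer_oracle(net, v)
        expected = np.convolve([0.3, 0.7], [0.8, 0.2])
        assert np.allclose(orc["P"], expected, atol=1e-12)

    def test_agrees_with_emu_simulation(self, toy1, toy1c):
        for fx in (toy1, toy1c):
            emus = sorted(set(fx.residue_map.values()), key=str)
            g = emu_decompose(fx.network, emus)
            for seed in range(10):
                v = sample_flux_profile(fx.network, seed=seed, burn=50)
                sim = simulate_mdvs(fx.network, v, g, on_dead="unlabeled")
                orc = isotopomer_oracle(fx.network, v, emus=emus)
                for e in emus:
                    assert np.max(np.abs(sim[e] - orc[e])) < 1e-8


class TestCorrection:
    def test_dummy_residue_identity(self):
        cm = CorrectionMatrix.identity()
        x = np.array([0.4, 0.6, 0.0])
        assert np.array_equal(correction_apply(x, cm), x)

    def test_empty_formula_is_identity(self):
        cm = CorrectionMatrix.from_formula("none", {}, traced_carbons=0)
        x = np.array([0.25, 0.75])
        assert np.allclose(correction_apply(x, cm), x, atol=1e-15)

    def test_glycine_m0_closed_form(self):
        """Unlabeled glycine: m=0 survival is the product of the heteroatom
        light-isotope probabilities, (1-aH)^5 (1-aN) (1-aO)^2."""
        cm = CorrectionMatrix.for_amino_acid("G")
        out_unnorm = cm.matrix(3) @ np.array([1.0, 0, 0, 0, 0, 0, 0])
        aH, aN, aO = 0.000115, 0.00364, 0.00038 + 0.00205
        expected = (1 - aH) ** 5 * (1 - aN) * (1 - aO) ** 2
        assert out_unnorm[0] == pytest.approx(expected, rel=1e-12)

    def test_lower_triangular_and_column_sums(self):
        for res in "GASMW":
            cm = CorrectionMatrix.for_amino_acid(res)
            n_raw = cm.expected_raw_len
            A = cm.matrix(n_raw)
            assert np.allclose(A, np.tril(A))
            assert np.all(A.sum(axis=0) <= 1 + 1e-9)

    def test_dimension_mismatch_raises(self):
        cm = CorrectionMatrix.for_amino_acid("G")  # expects length 3
        with pytest.raises(ValueError, match="length 3"):
            correction_apply(np.array([1.0, 0.0]), cm)
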