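import numpy as np
import pytest

from pepflux.emu_core import EMU
from pepflux.flux_fitting import FitConfig, FreeFluxSpace, fit_fluxes, flux_bounds
from pepflux.model_io import MeasurementSet, parse_model
from pepflux.peptide_labeling import Peptide, PeptidePanel, digest_proteome, select_panel
from pepflux.synthetic_data import generate_measurements, sample_flux_profile

from conftest import toy1_profile

CFG = FitConfig(starts=4, seed=0)


class TestFreeFluxSpace:
    def test_null_space_dimension_after_fixing_uptake(self, toy1):
        space = FreeFluxSpace(toy1.network)
        assert space.dim == 1
        v = space.profile(np.array([0.1]))
        toy1.network.check_steady_state(v)
        assert v["upt"] == pytest.approx(1.0, abs=1e-10)

    def test_infeasible_bounds_raise(self, toy1):
        from pepflux.errors import InfeasibleError

        net = parse_model(toy1.model_text.replace("upt\t1.0", "upt\t20.0"))
        with pytest.raises(InfeasibleError):
            FreeFluxSpace(net)


class TestFit:
    def test_noiseless_amino_acid_recovery(self, toy1, toy1_truth):
        meas = MeasurementSet({"A": (np.array([0.4, 0.6, 0.0]), np.full(3, 0.01))})
        fit = fit_fluxes(toy1.network, meas, residue_map=toy1.residue_map, config=CFG)
        assert fit.profile["v3"] == pytest.approx(0.6, abs=1e-3)
        assert fit.objective <= 1e-8

    def test_noiseless_peptide_recovery_through_convolution(self, toy1):
        rmap = {"P": EMU("P", (1, 2))}
        panel = PeptidePanel([Peptide("PP")])
        meas = MeasurementSet(
            {"PP": (np.array([0.16, 0.48, 0.36, 0.0, 0.0]), np.full(5, 0.01))},
            mode="peptide",
        )
        fit = fit_fluxes(toy1.network, meas, panel=panel, residue_map=rmap, config=CFG)
        assert fit.profile["v3"] == pytest.approx(0.6, abs=1e-3)
        assert fit.objective <= 1e-8

    def test_modes_agree_on_same_underlying_data(self, toy1, toy1_truth):
        aa_meas = generate_measurements(toy1.network, toy1_truth, toy1.residue_map)
        peps = digest_proteome(toy1.proteome_fasta)
        panel = select_panel(peps, 6, lengths=5, seed=0)
        pep_meas = generate_measurements(
            toy1.network, toy1_truth, toy1.residue_map, panel=panel
        )
        f_aa = fit_fluxes(toy1.network, aa_meas, residue_map=toy1.residue_map, config=CFG)
        f_pep = fit_fluxes(
            toy1.network, pep_meas, panel=panel, residue_map=toy1.residue_map, config=CFG
        )
        assert f_aa.profile["v3"] == pytest.approx(f_pep.profile["v3"], abs=1e-3)

    def test_random_truth_recovery(self, toy1):
        for seed in range(5):
            truth = sample_flux_profile(toy1.network, seed=seed, burn=100)
            meas = generate_measurements(toy1.network, truth, toy1.residue_map)
            fit = fit_fluxes(toy1.network, meas, residue_map=toy1.residue_map, config=CFG)
            assert fit.profile["v3"] == pytest.approx(truth["v3"], abs=1e-3)

    def test_inconsistent_target_reports_lack_of_fit(self, toy1):
        """Unlabeled P is impossible when the labeled-route flux is forced high."""
        text = toy1.model_text.replace("v3\tB (abc) -> C (ab) + CO2 (c)\t0\t0\t10",
                                       "v3\tB (abc) -> C (ab) + CO2 (c)\t0\t0.5\t10")
        net = parse_model(text)
        meas = MeasurementSet({"A": (np.array([1.0, 0.0, 0.0]), np.full(3, 0.01))})
        fit = fit_fluxes(net, meas, residue_map=toy1.residue_map, config=CFG)
        assert fit.objective > 1.0
        assert fit.profile["v3"] >= 0.5 - 1e-6


class TestBounds:
    def test_range_from_wide_error_bound(self, toy1):
        """P = [0.4, 0.6, 0] +- 0.05 and MDV(1) = v3 exactly: range [0.55, 0.65]."""
        meas = MeasurementSet({"A": (np.array([0.4, 0.6, 0.0]), np.full(3, 0.05))})
        fit = fit_fluxes(toy1.network, meas, residue_map=toy1.residue_map, config=CFG)
        b = flux_bounds(toy1.network, meas, fit, CFG, residue_map=toy1.residue_map)
        lo, hi = b.ranges["v3"]
        assert lo == pytest.approx(0.55, abs=1e-4)
        assert hi == pytest.approx(0.65, abs=1e-4)
        assert not b.failures

    def test_zero_error_bound_collapses_to_best_fit(self, toy1):
        meas = MeasurementSet({"A": (np.array([0.4, 0.6, 0.0]), np.zeros(3))})
        fit = fit_fluxes(toy1.network, meas, residue_map=toy1.residue_map, config=CFG)
        b = flux_bounds(toy1.network, meas, fit, CFG, residue_map=toy1.residue_map)
        for rid, (lo, hi) in b.ranges.items():
            assert hi - lo <= 1e-4

    def test_fully_measured_network_has_zero_widths(self, toy1):
        text = toy1.model_text.replace("upt\t1.0\t0.0", "upt\t1.0\t0.0\nv3\t0.6\t0.0")
        net = parse_model(text)
        meas = MeasurementSet({"A": (np.array([0.4, 0.6, 0.0]), np.full(3, 0.05))})
        fit = fit_fluxes(net, meas, residue_map=toy1.residue_map, config=CFG)
        b = flux_bounds(net, meas, fit, CFG, residue_map=toy1.residue_map)
        assert all(hi - lo <= 1e-9 for lo, hi in b.ranges.values())

    def test_more_measurements_never_widen_ranges(self, toy1, toy1_truth):
        peps = digest_proteome(toy1.proteome_fasta)
        panel = select_panel(peps, 3, lengths=5, seed=1)
        m1 = generate_measurements(toy1.network, toy1_truth, toy1.residue_map,
                                   panel=panel.prefix(1))
        m3 = generate_measurements(toy1.network, toy1_truth, toy1.residue_map, panel=panel)
        f1 = fit_fluxes(toy1.network, m1, panel=panel.prefix(1),
                        residue_map=toy1.residue_map, config=CFG)
        f3 = fit_fluxes(toy1.network, m3, panel=panel,
                        residue_map=toy1.residue_map, config=CFG)
        b1 = flux_bounds(toy1.network, m1, f1, CFG, residue_map=toy1.residue_map)
        b3 = flux_bounds(toy1.network, m3, f3, CFG, residue_map=toy1.residue_map)
        for rid in b1.ranges:
            w1 = b1.ranges[rid][1] - b1.ranges[rid][0]
            w3 = b3.ranges[rid][1] - b3.ranges[rid][0]
            assert w3 <= w1 + 1e-6
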