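import numpy as np
import pytest

from pepflux.community import (
    CommunityModel,
    Exchange,
    SpeciesSpec,
    _all_sub_emus,
    mixture_labeling,
    solve_community,
)
from pepflux.emu_core import EMU, emu_decompose, simulate_mdvs
from pepflux.errors import PepfluxError, TopologyError
from pepflux.flux_fitting import FitConfig, fit_fluxes
from pepflux.mdv import mean_mass
from pepflux.model_io import MeasurementSet, parse_model
from pepflux.peptide_labeling import digest_proteome, select_panel
from pepflux.synthetic_data import generate_measurements, simulate_amino_acid_mdvs

CFG = FitConfig(starts=4, seed=3)

DV_TRUTH = {"upt": 1.0, "r1": 0.7, "r2": 0.3, "r3": 0.7, "ac_ex": 1.0, "co2_ex": 1.0}
MM_TRUTH = {"upt2": 1.0, "s1": 0.5, "s2": 0.5, "s3": 0.25, "co2x_ex": 0.5}


def build_community(two_species, seed=0):
    """Ground-truth forward simulation: propagate exchange labeling, generate
    species-unique peptide measurements, then strip the propagated labeling so
    the solver must rediscover it."""
    dv = parse_model(two_species.model_texts["dv"])
    mm = parse_model(two_species.model_texts["mm"])
    rmaps = two_species.residue_maps
    graph = emu_decompose(dv, [EMU("Ac", p) for p in _all_sub_emus("Ac", 2)])
    ac = simulate_mdvs(dv, DV_TRUTH, graph)
    for e, mdv in ac.items():
        mm.substrate_emu_mdvs[("AcS", e.positions)] = mdv
    digests = {
        sp: [p.sequence for p in digest_proteome(two_species.proteomes[sp], species=sp)]
        for sp in ("dv", "mm")
    }
    pan_dv = select_panel(
        digest_proteome(two_species.proteomes["dv"], species="dv"),
        6, lengths=5, community=digests, seed=seed,
    )
    pan_mm = select_panel(
        digest_proteome(two_species.proteomes["mm"], species="mm"),
        6, lengths=5, community=digests, seed=seed,
    )
    meas_dv = generate_measurements(dv, DV_TRUTH, rmaps["dv"], panel=pan_dv)
    meas_mm = generate_measurements(mm, MM_TRUTH, rmaps["mm"], panel=pan_mm)
    mm.substrate_emu_mdvs.clear()
    cm = CommunityModel(
        species=[
            SpeciesSpec("dv", dv, pan_dv, meas_dv, rmaps["dv"]),
            SpeciesSpec("mm", mm, pan_mm, meas_mm, rmaps["mm"]),
        ],
        exchanges=[two_species.exchange],
    )
    return cm, ac


class TestMixtureLabeling:
    def test_even_mixture(self):
        out = mixture_labeling(
            [{"t": np.array([1.0, 0.0])}, {"t": np.array([0.0, 1.0])}], [0.5, 0.5]
        )
        assert np.allclose(out["t"], [0.5, 0.5])

    def test_degenerate_mixture_is_identity(self):
        a = {"t": np.array([0.2, 0.8])}
        out = mixture_labeling([a, {"t": np.array([1.0, 0.0])}], [1.0, 0.0])
        assert np.allclose(out["t"], a["t"])

    def test_bad_fraction_sum_rejected(self):
        with pytest.raises(PepfluxError, match="sum"):
            mixture_labeling([{"t": np.array([1.0])}] * 2, [0.6, 0.6])

    def test_average_labeling_is_not_average_flux(self, toy1c):
        """The flux->labeling map is nonlinear through the condensation
        product, so the bulk-averaged labeling of two populations is not
        attainable by any single profile: the fit shows a large lack of fit."""
        net = toy1c.network

        def prof(v3, v5):
            return {"upt": 1.0, "v1": v3, "v2": 1 - v3, "v3": v3,
                    "v4": 1 - v5, "v5": v5, "v6": v5, "co2_ex": 1 - v5}

        lab1 = simulate_amino_acid_mdvs(net, prof(0.2, 0.3), toy1c.residue_map)
        lab2 = simulate_amino_acid_mdvs(net, prof(0.8, 0.3), toy1c.residue_map)
        mix = mixture_labeling([lab1, lab2], [0.5, 0.5])
        meas = MeasurementSet(
            {t: (v / v.sum(), np.full(len(v), 0.01)) for t, v in mix.items()}
        )
        fit = fit_fluxes(net, meas, residue_map=toy1c.residue_map,
                         config=FitConfig(starts=6, seed=0))
        assert fit.objective > 1.0


class TestSolveCommunity:
    def test_chain_recovers_both_species(self, two_species):
        cm, ac_truth = build_community(two_species)
        res = solve_community(cm, CFG)
        assert res.order == ["dv", "mm"] and not res.blocked
        assert res.fits["dv"].profile["r1"] == pytest.approx(0.7, abs=1e-3)
        assert res.fits["mm"].profile["s1"] == pytest.approx(0.5, abs=1e-3)
        predicted = res.exchange_labeling[("dv", "Ac", (1, 2))]
        assert np.allclose(predicted, ac_truth[EMU("Ac", (1, 2))], atol=1e-3)

    def test_downstream_fit_reproduces_its_peptides(self, two_species):
        cm, _ = build_community(two_species)
        res = solve_community(cm, CFG)
        meas = cm.species_by_name("mm").measurements
        fitted = res.fits["mm"].fitted_mdvs
        for tid, (obs, err) in meas.entries.items():
            n = min(len(obs), len(fitted[tid]))
            assert np.all(np.abs(fitted[tid][:n] - obs[:n]) <= err[:n] + 1e-6)

    def test_carbon_conservation_end_to_end(self, two_species):
        """Labeled carbon entering the community equals labeled carbon leaving
        through sinks and secretions, at the fitted solution."""
        cm, _ = build_community(two_species)
        res = solve_community(cm, CFG)
        dv_net = cm.species_by_name("dv").network
        mm_net = cm.species_by_name("mm").network
        v_dv, v_mm = res.fits["dv"].profile, res.fits["mm"].profile

        def emu_mdv(net, v, met):
            c = net.carbon_count(met)
            g = emu_decompose(net, [EMU(met, tuple(range(1, c + 1)))])
            return simulate_mdvs(net, v, g, check_steady=False, on_dead="unlabeled")[
                EMU(met, tuple(range(1, c + 1)))
            ]

        label_in = v_dv["upt"] * mean_mass(dv_net.substrate_emu_mdv("Lac", (1, 2, 3)))
        # dv outputs: secreted Ac and exported CO2
        ac_m = mean_mass(emu_mdv(dv_net, v_dv, "Ac"))
        co2_m = mean_mass(emu_mdv(dv_net, v_dv, "CO2"))
        label_dv_out = v_dv["ac_ex"] * ac_m + v_dv["co2_ex"] * co2_m
        assert label_in == pytest.approx(label_dv_out, abs=1e-6)
        # mm consumes that Ac: sinks are M (via s1 and s3) and CO2x
        mm_net2 = parse_model(two_species.model_texts["mm"])
        for pos in _all_sub_emus("Ac", 2):
            mm_net2.substrate_emu_mdvs[("AcS", pos)] = res.exchange_labeling[
                ("dv", "Ac", pos)
            ]
        m_m = mean_mass(emu_mdv(mm_net2, v_mm, "M"))
        co2x_m = mean_mass(emu_mdv(mm_net2, v_mm, "CO2x"))
        m_flux = v_mm["s1"] + v_mm["s3"]
        label_mm_in = v_mm["upt2"] * ac_m
        label_mm_out = m_flux * m_m + v_mm["co2x_ex"] * co2x_m
        assert label_mm_in == pytest.approx(label_mm_out, abs=1e-6)

    def test_single_species_community_reduces_to_fit(self, two_species):
        cm, _ = build_community(two_species)
        solo = CommunityModel(species=[cm.species[0]], exchanges=[])
        res = solve_community(solo, CFG)
        spec = cm.species[0]
        direct = fit_fluxes(spec.network, spec.measurements, panel=spec.panel,
                            residue_map=spec.residue_map, config=CFG)
        for rid in spec.network.flux_ids:
            assert res.fits["dv"].profile[rid] == pytest.approx(
                direct.profile[rid], abs=1e-9
            )

    def test_shared_panel_peptide_rejected_before_solving(self, two_species):
        cm, _ = build_community(two_species)
        shared = cm.species[0].panel.peptides[0]
        bad_panel = cm.species[1].panel
        bad_panel.peptides.append(shared)
        with pytest.raises(PepfluxError, match="species-unique"):
            solve_community(cm, CFG)

    def test_cyclic_exchange_rejected(self, two_species):
        cm, _ = build_community(two_species)
        cm.exchanges.append(Exchange("mm", "CO2x", "dv", "CO2"))
        with pytest.raises(TopologyError, match="cyclic"):
            solve_community(cm, CFG)
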