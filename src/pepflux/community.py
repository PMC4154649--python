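"""Multi-species flux analysis.

Species-assignable peptides turn the community flux problem into a chain of
single-species problems: each species is fitted against its own peptide
measurements, with the labeling of its carbon sources given either by the
community substrate (for root species) or by the predicted labeling of
exchange metabolites secreted by already-solved upstream species.  This
requires the exchange topology to be acyclic — the solvable
"compartmentalizable" case; cyclic cross-feeding raises a clear error.

The module also provides the mixture-labeling construction that demonstrates
why naive averaging fails: because the labeling-to-flux map is nonlinear, the
fluxes fitted to the species-fraction-weighted average labeling are not the
average of the species' fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .emu_core import EMU
from .errors import PepfluxError, TopologyError
from .flux_fitting import FitConfig, FitResult, LabelingModel, fit_fluxes
from .model_io import MeasurementSet, Network
from .peptide_labeling import PeptidePanel


@dataclass
class SpeciesSpec:
    """One community member: model, species-unique panel, measurements, residue map."""

    name: str
    network: Network
    panel: PeptidePanel | None
    measurements: MeasurementSet
    residue_map: Mapping[str, EMU]


@dataclass(frozen=True)
class Exchange:
    """Metabolite handoff: ``producer`` secretes, ``consumer`` takes up.

    The metabolite may be named differently in the two species' models.
    """

    producer: str
    producer_metabolite: str
    consumer: str
    consumer_metabolite: str


@dataclass
class CommunityModel:
    species: list[SpeciesSpec]
    exchanges: list[Exchange] = field(default_factory=list)
    #: biomass fractions x_s, used only by :func:`mixture_labeling`
    fractions: Sequence[float] | None = None

    def species_by_name(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def validate(self):
        names = {s.name for s in self.species}
        for ex in self.exchanges:
            if ex.producer not in names or ex.consumer not in names:
                raise PepfluxError(f"exchange references unknown species: {ex}")
            cp = self.species_by_name(ex.producer).network.carbon_count(ex.producer_metabolite)
            cc = self.species_by_name(ex.consumer).network.carbon_count(ex.consumer_metabolite)
            if cp != cc:
                raise PepfluxError(
                    f"exchanged metabolite carbon counts disagree: "
                    f"{ex.producer_metabolite!r} ({cp}C) vs {ex.consumer_metabolite!r} ({cc}C)"
                )
        # peptide uniqueness across species panels
        seen: dict[str, str] = {}
        for s in self.species:
            if s.panel is None:
                continue
            for pep in s.panel:
                if pep.sequence in seen and seen[pep.sequence] != s.name:
                    raise PepfluxError(
                        f"peptide {pep.sequence!r} appears in panels of both "
                        f"{seen[pep.sequence]!r} and {s.name!r}; species-unique "
                        "panels are required"
                    )
                seen[pep.sequence] = s.name


def mixture_labeling(
    labelings: Sequence[Mapping[str, np.ndarray]],
    fractions: Sequence[float],
) -> dict[str, np.ndarray]:
    """Convex combination sum_s x_s f_s of congruent per-target MDV sets.

    This is what a bulk (species-blind) measurement of a community would see;
    fitting it does not recover the average flux profile because the
    labeling-to-flux map is nonlinear.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0):
        raise PepfluxError("species fractions must be non-negative")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise PepfluxError(f"species fractions sum to {fractions.sum():.12g}, not 1")
    if len(labelings) != len(fractions):
        raise PepfluxError("one fraction per labeling set required")
    keys = set(labelings[0])
    for lab in labelings[1:]:
        if set(lab) != keys:
            raise PepfluxError("labeling sets cover different targets")
    out: dict[str, np.ndarray] = {}
    for t in keys:
        vecs = [np.asarray(lab[t], dtype=float) for lab in labelings]
        n = max(len(v) for v in vecs)
        acc = np.zeros(n)
        for x, v in zip(fractions, vecs):
            acc[: len(v)] += x * v
        out[t] = acc
    return out


def _all_sub_emus(met: str, carbons: int) -> list[tuple[int, ...]]:
    subsets = []
    for mask in range(1, 2**carbons):
        subsets.append(tuple(p + 1 for p in range(carbons) if mask >> p & 1))
    return subsets


@dataclass
class CommunityResult:
    fits: dict[str, FitResult]
    #: predicted MDVs of every exchanged metabolite's EMUs, keyed by
    #: (producer species, metabolite, positions)
    exchange_labeling: dict[tuple[str, str, tuple[int, ...]], np.ndarray]
    order: list[str]
    blocked: dict[str, str] = field(default_factory=dict)


def solve_community(cm: CommunityModel, config: FitConfig = FitConfig()) -> CommunityResult:
    """Fit each species in exchange-topological order, propagating labeling.

    Root species use the community substrate labeling already present in their
    model; downstream species receive the predicted EMU MDVs of every
    exchanged metabolite as substrate labeling.  Upstream non-convergence
    marks dependents as blocked rather than failing the whole community.
    """
    cm.validate()
    g = nx.DiGraph()
    g.add_nodes_from(s.name for s in cm.species)
    for ex in cm.exchanges:
        g.add_edge(ex.producer, ex.consumer)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        raise TopologyError(
            "cyclic exchange topology: the iterative compartmentalized solver "
            "only supports acyclic metabolite handoffs"
        )
    fits: dict[str, FitResult] = {}
    blocked: dict[str, str] = {}
    exchange_labeling: dict[tuple[str, str, tuple[int, ...]], np.ndarray] = {}
    for name in order:
        spec = cm.species_by_name(name)
        upstream = [ex for ex in cm.exchanges if ex.consumer == name]
        bad = [ex.producer for ex in upstream if ex.producer in blocked or ex.producer not in fits]
        if bad:
            blocked[name] = f"upstream species {sorted(set(bad))} did not converge"
            continue
        net = spec.network
        for ex in upstream:
            carbons = net.carbon_count(ex.consumer_metabolite)
            for pos in _all_sub_emus(ex.producer_metabolite, carbons):
                key = (ex.producer, ex.producer_metabolite, pos)
                net.substrate_emu_mdvs[(ex.consumer_metabolite, pos)] = exchange_labeling[key]
        try:
            fit = fit_fluxes(
                net,
                spec.measurements,
                panel=spec.panel,
                residue_map=spec.residue_map,
                config=config,
            )
        except PepfluxError as exc:
            blocked[name] = str(exc)
            continue
        fits[name] = fit
        # predict labeling of everything this species secretes
        secretes = [ex for ex in cm.exchanges if ex.producer == name]
        if secretes:
            targets = []
            for ex in secretes:
                carbons = net.carbon_count(ex.producer_metabolite)
                targets.extend(
                    EMU(ex.producer_metabolite, pos)
                    for pos in _all_sub_emus(ex.producer_metabolite, carbons)
                )
            from .emu_core import emu_decompose, simulate_mdvs

            graph = emu_decompose(net, targets)
            mdvs = simulate_mdvs(net, fit.profile, graph, check_steady=False, on_dead="unlabeled")
            for t in targets:
                exchange_labeling[(name, t.metabolite, t.positions)] = mdvs[t]
    return CommunityResult(
        fits=fits, exchange_labeling=exchange_labeling, order=order, blocked=blocked
    )


__all__ = [
    "CommunityModel",
    "CommunityResult",
    "Exchange",
    "SpeciesSpec",
    "mixture_labeling",
    "solve_community",
]
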