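"""Synthetic study systems: toy networks, ground-truth fluxes, noisy data.

Every input the analysis modules need can be generated here: small
carbon-transition networks with known structure, uniformly sampled feasible
flux profiles, toy proteomes whose tryptic digests provide ample
composition-distinct peptides, and simulated amino-acid / peptide measurements
with multiplicative-relative uniform noise (MDV' = MDV * (1 + delta * r),
r ~ Uniform(-1, 1), at amplitudes delta of 0.05, 0.08 and 0.10 for the
degradation studies).

Fixtures
--------
``toy1``
    Three-carbon substrate A split over two routes (direct A -> C + CO2, or
    via B) that transfer different substrate carbons into the two-carbon
    product P; one free flux after fixing uptake at 1, so with [1-13C]
    substrate the m = 1 fraction of P equals the flux through the B route.
``toy1c``
    toy1 plus a condensation branch (C + D -> E) exercising combined EMUs.
``ecc1``
    A reduced central-carbon network (glycolysis-like split, an oxidative
    pentose-phosphate-like branch, a TCA-like cycle with anaplerosis, and two
    secretion/biomass drains; 14 fluxes, 3 free after fixing uptake) with a
    residue map covering twelve amino acids.
``two_species``
    An acyclic producer/consumer chain: species "dv" ferments a 3-carbon
    substrate to a 2-carbon exchange metabolite (acetate-like) plus CO2;
    species "mm" consumes it over two routes with different carbon fates.
    One free flux per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .community import Exchange
from .emu_core import EMU, emu_decompose, simulate_mdvs
from .errors import PepfluxError
from .flux_fitting import FluxProfile, FreeFluxSpace
from .model_io import MeasurementSet, Network, parse_model
from .peptide_labeling import Peptide, PeptidePanel, peptide_mdv

# ---------------------------------------------------------------------------
# model texts

TOY1_TEXT = """\
[reactions]
# id\tequation\treversible\tlb\tub
upt\t=> A\t0\t0\t10
v1\tA (abc) -> B (abc)\t0\t0\t10
v2\tA (abc) -> C (bc) + CO2 (a)\t0\t0\t10
v3\tB (abc) -> C (ab) + CO2 (c)\t0\t0\t10
v4\tC (ab) -> P (ab)\t0\t0\t10
co2_ex\tCO2 =>\t0\t0\t10

[substrate_labeling]
A\t1\t1.0
A\t2\t0.0
A\t3\t0.0

[measured_fluxes]
upt\t1.0\t0.0
"""

TOY1C_TEXT = TOY1_TEXT.replace(
    "co2_ex\tCO2 =>\t0\t0\t10",
    "v5\tCO2 (a) -> D (a)\t0\t0\t10\n"
    "v6\tC (ab) + D (c) -> E (abc)\t0\t0\t10\n"
    "co2_ex\tCO2 =>\t0\t0\t10",
)

ECC1_TEXT = """\
[reactions]
# reduced central-carbon fixture: glycolytic split, PPP-like branch,
# TCA-like cycle with anaplerosis, secretion and biomass drains
upt\tGlc (abcdef) -> G6P (abcdef)\t0\t0\t10
emp\tG6P (abcdef) -> T3 (cba) + T3 (def)\t0\t0\t10
ppp\tG6P (abcdef) -> P5 (bcdef) + CO2 (a)\t0\t0\t10
pk5\tP5 (abcde) -> T3 (cde) + AcX (ab)\t0\t0\t10
t3p\tT3 (abc) -> Pyr (abc)\t0\t0\t10
pdh\tPyr (abc) -> AcA (bc) + CO2 (a)\t0\t0\t10
ac2\tAcX (ab) -> AcA (ab)\t0\t0\t10
acx_ex\tAcX =>\t0\t0\t10
cs\tOAA (abcd) + AcA (ef) -> AKG (abcde) + CO2 (f)\t0\t0\t10
akgd\tAKG (abcde) -> Suc (bcde) + CO2 (a)\t0\t0\t10
sdh\tSuc (abcd) -> OAA (abcd)\t0\t0\t10
pc\tPyr (abc) + CO2 (d) -> OAA (abcd)\t0\t0\t10
akg_ex\tAKG =>\t0\t0\t10
co2_ex\tCO2 =>\t0\t0\t10

[substrate_labeling]
Glc\t1\t1.0
Glc\t2\t0.0
Glc\t3\t0.0
Glc\t4\t0.0
Glc\t5\t0.0
Glc\t6\t0.0

[measured_fluxes]
# uptake plus both extracellular drains are measured, as in a real labeling
# experiment (secretion by exometabolomics, biomass drain from growth rate);
# the remaining free direction is the glycolysis/PPP split
upt\t1.0\t0.0
acx_ex\t0.2\t0.0
akg_ex\t0.3\t0.0
"""

DV_TEXT = """\
[reactions]
upt\tLac (abc) -> LacI (abc)\t0\t0\t10
r1\tLacI (abc) -> B (abc)\t0\t0\t10
r2\tLacI (abc) -> Ac (bc) + CO2 (a)\t0\t0\t10
r3\tB (abc) -> Ac (ab) + CO2 (c)\t0\t0\t10
ac_ex\tAc =>\t0\t0\t10
co2_ex\tCO2 =>\t0\t0\t10

[substrate_labeling]
Lac\t1\t1.0
Lac\t2\t0.0
Lac\t3\t0.0

[measured_fluxes]
upt\t1.0\t0.0
"""

MM_TEXT = """\
[reactions]
upt2\tAcS (ab) -> AcI (ab)\t0\t0\t10
s1\tAcI (ab) -> M (ab)\t0\t0\t10
s2\tAcI (ab) -> C1 (b) + CO2x (a)\t0\t0\t10
s3\tC1 (a) + C1 (b) -> M (ab)\t0\t0\t10
co2x_ex\tCO2x =>\t0\t0\t10

[measured_fluxes]
upt2\t1.0\t0.0
"""

# ---------------------------------------------------------------------------
# residue -> EMU maps (the toy analogue of amino-acid biosynthetic precursors)

TOY1_RESIDUE_MAP: dict[str, EMU] = {
    "A": EMU("P", (1, 2)),
    "G": EMU("CO2", (1,)),
    "V": EMU("B", (1, 2, 3)),
    "S": EMU("B", (1, 2)),
    "L": EMU("B", (1, 3)),
    "T": EMU("P", (1,)),
    "D": EMU("P", (2,)),
    "E": EMU("B", (3,)),
    "K": EMU("P", (1, 2)),
    "R": EMU("B", (2, 3)),
}

ECC1_RESIDUE_MAP: dict[str, EMU] = {
    "A": EMU("Pyr", (1, 2, 3)),
    "S": EMU("T3", (1, 2, 3)),
    "G": EMU("T3", (1, 2)),
    "D": EMU("OAA", (1, 2, 3, 4)),
    "T": EMU("OAA", (1, 2, 3, 4)),
    "E": EMU("AKG", (1, 2, 3, 4, 5)),
    "Q": EMU("AKG", (1, 2, 3, 4, 5)),
    "K": EMU("OAA", (1, 2, 3, 4)),
    "R": EMU("AKG", (1, 2, 3, 4, 5)),
    "V": EMU("P5", (1, 2, 3, 4, 5)),
    "L": EMU("AcA", (1, 2)),
    "I": EMU("P5", (2, 3)),
}

DV_RESIDUE_MAP: dict[str, EMU] = {
    "A": EMU("Ac", (1, 2)),
    "G": EMU("CO2", (1,)),
    "V": EMU("B", (1, 2, 3)),
    "S": EMU("Ac", (1,)),
    "T": EMU("Ac", (2,)),
    "K": EMU("B", (1, 2)),
    "R": EMU("B", (2, 3)),
    "E": EMU("B", (1,)),
}

MM_RESIDUE_MAP: dict[str, EMU] = {
    "A": EMU("M", (1, 2)),
    "G": EMU("CO2x", (1,)),
    "D": EMU("M", (1,)),
    "E": EMU("M", (2,)),
    "K": EMU("M", (1, 2)),
    "R": EMU("M", (1,)),
}


# ---------------------------------------------------------------------------
# toy proteomes


def make_toy_proteome(
    alphabet: str,
    seed: int = 0,
    words_per_length: int = 40,
    lengths: Sequence[int] = (5, 10, 15),
    species: str = "toy",
    peptides_per_protein: int = 10,
) -> str:
    """FASTA text whose tryptic digest yields composition-distinct peptides.

    Each peptide is ``length - 1`` residues drawn from ``alphabet`` (which must
    exclude K, R and P) followed by K or R, so trypsin cuts exactly at the
    designed boundaries.  Words with a previously seen composition are
    rejected, guaranteeing at least ``words_per_length`` composition-distinct
    candidates per length group.
    """
    bad = set(alphabet) & set("KRP")
    if bad:
        raise PepfluxError(f"alphabet must exclude K, R and P; found {sorted(bad)}")
    rng = np.random.default_rng(seed)
    letters = sorted(set(alphabet))
    words: list[str] = []
    seen: set[frozenset] = set()
    for L in lengths:
        made = 0
        attempts = 0
        while made < words_per_length:
            attempts += 1
            if attempts > 100000:
                raise PepfluxError(
                    f"cannot build {words_per_length} composition-distinct words of "
                    f"length {L} over alphabet {alphabet!r}"
                )
            body = "".join(rng.choice(letters, size=L - 1))
            word = body + ("K" if rng.random() < 0.5 else "R")
            from collections import Counter

            comp = frozenset(Counter(word).items())
            if comp in seen:
                continue
            seen.add(comp)
            words.append(word)
            made += 1
    order = rng.permutation(len(words))
    words = [words[i] for i in order]
    records = []
    for i in range(0, len(words), peptides_per_protein):
        chunk = "".join(words[i : i + peptides_per_protein])
        records.append(f">{species}_prot{i // peptides_per_protein + 1}\n{chunk}")
    return "\n".join(records) + "\n"


# ---------------------------------------------------------------------------
# fixture bundles


@dataclass
class Fixture:
    name: str
    model_text: str
    network: Network
    residue_map: dict[str, EMU]
    proteome_fasta: str


@dataclass
class CommunityFixture:
    name: str
    species_names: tuple[str, str]
    networks: dict[str, Network]
    model_texts: dict[str, str]
    residue_maps: dict[str, dict[str, EMU]]
    proteomes: dict[str, str]
    exchange: Exchange


def make_toy_fixtures() -> dict[str, object]:
    """Build every bundled study system; deterministic."""
    toy1 = Fixture(
        "toy1",
        TOY1_TEXT,
        parse_model(TOY1_TEXT),
        dict(TOY1_RESIDUE_MAP),
        make_toy_proteome("AGVSLTDE", seed=11, species="toy1"),
    )
    toy1c_map = dict(TOY1_RESIDUE_MAP)
    toy1c_map["Q"] = EMU("E", (1, 2, 3))
    toy1c = Fixture(
        "toy1c",
        TOY1C_TEXT,
        parse_model(TOY1C_TEXT),
        toy1c_map,
        make_toy_proteome("AGVSLTDEQ", seed=12, species="toy1c"),
    )
    ecc1 = Fixture(
        "ecc1",
        ECC1_TEXT,
        parse_model(ECC1_TEXT),
        dict(ECC1_RESIDUE_MAP),
        make_toy_proteome("ASGDTEQVLI", seed=13, species="ecc1"),
    )
    two_species = CommunityFixture(
        "two_species",
        ("dv", "mm"),
        {"dv": parse_model(DV_TEXT), "mm": parse_model(MM_TEXT)},
        {"dv": DV_TEXT, "mm": MM_TEXT},
        {"dv": dict(DV_RESIDUE_MAP), "mm": dict(MM_RESIDUE_MAP)},
        {
            "dv": make_toy_proteome("AGVSTE", seed=21, species="dv"),
            "mm": make_toy_proteome("AGDE", seed=22, species="mm", lengths=(5, 10)),
        },
        Exchange("dv", "Ac", "mm", "AcS"),
    )
    return {"toy1": toy1, "toy1c": toy1c, "ecc1": ecc1, "two_species": two_species}


# ---------------------------------------------------------------------------
# ground-truth flux profiles


def sample_flux_profile(net: Network, seed: int = 0, burn: int = 1000) -> FluxProfile:
    """Uniform-at-random feasible profile via hit-and-run; deterministic per seed.

    The polytope is the bounded null space of the stoichiometry with measured
    fluxes held fixed, so the profile is already normalized to substrate
    uptake = 1 when the model fixes the uptake there.
    """
    space = FreeFluxSpace(net)
    rng = np.random.default_rng(seed)
    theta = space.sample(rng, 1, burn=burn)[0]
    return space.profile(theta)


# ---------------------------------------------------------------------------
# simulated measurements


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative-relative uniform noise of amplitude delta."""

    delta: float = 0.0
    seed: int = 0
    distribution: str = "uniform"

    def __post_init__(self):
        if self.delta < 0:
            raise PepfluxError("noise amplitude must be non-negative")
        if self.distribution != "uniform":
            raise PepfluxError("only the uniform noise distribution is supported")


def simulate_amino_acid_mdvs(
    net: Network, v: Mapping[str, float], residue_map: Mapping[str, EMU],
    residues: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Noiseless residue MDVs implied by flux profile ``v``."""
    residues = list(residues) if residues is not None else sorted(residue_map)
    emus = sorted({residue_map[r] for r in residues}, key=str)
    graph = emu_decompose(net, emus)
    mdvs = simulate_mdvs(net, v, graph, check_steady=False, on_dead="unlabeled")
    return {r: mdvs[residue_map[r]] for r in residues}


def generate_measurements(
    net: Network,
    v: Mapping[str, float],
    residue_map: Mapping[str, EMU],
    panel: PeptidePanel | None = None,
    noise: NoiseSpec = NoiseSpec(),
    residues: Sequence[str] | None = None,
    sigma_default: float = 0.01,
    renormalize: bool = True,
    sigma_override: float | None = None,
) -> MeasurementSet:
    """Simulate amino-acid (or, with a panel, peptide) MDVs and add noise.

    Noise is applied elementwise: MDV'(m) = MDV(m) * (1 + delta * r),
    r ~ Uniform(-1, 1); the noisy vector is clamped at zero and, by default,
    renormalized to sum one so it remains a valid MDV.  The per-element error
    bound sigma is delta when delta > 0, else ``sigma_default``;
    ``sigma_override`` pins it regardless (e.g. to study lack of fit under
    growing noise at a fixed instrument precision).
    """
    aa = simulate_amino_acid_mdvs(net, v, residue_map, residues)
    if panel is None:
        targets = dict(aa)
        mode = "amino_acid"
    else:
        targets = {s: peptide_mdv(s, aa) for s in panel.sequences()}
        mode = "peptide"
    rng = np.random.default_rng(noise.seed)
    sigma = noise.delta if noise.delta > 0 else sigma_default
    if sigma_override is not None:
        sigma = sigma_override
    entries = {}
    for tid, mdv in targets.items():
        if noise.delta > 0:
            r = rng.uniform(-1.0, 1.0, size=len(mdv))
            noisy = np.clip(mdv * (1.0 + noise.delta * r), 0.0, None)
            if renormalize:
                noisy = noisy / noisy.sum()
        else:
            noisy = np.asarray(mdv, dtype=float)
        entries[tid] = (noisy, np.full(len(mdv), sigma))
    return MeasurementSet(
        entries=entries,
        mode=mode,
        sum_tol=1e-6 if (renormalize or noise.delta == 0) else 1.0,
        normalize=renormalize or noise.delta == 0,
    )


__all__ = [
    "CommunityFixture",
    "DV_RESIDUE_MAP",
    "DV_TEXT",
    "ECC1_RESIDUE_MAP",
    "ECC1_TEXT",
    "Fixture",
    "MM_RESIDUE_MAP",
    "MM_TEXT",
    "NoiseSpec",
    "TOY1C_TEXT",
    "TOY1_RESIDUE_MAP",
    "TOY1_TEXT",
    "generate_measurements",
    "make_toy_fixtures",
    "make_toy_proteome",
    "sample_flux_profile",
    "simulate_amino_acid_mdvs",
]
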