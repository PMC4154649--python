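"""Carbon-transition metabolic models and MDV measurement tables.

The model format is a small sectioned TSV dialect::

    [reactions]
    # id    equation                        reversible  lb   ub
    upt     => A                            0           1    1
    v1      A (abc) -> B (abc)              0           0    10
    v2      A (abc) -> C (bc) + CO2 (a)     0           0    10

    [substrate_labeling]
    # metabolite  position  purity
    A   1   1.0
    A   2   0.0
    A   3   0.0

    [measured_fluxes]
    # reaction  value  error
    upt  1.0  0.0

Atom mappings are lowercase letters, one per carbon, parenthesized after each
species; letters are local to a reaction and must form a bijection between the
reactant and product sides.  Exchange reactions (``=> A`` uptake, ``CO2 =>``
export) carry no mapping.  A species may occur more than once on a side to
express a stoichiometric coefficient of two (``C1 (a) + C1 (b) -> M (ab)``).

Reversible reactions (``reversible = 1``) are split into an irreversible
forward/backward pair ``id__f`` / ``id__b`` with the inverse atom mapping; the
net flux is forward minus backward and the backward flux is capped at a
configurable multiple of the substrate uptake (default 10).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MeasurementError, ModelParseError, ModelValidationError
from .mdv import as_mdv_array, positional_mdv

#: default 13C natural abundance used for substrate positions the labeling
#: specification does not cover
NATURAL_13C = 0.0107

#: default cap on backward exchange fluxes, as a multiple of substrate uptake
DEFAULT_EXCHANGE_CAP = 10.0

Occurrence = tuple[str, tuple[str, ...]]  # (metabolite id, atom-map letters)


@dataclass(frozen=True)
class Reaction:
    """One irreversible flux with its carbon transitions."""

    id: str
    reactants: tuple[Occurrence, ...]
    products: tuple[Occurrence, ...]
    lb: float = 0.0
    ub: float = np.inf
    #: id of the reversible parent reaction, if this flux is half of a pair
    parent: str | None = None

    @property
    def is_exchange(self) -> bool:
        """True for pure uptake (no reactants) or pure export (no products)."""
        return not self.reactants or not self.products


@dataclass
class Network:
    """A carbon-transition metabolic model.

    Fluxes are dimensionless, normalized so that substrate uptake equals one.
    ``substrate_labeling`` maps a substrate metabolite to its per-position
    (1-based) 13C purity; alternatively ``substrate_emu_mdvs`` may pin the full
    MDV of individual substrate EMUs, which is how predicted exchange-metabolite
    labeling is handed to a downstream community member.
    """

    reactions: list[Reaction]
    substrate_labeling: dict[str, dict[int, float]] = field(default_factory=dict)
    measured_fluxes: dict[str, tuple[float, float]] = field(default_factory=dict)
    substrate_emu_mdvs: dict[tuple[str, tuple[int, ...]], np.ndarray] = field(default_factory=dict)
    #: purity assumed for substrate positions absent from the labeling spec
    unspecified_purity: float = NATURAL_13C

    def __post_init__(self):
        self._carbon_counts: dict[str, int] = {}
        for rxn in self.reactions:
            for met, letters in rxn.reactants + rxn.products:
                if letters:
                    prev = self._carbon_counts.setdefault(met, len(letters))
                    if prev != len(letters):
                        raise ModelValidationError(
                            f"metabolite {met!r} has inconsistent carbon counts "
                            f"({prev} vs {len(letters)}, reaction {rxn.id!r})"
                        )

    # -- structural views ---------------------------------------------------

    @property
    def flux_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def carbon_count(self, met: str) -> int:
        try:
            return self._carbon_counts[met]
        except KeyError:
            raise KeyError(f"metabolite {met!r} carries no atom mapping anywhere") from None

    @property
    def metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for rxn in self.reactions:
            for met, _ in rxn.reactants + rxn.products:
                seen.setdefault(met, None)
        return list(seen)

    def is_substrate(self, met: str) -> bool:
        """A metabolite whose labeling state is specified externally."""
        if met in self.substrate_labeling:
            return True
        return any(m == met for (m, _pos) in self.substrate_emu_mdvs)

    def producers(self, met: str) -> list[Reaction]:
        return [r for r in self.reactions if any(m == met for m, _ in r.products)]

    def consumers(self, met: str) -> list[Reaction]:
        return [r for r in self.reactions if any(m == met for m, _ in r.reactants)]

    @property
    def balanced_metabolites(self) -> list[str]:
        """Metabolites with at least one producing and one consuming flux.

        These receive a row in the stoichiometric matrix.  Terminal sinks
        (produced, never consumed) and dead ends are exchange pools and are
        left unbalanced.
        """
        return [m for m in self.metabolites if self.producers(m) and self.consumers(m)]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Return (S, row metabolite ids); columns follow ``flux_ids``."""
        mets = self.balanced_metabolites
        idx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, _ in rxn.products:
                if met in idx:
                    S[idx[met], j] += 1.0
            for met, _ in rxn.reactants:
                if met in idx:
                    S[idx[met], j] -= 1.0
        return S, mets

    # -- labeling of substrate EMUs ----------------------------------------

    def substrate_position_purity(self, met: str, pos: int) -> float:
        spec = self.substrate_labeling.get(met, {})
        return spec.get(pos, self.unspecified_purity)

    def substrate_emu_mdv(self, met: str, positions: tuple[int, ...]) -> np.ndarray:
        """MDV of the substrate EMU on ``positions`` (1-based)."""
        key = (met, tuple(positions))
        if key in self.substrate_emu_mdvs:
            return np.asarray(self.substrate_emu_mdvs[key], dtype=float)
        if met not in self.substrate_labeling:
            raise KeyError(f"{met!r} is not a substrate with positional labeling")
        return positional_mdv(
            self.substrate_position_purity(met, p) for p in positions
        )

    def check_steady_state(self, v: Mapping[str, float], tol: float = 1e-8) -> None:
        S, mets = self.stoichiometric_matrix()
        vec = np.array([v[j] for j in self.flux_ids])
        resid = S @ vec
        if np.max(np.abs(resid)) > tol:
            worst = mets[int(np.argmax(np.abs(resid)))]
            raise ModelValidationError(
                f"flux profile violates steady state at {worst!r} "
                f"(|S v| = {np.max(np.abs(resid)):.3g} > {tol:g})"
            )


# ---------------------------------------------------------------------------
# parsing

_EQ_ARROW = re.compile(r"\s*(->|=>)\s*")
_SPECIES = re.compile(r"^\s*(?P<met>[A-Za-z0-9_.\-]+)\s*(\(\s*(?P<map>[a-z]+)\s*\))?\s*$")


def _parse_side(side: str, rid: str, lineno: int) -> tuple[Occurrence, ...]:
    side = side.strip()
    if not side:
        return ()
    occs = []
    for term in side.split("+"):
        m = _SPECIES.match(term)
        if not m:
            raise ModelParseError(
                f"line {lineno}: reaction {rid!r}: cannot parse species term {term.strip()!r}"
            )
        letters = tuple(m.group("map")) if m.group("map") else ()
        occs.append((m.group("met"), letters))
    return tuple(occs)


def _validate_mapping(rid: str, reactants, products, lineno: int) -> None:
    has_map = any(l for _, l in reactants) or any(l for _, l in products)
    if not reactants or not products:
        if has_map:
            raise ModelParseError(
                f"line {lineno}: exchange reaction {rid!r} must not carry an atom mapping"
            )
        return
    if not has_map:
        raise ModelParseError(
            f"line {lineno}: internal reaction {rid!r} is missing its atom mapping"
        )
    for side_name, side in (("reactant", reactants), ("product", products)):
        for met, letters in side:
            if not letters:
                raise ModelParseError(
                    f"line {lineno}: reaction {rid!r}: {side_name} {met!r} lacks an atom mapping"
                )
    rlet = [l for _, letters in reactants for l in letters]
    plet = [l for _, letters in products for l in letters]
    for name, letters in (("reactant", rlet), ("product", plet)):
        dupes = sorted({l for l in letters if letters.count(l) > 1})
        if dupes:
            raise ModelValidationError(
                f"reaction {rid!r}: duplicate {name} letter(s) {', '.join(dupes)}"
            )
    missing = sorted(set(rlet) - set(plet))
    extra = sorted(set(plet) - set(rlet))
    if missing or extra:
        what = []
        if missing:
            what.append(
                f"letter(s) {', '.join(map(repr, missing))} unbalanced (reactant only)"
            )
        if extra:
            what.append(
                f"letter(s) {', '.join(map(repr, extra))} unbalanced (product only)"
            )
        raise ModelValidationError(f"reaction {rid!r}: " + "; ".join(what))


def _invert_occurrences(reactants, products):
    """Swap sides for the backward half of a reversible reaction."""
    return products, reactants


def parse_model(
    text: str,
    *,
    exchange_cap: float = DEFAULT_EXCHANGE_CAP,
    unspecified_purity: float = NATURAL_13C,
) -> Network:
    """Parse the sectioned carbon-transition TSV dialect into a ``Network``.

    Reversible reactions are split into a forward/backward pair; the backward
    flux is bounded by ``exchange_cap``.
    """
    section = None
    reactions: list[Reaction] = []
    labeling: dict[str, dict[int, float]] = {}
    measured: dict[str, tuple[float, float]] = {}
    seen_ids: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in ("reactions", "substrate_labeling", "measured_fluxes"):
                raise ModelParseError(f"line {lineno}: unknown section {section!r}")
            continue
        if section is None:
            raise ModelParseError(f"line {lineno}: content before any [section] header")
        fields = re.split(r"\t+|\s{2,}", line)
        fields = [f.strip() for f in fields if f.strip()]
        if section == "reactions":
            if len(fields) < 2:
                raise ModelParseError(f"line {lineno}: expected id and equation")
            rid, equation = fields[0], fields[1]
            if rid in seen_ids:
                raise ModelParseError(f"line {lineno}: duplicate reaction id {rid!r}")
            seen_ids.add(rid)
            rev = bool(int(fields[2])) if len(fields) > 2 else False
            lb = float(fields[3]) if len(fields) > 3 else 0.0
            ub = float(fields[4]) if len(fields) > 4 else np.inf
            parts = _EQ_ARROW.split(equation, maxsplit=1)
            if len(parts) != 3:
                raise ModelParseError(
                    f"line {lineno}: reaction {rid!r}: no '->' in equation {equation!r}"
                )
            reactants = _parse_side(parts[0], rid, lineno)
            products = _parse_side(parts[2], rid, lineno)
            if not reactants and not products:
                raise ModelParseError(f"line {lineno}: reaction {rid!r} has no species")
            _validate_mapping(rid, reactants, products, lineno)
            if rev:
                if lb < 0:
                    lb = 0.0  # the split pair encodes reversibility
                reactions.append(Reaction(f"{rid}__f", reactants, products, lb=0.0, ub=ub, parent=rid))
                back_r, back_p = _invert_occurrences(reactants, products)
                reactions.append(
                    Reaction(f"{rid}__b", back_r, back_p, lb=0.0, ub=exchange_cap, parent=rid)
                )
            else:
                reactions.append(Reaction(rid, reactants, products, lb=lb, ub=ub))
        elif section == "substrate_labeling":
            if len(fields) != 3:
                raise ModelParseError(
                    f"line {lineno}: expected 'metabolite position purity'"
                )
            met, pos, purity = fields[0], int(fields[1]), float(fields[2])
            if not 0.0 <= purity <= 1.0:
                raise ModelParseError(f"line {lineno}: purity {purity} outside [0, 1]")
            labeling.setdefault(met, {})[pos] = purity
        elif section == "measured_fluxes":
            if len(fields) not in (2, 3):
                raise ModelParseError(f"line {lineno}: expected 'reaction value [error]'")
            err = float(fields[2]) if len(fields) == 3 else 0.0
            measured[fields[0]] = (float(fields[1]), err)
    if not reactions:
        raise ModelParseError("model has no [reactions] section or it is empty")
    net = Network(
        reactions=reactions,
        substrate_labeling=labeling,
        measured_fluxes=measured,
        unspecified_purity=unspecified_purity,
    )
    for rid in measured:
        if rid not in net.flux_ids and not any(r.parent == rid for r in net.reactions):
            raise ModelParseError(f"measured flux {rid!r} references no reaction")
    return net


def serialize_model(net: Network) -> str:
    """Render a ``Network`` back into the sectioned TSV dialect.

    Split reversible pairs are re-merged into a single ``reversible = 1`` line.
    ``parse_model(serialize_model(net))`` reproduces the network.
    """
    lines = ["[reactions]"]
    done_parents: set[str] = set()

    def fmt_side(occs):
        return " + ".join(
            f"{met} ({''.join(letters)})" if letters else met for met, letters in occs
        )

    for rxn in net.reactions:
        if rxn.parent is not None:
            if rxn.parent in done_parents:
                continue
            done_parents.add(rxn.parent)
            fwd = next(r for r in net.reactions if r.parent == rxn.parent and r.id.endswith("__f"))
            eq = f"{fmt_side(fwd.reactants)} -> {fmt_side(fwd.products)}"
            lines.append(f"{rxn.parent}\t{eq}\t1\t{fwd.lb!r}\t{fwd.ub!r}")
            continue
        arrow = "=>" if rxn.is_exchange else "->"
        eq = f"{fmt_side(rxn.reactants)} {arrow} {fmt_side(rxn.products)}".strip()
        lines.append(f"{rxn.id}\t{eq}\t0\t{rxn.lb!r}\t{rxn.ub!r}")
    if net.substrate_labeling:
        lines.append("")
        lines.append("[substrate_labeling]")
        for met, spec in net.substrate_labeling.items():
            for pos in sorted(spec):
                lines.append(f"{met}\t{pos}\t{spec[pos]!r}")
    if net.measured_fluxes:
        lines.append("")
        lines.append("[measured_fluxes]")
        for rid, (val, err) in net.measured_fluxes.items():
            lines.append(f"{rid}\t{val!r}\t{err!r}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# atom-balance report


@dataclass(frozen=True)
class BalanceFinding:
    reaction: str
    message: str

    def __str__(self):
        return f"{self.reaction}: {self.message}"


def check_atom_balance(net: Network) -> list[BalanceFinding]:
    """Report per-reaction atom-mapping defects and carbon-count conflicts.

    The returned list is empty iff every internal reaction's mapping is a
    bijection and each metabolite has a single carbon count.  Parsing already
    rejects broken models; this reporting form exists for programmatically
    built networks and for diagnostics.
    """
    findings: list[BalanceFinding] = []
    counts: dict[str, tuple[int, str]] = {}
    for rxn in net.reactions:
        if rxn.is_exchange:
            continue
        rlet = [l for _, letters in rxn.reactants for l in letters]
        plet = [l for _, letters in rxn.products for l in letters]
        for name, letters in (("reactant", rlet), ("product", plet)):
            for dup in sorted({l for l in letters if letters.count(l) > 1}):
                findings.append(
                    BalanceFinding(rxn.id, f"duplicate {name} letter {dup!r}")
                )
        for l in sorted(set(rlet) - set(plet)):
            findings.append(BalanceFinding(rxn.id, f"letter {l!r} lost on product side"))
        for l in sorted(set(plet) - set(rlet)):
            findings.append(BalanceFinding(rxn.id, f"letter {l!r} appears only on product side"))
        for met, letters in rxn.reactants + rxn.products:
            if not letters:
                continue
            if met in counts and counts[met][0] != len(letters):
                findings.append(
                    BalanceFinding(
                        rxn.id,
                        f"metabolite {met!r} has {len(letters)} carbons here but "
                        f"{counts[met][0]} in reaction {counts[met][1]!r}",
                    )
                )
            else:
                counts.setdefault(met, (len(letters), rxn.id))
    return findings


# ---------------------------------------------------------------------------
# measurement tables


@dataclass
class MeasurementSet:
    """Observed MDVs with per-element error bounds.

    ``entries`` maps a target id (amino-acid/fragment id or peptide sequence)
    to ``(mdv, err)`` arrays of equal length.  ``mode`` distinguishes
    amino-acid from peptide measurements.
    """

    entries: dict[str, tuple[np.ndarray, np.ndarray]]
    mode: str = "amino_acid"
    #: maximum tolerated deviation of each MDV's sum from one; raw (noisy,
    #: un-renormalized) data may relax this
    sum_tol: float = 1e-6
    #: rescale each MDV to sum exactly one (within sum_tol) on construction
    normalize: bool = True

    def __post_init__(self):
        if self.mode not in ("amino_acid", "peptide"):
            raise MeasurementError(f"unknown measurement mode {self.mode!r}")
        for tid, (mdv, err) in self.entries.items():
            mdv = as_mdv_array(mdv, tol=self.sum_tol, renormalize=self.normalize)
            err = np.asarray(err, dtype=float)
            if err.shape != mdv.shape:
                raise MeasurementError(f"target {tid!r}: error bound shape mismatch")
            if np.any(err < 0):
                raise MeasurementError(f"target {tid!r}: negative error bound")
            self.entries[tid] = (mdv, err)

    def targets(self) -> list[str]:
        return list(self.entries)


def read_mdv_table(source, mode: str = "amino_acid") -> MeasurementSet:
    """Read a measurement CSV (columns target_id, m, fraction, error).

    Fractions of each target must sum to one within 1e-6 (they are then
    renormalized exactly); larger deviations and negative fractions are
    integrity errors.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, comment="#")
    required = {"target_id", "m", "fraction", "error"}
    if not required.issubset(df.columns):
        raise MeasurementError(
            f"measurement table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    entries: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tid, grp in df.groupby("target_id", sort=False):
        grp = grp.sort_values("m")
        ms = grp["m"].to_numpy()
        if not np.array_equal(ms, np.arange(len(ms))):
            raise MeasurementError(f"target {tid!r}: m values are not 0..{len(ms) - 1}")
        frac = grp["fraction"].to_numpy(dtype=float)
        if np.any(frac < 0):
            raise MeasurementError(f"target {tid!r}: negative fraction")
        if abs(frac.sum() - 1.0) > 1e-6:
            raise MeasurementError(
                f"target {tid!r}: fractions sum to {frac.sum():.8g}, deviates from 1 by more than 1e-6"
            )
        entries[str(tid)] = (frac, grp["error"].to_numpy(dtype=float))
    return MeasurementSet(entries=entries, mode=mode)


def write_mdv_table(meas: MeasurementSet, path=None) -> str | None:
    """Write a MeasurementSet as CSV; returns the text when ``path`` is None.

    Floats are written with ``repr`` so that a write/read round trip is
    bit-exact.
    """
    lines = ["target_id,m,fraction,error"]
    for tid, (mdv, err) in meas.entries.items():
        for m, (f, e) in enumerate(zip(mdv, err)):
            lines.append(f"{tid},{m},{float(f)!r},{float(e)!r}")
    text = "\n".join(lines) + "\n"
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)
    return None


__all__ = [
    "BalanceFinding",
    "DEFAULT_EXCHANGE_CAP",
    "MeasurementSet",
    "NATURAL_13C",
    "Network",
    "Reaction",
    "check_atom_balance",
    "parse_model",
    "read_mdv_table",
    "serialize_model",
    "write_mdv_table",
]
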