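"""EMU decomposition and steady-state labeling simulation.

An elementary metabolite unit (EMU) is a subset of a metabolite's carbon atoms
whose mass distribution can be balanced independently of the rest of the
molecule.  Tracing target EMUs backward through the atom mappings yields a
dependency graph that is acyclic across EMU sizes: a size-k EMU depends only on
EMUs of size <= k, and condensation reactions introduce "combined" EMUs whose
MDV is the convolution of their (strictly smaller) constituents.  Steady-state
MDVs are then obtained by one sparse linear solve per size stratum, in
increasing size order.

The module also provides a brute-force positional-isotopomer solver used as an
independent oracle on small networks, and natural-abundance correction
matrices that map a carbon-backbone MDV to the observed MDV including
heteroatom isotope effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import DeadEMUError, ModelValidationError, UnreachableEMUError
from .mdv import convolve_many, delta_mdv
from .model_io import Network

# ---------------------------------------------------------------------------
# EMU node types


@dataclass(frozen=True)
class EMU:
    """A metabolite fragment: ``metabolite`` and sorted 1-based carbon positions."""

    metabolite: str
    positions: tuple[int, ...]

    def __post_init__(self):
        pos = tuple(sorted(self.positions))
        if len(set(pos)) != len(pos) or not pos or pos[0] < 1:
            raise ValueError(f"invalid EMU positions {self.positions!r}")
        object.__setattr__(self, "positions", pos)

    @property
    def size(self) -> int:
        return len(self.positions)

    def __str__(self):
        return f"{self.metabolite}({','.join(map(str, self.positions))})"


@dataclass(frozen=True)
class CombinedEMU:
    """Condensation product: its MDV is the convolution of the constituents'."""

    constituents: tuple[EMU, ...]

    def __post_init__(self):
        object.__setattr__(
            self,
            "constituents",
            tuple(sorted(self.constituents, key=lambda e: (e.metabolite, e.positions))),
        )

    @property
    def size(self) -> int:
        return sum(e.size for e in self.constituents)

    def __str__(self):
        return " x ".join(str(e) for e in self.constituents)


class EMUGraph:
    """Size-stratified EMU dependency graph.

    ``productions[e]`` lists ``(flux_id, source)`` pairs, one per producing
    reaction occurrence, where ``source`` is an :class:`EMU` (substrate or
    internal) or a :class:`CombinedEMU`.  ``targets`` are the EMUs the graph
    was decomposed for.
    """

    def __init__(self, net: Network, targets, productions, substrates):
        self.net = net
        self.targets: tuple[EMU, ...] = tuple(targets)
        self.productions: dict[EMU, list[tuple[str, object]]] = productions
        self.substrates: set[EMU] = substrates
        self.graph = nx.DiGraph()
        for e, prods in productions.items():
            self.graph.add_node(e)
            for fid, src in prods:
                self.graph.add_edge(src, e, flux=fid)
                if isinstance(src, CombinedEMU):
                    for c in src.constituents:
                        self.graph.add_edge(c, src)

    @property
    def sizes(self) -> list[int]:
        return sorted({e.size for e in self.productions})

    def internal_emus(self, size: int | None = None) -> list[EMU]:
        emus = list(self.productions)
        if size is not None:
            emus = [e for e in emus if e.size == size]
        return emus

    def combined_nodes(self) -> list[CombinedEMU]:
        return [n for n in self.graph.nodes if isinstance(n, CombinedEMU)]


def _trace_occurrence(rxn, occ_index: int, positions: tuple[int, ...]):
    """Map ``positions`` of product occurrence ``occ_index`` back to reactant EMUs.

    Returns a list of (reactant metabolite, positions) groups, one per reactant
    occurrence contributing at least one carbon.
    """
    met, letters = rxn.products[occ_index]
    needed = [letters[p - 1] for p in positions]
    groups: dict[int, list[int]] = {}
    for letter in needed:
        for k, (_rmet, rletters) in enumerate(rxn.reactants):
            if letter in rletters:
                groups.setdefault(k, []).append(rletters.index(letter) + 1)
                break
        else:  # pragma: no cover - parse guarantees the bijection
            raise ModelValidationError(
                f"reaction {rxn.id!r}: product letter {letter!r} has no reactant origin"
            )
    return [
        (rxn.reactants[k][0], tuple(sorted(pos))) for k, pos in sorted(groups.items())
    ]


def emu_decompose(net: Network, targets) -> EMUGraph:
    """Decompose ``net`` into the EMUs reachable backward from ``targets``.

    Substrate EMUs (metabolites with externally specified labeling) terminate
    the trace and become leaves.  A reaction that condenses fragments from two
    or more reactant occurrences into one product EMU yields a combined node.
    """
    targets = [t if isinstance(t, EMU) else EMU(*t) for t in targets]
    for t in targets:
        if t.positions[-1] > net.carbon_count(t.metabolite):
            raise ValueError(f"target {t} exceeds carbon count of {t.metabolite!r}")
    productions: dict[EMU, list[tuple[str, object]]] = {}
    substrates: set[EMU] = set()
    stack = list(targets)
    while stack:
        e = stack.pop()
        if e in productions or e in substrates:
            continue
        if net.is_substrate(e.metabolite):
            substrates.add(e)
            continue
        prods: list[tuple[str, object]] = []
        for rxn in net.producers(e.metabolite):
            for k, (met, letters) in enumerate(rxn.products):
                if met != e.metabolite:
                    continue
                if not letters:
                    continue  # unmapped exchange production
                groups = _trace_occurrence(rxn, k, e.positions)
                sources = [EMU(m, pos) for m, pos in groups]
                src: object
                src = sources[0] if len(sources) == 1 else CombinedEMU(tuple(sources))
                prods.append((rxn.id, src))
                stack.extend(sources)
        if not prods:
            raise UnreachableEMUError(
                f"EMU {e} has no mapped producing reaction and {e.metabolite!r} "
                "is not a substrate"
            )
        productions[e] = prods
    return EMUGraph(net, targets, productions, substrates)


# ---------------------------------------------------------------------------
# steady-state simulation


def simulate_mdvs(
    net: Network,
    v: Mapping[str, float],
    graph: EMUGraph,
    *,
    check_steady: bool = True,
    on_dead: str = "raise",
) -> dict[EMU, np.ndarray]:
    """Steady-state MDVs of the graph's target EMUs under flux profile ``v``.

    One sparse direct solve per size stratum, ascending; combined-EMU MDVs are
    the convolution of their constituents.  ``on_dead`` controls the treatment
    of EMUs with (numerically) zero production: ``"raise"`` flags them as
    :class:`DeadEMUError`, ``"unlabeled"`` pins them to the unlabeled MDV,
    which is the appropriate convention inside an optimizer where a flux may
    touch zero (the dead EMU then carries no material downstream either).
    """
    if check_steady:
        net.check_steady_state(v)
    solved: dict[object, np.ndarray] = {}

    def source_mdv(src) -> np.ndarray:
        if src in solved:
            return solved[src]
        if isinstance(src, CombinedEMU):
            out = convolve_many(source_mdv(c) for c in src.constituents)
        else:
            out = net.substrate_emu_mdv(src.metabolite, src.positions)
        solved[src] = out
        return out

    for size in graph.sizes:
        emus = graph.internal_emus(size)
        index = {e: i for i, e in enumerate(emus)}
        n = len(emus)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        b = np.zeros((n, size + 1))
        for e, i in index.items():
            for fid, src in graph.productions[e]:
                vj = float(v[fid])
                diag[i] += vj
                if isinstance(src, EMU) and src in index:
                    rows.append(i)
                    cols.append(index[src])
                    vals.append(-vj)
                else:
                    b[i] += vj * source_mdv(src)
        dead = [emus[i] for i in range(n) if diag[i] <= 1e-12]
        if dead:
            if on_dead == "raise":
                raise DeadEMUError(
                    "zero production for EMU(s): " + ", ".join(map(str, dead))
                )
            for e in dead:
                i = index[e]
                diag[i] = 1.0
                b[i] = delta_mdv(size + 1)
                # drop its same-stratum inflow terms
                vals = [
                    0.0 if r == i else val for r, val in zip(rows, vals)
                ]
        A = sp.csc_matrix(
            (np.concatenate([diag, vals]) if vals else diag,
             (np.concatenate([np.arange(n), rows]).astype(int) if rows else np.arange(n),
              np.concatenate([np.arange(n), cols]).astype(int) if cols else np.arange(n))),
            shape=(n, n),
        )
        try:
            lu = spla.splu(A)
            X = lu.solve(b)
        except RuntimeError as exc:
            raise DeadEMUError(f"singular EMU balance system at size {size}: {exc}")
        X = np.clip(X, 0.0, None)
        sums = X.sum(axis=1, keepdims=True)
        if on_dead == "raise" and np.any(np.abs(sums - 1.0) > 1e-6):
            worst = emus[int(np.argmax(np.abs(sums - 1.0)))]
            raise DeadEMUError(
                f"EMU {worst} balance produced a non-normalized MDV "
                f"(sum deviates by {np.max(np.abs(sums - 1.0)):.3g})"
            )
        # tolerate drift from ill-conditioned near-zero production: an
        # optimizer's line search may probe slightly infeasible profiles
        X = X / np.where(sums > 0, sums, 1.0)
        for e, i in index.items():
            solved[e] = X[i]
    return {t: solved[t] if t in solved else source_mdv(t) for t in graph.targets}


# ---------------------------------------------------------------------------
# full positional-isotopomer oracle

#: hard cap on per-metabolite carbons for the exponential-size oracle
_ORACLE_CARBON_CAP = 12


def isotopomer_oracle(
    net: Network,
    v: Mapping[str, float],
    *,
    tol: float = 1e-13,
    max_iter: int = 500,
    emus: Sequence[EMU] = (),
) -> dict[object, np.ndarray]:
    """Solve the complete 2^C positional-isotopomer steady state; return MDVs.

    Keys are metabolite ids; any requested ``emus`` additionally appear under
    their :class:`EMU` keys, with MDVs obtained by marginalizing the joint
    isotopomer distribution over the EMU's positions.

    Exponential in carbon count and meant purely as an independent check of
    :func:`simulate_mdvs` on toy networks.  Without condensation reactions the
    balance is linear and solved in a single pass; condensation couples
    reactant distributions bilinearly, which is handled by fixed-point
    iteration of exact linear solves.
    """
    mets = [m for m in net.metabolites if m in net._carbon_counts]
    for m in mets:
        if net.carbon_count(m) > _ORACLE_CARBON_CAP:
            raise ModelValidationError(
                f"metabolite {m!r} has {net.carbon_count(m)} carbons, oracle cap is "
                f"{_ORACLE_CARBON_CAP}"
            )
    internal = [m for m in mets if not net.is_substrate(m)]
    substrate = [m for m in mets if net.is_substrate(m)]

    def substrate_joint(m: str) -> np.ndarray:
        # bit i-1 of the state indexes carbon position i; np.kron in position
        # order builds exactly that layout
        c = net.carbon_count(m)
        out = np.ones(1)
        for i in range(c):
            pi = net.substrate_position_purity(m, i + 1)
            out = np.kron(np.array([1.0 - pi, pi]), out)
        return out

    joint: dict[str, np.ndarray] = {m: substrate_joint(m) for m in substrate}
    offsets: dict[str, int] = {}
    sizes: dict[str, int] = {}
    off = 0
    for m in internal:
        offsets[m], sizes[m] = off, 2 ** net.carbon_count(m)
        off += sizes[m]
        joint[m] = delta_mdv(sizes[m])  # initial iterate: unlabeled
    ntot = off

    def marginal(m: str, positions: tuple[int, ...]) -> np.ndarray:
        """Joint marginal of ``positions`` (1-based) of metabolite ``m``."""
        c = net.carbon_count(m)
        dist = joint[m]
        out = np.zeros(2 ** len(positions))
        for s in range(2**c):
            t = 0
            for bi, p in enumerate(positions):
                if s >> (p - 1) & 1:
                    t |= 1 << bi
            out[t] += dist[s]
        return out

    # For every mapped product occurrence, record where each product carbon
    # comes from: (reactant occurrence index, reactant metabolite, position).
    linear_terms = []  # single-reactant origin: linear inflow
    cond_terms = []  # condensation: bilinear, handled by fixed point
    prod_fluxes = []  # (metabolite, flux id) for the production diagonal
    for rxn in net.reactions:
        for kprod, (m, letters) in enumerate(rxn.products):
            if not letters or m not in offsets:
                continue
            c = net.carbon_count(m)
            origin = []
            for p in range(1, c + 1):
                letter = letters[p - 1]
                for kk, (rmet, rletters) in enumerate(rxn.reactants):
                    if letter in rletters:
                        origin.append((kk, rmet, rletters.index(letter) + 1))
                        break
            occs = sorted({kk for kk, _, _ in origin})
            prod_fluxes.append((m, rxn.id))
            if len(occs) == 1:
                linear_terms.append((m, rxn.id, origin))
            else:
                cond_terms.append((m, rxn.id, origin, occs, rxn))

    diag = np.zeros(ntot)
    for m, fid in prod_fluxes:
        diag[offsets[m] : offsets[m] + sizes[m]] += float(v[fid])
    dead = diag <= 1e-12
    diag = np.where(dead, 1.0, diag)

    rows, cols, vals = [], [], []
    b_const = np.zeros(ntot)
    for m, fid, origin in linear_terms:
        vj = float(v[fid])
        base, c = offsets[m], net.carbon_count(m)
        rmet = origin[0][1]
        rpos = [rp for _, _, rp in origin]  # reactant position feeding carbon p
        if rmet in offsets:
            rbase, rc = offsets[rmet], net.carbon_count(rmet)
            for sr in range(2**rc):
                s = 0
                for p0, rp in enumerate(rpos):
                    if sr >> (rp - 1) & 1:
                        s |= 1 << p0
                rows.append(base + s)
                cols.append(rbase + sr)
                vals.append(-vj)
        else:
            rc = net.carbon_count(rmet)
            dist = joint[rmet]
            inflow = np.zeros(2**c)
            for sr in range(2**rc):
                s = 0
                for p0, rp in enumerate(rpos):
                    if sr >> (rp - 1) & 1:
                        s |= 1 << p0
                inflow[s] += dist[sr]
            b_const[base : base + 2**c] += vj * inflow

    A = sp.csc_matrix(
        (
            np.concatenate([diag, vals]) if vals else diag,
            (
                np.concatenate([np.arange(ntot), rows]).astype(int) if rows else np.arange(ntot),
                np.concatenate([np.arange(ntot), cols]).astype(int) if cols else np.arange(ntot),
            ),
        ),
        shape=(ntot, ntot),
    )
    lu = spla.splu(A) if ntot else None
    for _ in range(max_iter):
        b = b_const.copy()
        for m, fid, origin, occs, rxn in cond_terms:
            vj = float(v[fid])
            base, c = offsets[m], net.carbon_count(m)
            margs = {}
            pos_idx = {}
            for kk in occs:
                rmet = rxn.reactants[kk][0]
                pos = tuple(rp for o, _, rp in origin if o == kk)
                margs[kk] = marginal(rmet, pos)
                pos_idx[kk] = [i for i, (o, _, _) in enumerate(origin) if o == kk]
            inflow = np.zeros(2**c)
            for s in range(2**c):
                prob = 1.0
                for kk in occs:
                    t = 0
                    for bi, pi in enumerate(pos_idx[kk]):
                        if s >> pi & 1:
                            t |= 1 << bi
                    prob *= margs[kk][t]
                inflow[s] = prob
            b[base : base + 2**c] += vj * inflow
        for m in internal:
            base = offsets[m]
            if dead[base]:
                b[base : base + sizes[m]] = 0.0
                b[base] = 1.0  # dead pool: unlabeled by convention
        if lu is None:
            break
        x = lu.solve(b)
        delta = max(
            (
                float(np.max(np.abs(x[offsets[m] : offsets[m] + sizes[m]] - joint[m])))
                for m in internal
            ),
            default=0.0,
        )
        for m in internal:
            joint[m] = x[offsets[m] : offsets[m] + sizes[m]]
        if not cond_terms or delta < tol:
            break

    out: dict[object, np.ndarray] = {}
    for m in mets:
        c = net.carbon_count(m)
        mdv = np.zeros(c + 1)
        dist = joint[m]
        for s in range(2**c):
            mdv[bin(s).count("1")] += dist[s]
        out[m] = mdv / mdv.sum()
    for e in emus:
        marg = marginal(e.metabolite, e.positions)
        mdv = np.zeros(e.size + 1)
        for s in range(2**e.size):
            mdv[bin(s).count("1")] += marg[s]
        out[e] = mdv / mdv.sum()
    return out


# ---------------------------------------------------------------------------
# natural-abundance correction

#: standard heavy-isotope abundances (fraction of atoms); O and S list the
#: +1 and +2 mass shifts separately
ISOTOPE_SHIFTS: dict[str, np.ndarray] = {
    "H": np.array([1 - 0.000115, 0.000115]),
    "C": np.array([1 - 0.0107, 0.0107]),
    "N": np.array([1 - 0.00364, 0.00364]),
    "O": np.array([1 - 0.00038 - 0.00205, 0.00038, 0.00205]),
    "S": np.array([1 - 0.0075 - 0.0421, 0.0075, 0.0421]),
}

#: molecular formulas of the free amino acids, keyed by one-letter code
AA_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 5, "N": 1, "O": 2},
    "A": {"C": 3, "H": 7, "N": 1, "O": 2},
    "S": {"C": 3, "H": 7, "N": 1, "O": 3},
    "P": {"C": 5, "H": 9, "N": 1, "O": 2},
    "V": {"C": 5, "H": 11, "N": 1, "O": 2},
    "T": {"C": 4, "H": 9, "N": 1, "O": 3},
    "C": {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1},
    "L": {"C": 6, "H": 13, "N": 1, "O": 2},
    "I": {"C": 6, "H": 13, "N": 1, "O": 2},
    "N": {"C": 4, "H": 8, "N": 2, "O": 3},
    "D": {"C": 4, "H": 7, "N": 1, "O": 4},
    "Q": {"C": 5, "H": 10, "N": 2, "O": 3},
    "K": {"C": 6, "H": 14, "N": 2, "O": 2},
    "E": {"C": 5, "H": 9, "N": 1, "O": 4},
    "M": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 1},
    "H": {"C": 6, "H": 9, "N": 3, "O": 2},
    "F": {"C": 9, "H": 11, "N": 1, "O": 2},
    "R": {"C": 6, "H": 14, "N": 4, "O": 2},
    "Y": {"C": 9, "H": 11, "N": 1, "O": 3},
    "W": {"C": 11, "H": 12, "N": 2, "O": 2},
}

DEFAULT_SHIFT_WINDOW = 4


@dataclass(frozen=True)
class CorrectionMatrix:
    """Lower-triangular map from backbone-carbon MDV to observed MDV.

    Column m holds the natural-abundance mass-shift distribution of all atoms
    that are not traced carbons, placed at rows m, m+1, ...; columns therefore
    sum to at most one (probability mass beyond the shift window is dropped).
    """

    id: str
    shift: np.ndarray
    expected_raw_len: int | None = None

    @property
    def window(self) -> int:
        return len(self.shift) - 1

    def matrix(self, n_raw: int) -> np.ndarray:
        n = n_raw + self.window
        A = np.zeros((n, n))
        for j in range(n_raw):
            k = min(len(self.shift), n - j)
            A[j : j + k, j] = self.shift[:k]
        return A

    @classmethod
    def identity(cls, ident: str = "X") -> "CorrectionMatrix":
        return cls(ident, np.array([1.0]))

    @classmethod
    def from_formula(
        cls,
        ident: str,
        formula: Mapping[str, int],
        traced_carbons: int,
        window: int = DEFAULT_SHIFT_WINDOW,
    ) -> "CorrectionMatrix":
        """Build the shift distribution from a molecular formula.

        ``traced_carbons`` carbons are excluded (their labeling is the tracer
        signal); all other atoms, including any untraced carbons, contribute
        their natural heavy-isotope binomials.  An empty formula yields the
        identity.
        """
        shift = np.array([1.0])
        for elem, count in formula.items():
            if elem not in ISOTOPE_SHIFTS:
                raise ValueError(f"no isotope data for element {elem!r}")
            n = count - traced_carbons if elem == "C" else count
            if n < 0:
                raise ValueError(
                    f"{ident}: traced carbons ({traced_carbons}) exceed formula carbons ({count})"
                )
            for _ in range(n):
                shift = np.convolve(shift, ISOTOPE_SHIFTS[elem])
        shift = shift[: window + 1]
        expected = traced_carbons + 1 if "C" in formula else None
        return cls(ident, shift, expected_raw_len=expected)

    @classmethod
    def for_amino_acid(
        cls, residue: str, window: int = DEFAULT_SHIFT_WINDOW
    ) -> "CorrectionMatrix":
        if residue == "X":
            return cls.identity()
        formula = AA_FORMULAS[residue]
        return cls.from_formula(residue, formula, traced_carbons=formula["C"], window=window)


def correction_apply(raw, cm: CorrectionMatrix) -> np.ndarray:
    """Apply a natural-abundance correction matrix and renormalize to sum 1."""
    raw = np.asarray(raw, dtype=float)
    if cm.expected_raw_len is not None and len(raw) != cm.expected_raw_len:
        raise ValueError(
            f"correction matrix {cm.id!r} expects an MDV of length "
            f"{cm.expected_raw_len}, got {len(raw)}"
        )
    A = cm.matrix(len(raw))
    padded = np.zeros(A.shape[1])
    padded[: len(raw)] = raw
    out = A @ padded
    return out / out.sum()


__all__ = [
    "AA_FORMULAS",
    "CombinedEMU",
    "CorrectionMatrix",
    "DEFAULT_SHIFT_WINDOW",
    "EMU",
    "EMUGraph",
    "ISOTOPE_SHIFTS",
    "correction_apply",
    "emu_decompose",
    "isotopomer_oracle",
    "simulate_mdvs",
]
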