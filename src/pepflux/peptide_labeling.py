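"""Peptide panels and peptide mass distribution vectors.

A peptide's labeling depends only on its amino-acid composition, not on
residue order: the peptide MDV is the Cauchy product (discrete convolution) of
its residues' MDVs.  Panels are therefore chosen to be pairwise
composition-distinct — two anagrams carry identical labeling information — and,
in community mode, unique to a single species' proteome so the peptide can be
attributed to the species it came from.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .emu_core import CorrectionMatrix, correction_apply
from .errors import PepfluxError
from .mdv import convolve_many

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: inert padding residue: contributes the delta MDV [1, 0]
DUMMY_RESIDUE = "X"


@dataclass(frozen=True)
class Peptide:
    sequence: str
    protein: str = ""
    species: str = ""

    @property
    def composition(self) -> frozenset:
        """Order-insensitive residue multiset, the labeling-relevant identity."""
        return frozenset(Counter(self.sequence).items())

    def __len__(self):
        return len(self.sequence)


@dataclass
class PeptidePanel:
    """A list of composition-distinct peptides with species provenance."""

    peptides: list[Peptide]
    lengths: object = "mixed"  # 5 | 10 | 15 | "mixed" | sequence of ints

    def __post_init__(self):
        seen: dict[frozenset, str] = {}
        for p in self.peptides:
            bad = set(p.sequence) - CANONICAL_RESIDUES - {DUMMY_RESIDUE}
            if bad:
                raise PepfluxError(
                    f"peptide {p.sequence!r} uses non-canonical residue(s) {sorted(bad)}"
                )
            if p.composition in seen:
                raise PepfluxError(
                    f"peptides {seen[p.composition]!r} and {p.sequence!r} share a "
                    "composition; their labeling is indistinguishable"
                )
            seen[p.composition] = p.sequence

    def __len__(self):
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def prefix(self, n: int) -> "PeptidePanel":
        return PeptidePanel(self.peptides[:n], lengths=self.lengths)

    def to_csv(self, path=None) -> str | None:
        lines = ["sequence,species,protein,length"]
        for p in self.peptides:
            lines.append(f"{p.sequence},{p.species},{p.protein},{len(p)}")
        text = "\n".join(lines) + "\n"
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


# ---------------------------------------------------------------------------
# in-silico digestion


@dataclass(frozen=True)
class ProteaseRules:
    """Cleavage specification; the default is trypsin (after K/R, not before P)."""

    cleave_after: str = "KR"
    no_cleave_before: str = "P"
    missed_cleavages: int = 0


def digest_sequence(seq: str, rules: ProteaseRules = ProteaseRules()) -> list[str]:
    """Cleave one protein sequence into peptides (scanning implementation)."""
    sites = [0]
    for i, ch in enumerate(seq[:-1]):
        if ch in rules.cleave_after and seq[i + 1] not in rules.no_cleave_before:
            sites.append(i + 1)
    sites.append(len(seq))
    base = [seq[a:b] for a, b in zip(sites, sites[1:]) if b > a]
    if rules.missed_cleavages == 0:
        return base
    out = []
    for k in range(rules.missed_cleavages + 1):
        for i in range(len(base) - k):
            out.append("".join(base[i : i + k + 1]))
    return out


def digest_proteome(
    fasta, rules: ProteaseRules = ProteaseRules(), species: str = ""
) -> list[Peptide]:
    """Digest a proteome FASTA (path, handle, or in-memory text).

    Records containing non-amino-acid characters are skipped; a
    ``UserWarning`` naming the record is emitted for each.
    """
    import io
    import warnings

    if isinstance(fasta, str) and "\n" in fasta:
        fasta = io.StringIO(fasta)
    peptides: list[Peptide] = []
    for rec in SeqIO.parse(fasta, "fasta"):
        seq = str(rec.seq).upper()
        if set(seq) - CANONICAL_RESIDUES:
            warnings.warn(
                f"record {rec.id!r} contains non-amino-acid characters; skipped"
            )
            continue
        for pep in digest_sequence(seq, rules):
            peptides.append(Peptide(pep, protein=rec.id, species=species))
    return peptides


# ---------------------------------------------------------------------------
# panel selection


def _length_filter(length_spec) -> callable:
    if length_spec == "mixed":
        allowed = {5, 10, 15}
    elif isinstance(length_spec, int):
        allowed = {length_spec}
    else:
        allowed = set(length_spec)
    return lambda p: len(p) in allowed


def select_panel(
    peptides: Sequence[Peptide],
    n: int,
    lengths="mixed",
    community: Mapping[str, Iterable[str]] | None = None,
    seed: int = 0,
) -> PeptidePanel:
    """Choose ``n`` composition-distinct peptides matching the length spec.

    Candidates are sorted by (length, sequence), shuffled with a seeded RNG,
    and taken greedily while rejecting repeated compositions.  In community
    mode (``community`` maps species id to its full digest sequences) any
    peptide occurring in more than one species' proteome is excluded, so every
    selected peptide is attributable to exactly one species.
    """
    keep = _length_filter(lengths)
    candidates = [p for p in peptides if keep(p)]
    if community is not None:
        membership: dict[str, set[str]] = {}
        for sp, seqs in community.items():
            for s in seqs:
                membership.setdefault(s, set()).add(sp)
        candidates = [
            p for p in candidates if len(membership.get(p.sequence, {p.species})) == 1
        ]
    # deduplicate identical strings, deterministic order
    uniq: dict[str, Peptide] = {}
    for p in sorted(candidates, key=lambda p: (len(p), p.sequence)):
        uniq.setdefault(p.sequence, p)
    ordered = list(uniq.values())
    rng = np.random.default_rng(seed)
    ordered = [ordered[i] for i in rng.permutation(len(ordered))]
    chosen: list[Peptide] = []
    seen: set[frozenset] = set()
    for p in ordered:
        if p.composition in seen:
            continue
        seen.add(p.composition)
        chosen.append(p)
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise PepfluxError(
            f"only {len(chosen)} composition-distinct peptide(s) available, {n} requested"
        )
    return PeptidePanel(chosen, lengths=lengths)


# ---------------------------------------------------------------------------
# peptide MDV


def peptide_mdv(
    seq: str,
    aa_mdvs: Mapping[str, np.ndarray],
    corrections: Mapping[str, CorrectionMatrix] | None = None,
) -> np.ndarray:
    """Convolve residue MDVs into the peptide MDV.

    Dummy residues ``X`` contribute the delta MDV [1, 0] and are inert:
    padding a sequence with X leaves its MDV unchanged apart from trailing
    zeros.  When ``corrections`` is given, each residue's MDV is first mapped
    through its natural-abundance correction matrix (the dummy residue always
    uses the identity).
    """
    residue_mdvs = []
    for ch in seq:
        if ch == DUMMY_RESIDUE:
            residue_mdvs.append(np.array([1.0, 0.0]))
            continue
        if ch not in aa_mdvs:
            raise PepfluxError(f"no MDV supplied for residue {ch!r} in {seq!r}")
        raw = np.asarray(aa_mdvs[ch], dtype=float)
        if corrections is not None and ch in corrections:
            raw = correction_apply(raw, corrections[ch])
        residue_mdvs.append(raw)
    out = convolve_many(residue_mdvs)
    s = out.sum()
    if abs(s - 1.0) > 1e-9:
        raise PepfluxError(f"peptide MDV for {seq!r} sums to {s:.12g}")
    return out / s


__all__ = [
    "CANONICAL_RESIDUES",
    "DUMMY_RESIDUE",
    "Peptide",
    "PeptidePanel",
    "ProteaseRules",
    "digest_proteome",
    "digest_sequence",
    "peptide_mdv",
    "select_panel",
]
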