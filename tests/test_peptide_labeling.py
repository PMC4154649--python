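import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepflux.errors import PepfluxError
from pepflux.mdv import mean_mass
from pepflux.peptide_labeling import (
    Peptide,
    PeptidePanel,
    ProteaseRules,
    digest_proteome,
    digest_sequence,
    peptide_mdv,
    select_panel,
)


def regex_tryptic_split(seq: str) -> list[str]:
    """Independent trypsin oracle: cleave after K/R unless P follows."""
    return [p for p in re.split(r"(?<=[KR])(?!P)", seq) if p]


def poly_product(vectors):
    """Independent polynomial-multiplication oracle (naive double loop)."""
    out = [1.0]
    for vec in vectors:
        new = [0.0] * (len(out) + len(vec) - 1)
        for i, a in enumerate(out):
            for j, b in enumerate(vec):
                new[i + j] += a * b
        out = new
    return np.array(out)


class TestDigestion:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAKAAR", ["AAK", "AAR"]),
            ("AAKPAAR", ["AAKPAAR"]),
            ("KKK", ["K", "K", "K"]),
            ("AAA", ["AAA"]),
        ],
    )
    def test_rule_application(self, seq, expected):
        assert digest_sequence(seq) == expected

    def test_matches_regex_oracle_on_random_proteins(self):
        rng = np.random.default_rng(7)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(50):
            seq = "".join(rng.choice(letters, size=200))
            assert digest_sequence(seq) == regex_tryptic_split(seq)

    def test_missed_cleavages(self):
        assert set(digest_sequence("AAKAAR", ProteaseRules(missed_cleavages=1))) == {
            "AAK",
            "AAR",
            "AAKAAR",
        }

    def test_bad_record_skipped_with_warning(self):
        fasta = ">ok\nAAKAAR\n>bad\nAAZAAR\n"
        with pytest.warns(UserWarning, match="bad"):
            peps = digest_proteome(fasta)
        assert {p.protein for p in peps} == {"ok"}


class TestPanelSelection:
    TABLE1_5AA = ["GWQAK", "LGLQK", "VAASK"]

    def test_published_five_residue_peptides_are_composition_distinct(self):
        peps = [Peptide(s) for s in self.TABLE1_5AA]
        panel = select_panel(peps, 3, lengths=5, seed=0)
        assert sorted(panel.sequences()) == sorted(self.TABLE1_5AA)

    def test_anagram_excluded(self):
        peps = [Peptide("GWQAK"), Peptide("WGQAK")]
        panel = select_panel(peps, 1, lengths=5, seed=0)
        assert len(panel) == 1
        with pytest.raises(PepfluxError, match="1 composition-distinct"):
            select_panel(peps, 2, lengths=5, seed=0)

    def test_community_shared_peptide_excluded(self):
        peps = [Peptide("AAGGK", species="x"), Peptide("AAGVK", species="x")]
        community = {"x": ["AAGGK", "AAGVK"], "y": ["AAGGK"]}
        panel = select_panel(peps, 1, lengths=5, community=community, seed=0)
        assert panel.sequences() == ["AAGVK"]

    def test_deterministic_given_seed(self, toy1):
        peps = digest_proteome(toy1.proteome_fasta)
        a = select_panel(peps, 10, lengths="mixed", seed=42).sequences()
        b = select_panel(peps, 10, lengths="mixed", seed=42).sequences()
        c = select_panel(peps, 10, lengths="mixed", seed=43).sequences()
        assert a == b and a != c

    def test_panel_rejects_shared_composition(self):
        with pytest.raises(PepfluxError, match="share a composition"):
            PeptidePanel([Peptide("AG"), Peptide("GA")])


class TestPeptideMDV:
    AA = {"P": np.array([0.4, 0.6, 0.0])}

    def test_single_residue_identity(self):
        assert np.allclose(peptide_mdv("P", self.AA), [0.4, 0.6, 0.0])

    def test_two_residues_square_the_polynomial(self):
        assert np.allclose(peptide_mdv("PP", self.AA), [0.16, 0.48, 0.36, 0.0, 0.0])

    def test_dummy_padding_is_inert(self):
        aa = {"V": np.array([0.5, 0.3, 0.2]), "L": np.array([0.9, 0.1]),
              "A": np.array([0.7, 0.3]), "Y": np.array([0.6, 0.4]),
              "R": np.array([0.2, 0.8])}
        short = peptide_mdv("VLAYR", aa)
        padded = peptide_mdv("VLAYRXXXXXXXXXX", aa)
        assert len(padded) == len(short) + 10
        assert np.allclose(padded[: len(short)], short, atol=1e-15)
        assert np.allclose(padded[len(short):], 0.0)

    def test_missing_residue_names_it(self):
        with pytest.raises(PepfluxError, match="'Q'"):
            peptide_mdv("PQ", self.AA)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_convolution_properties(self, data):
        """Against the polynomial oracle; order-independent; mean-mass additive."""
        rng_seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rng_seed)
        n_res = data.draw(st.integers(1, 6))
        residues = "AGVSLT"[:n_res]
        aa = {r: rng.dirichlet(np.ones(rng.integers(2, 5))) for r in residues}
        seq = "".join(rng.choice(list(residues), size=rng.integers(1, 8)))
        out = peptide_mdv(seq, aa)
        oracle = poly_product([aa[ch] for ch in seq])
        assert np.max(np.abs(out - oracle)) < 1e-12
        perm = "".join(rng.permutation(list(seq)))
        assert np.allclose(peptide_mdv(perm, aa), out, atol=1e-12)
        assert mean_mass(out) == pytest.approx(
            sum(mean_mass(aa[ch]) for ch in seq), abs=1e-9
        )
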