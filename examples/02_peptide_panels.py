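"""Digest a proteome, pick a composition-distinct panel, convolve a peptide MDV.

Peptide labeling depends only on amino-acid composition (the Cauchy product of
residue MDVs is commutative), so the panel keeps one peptide per composition;
anagrams carry no extra information.
"""

import numpy as np

from pepflux import digest_proteome, peptide_mdv, select_panel
from pepflux.synthetic_data import make_toy_fixtures

toy1 = make_toy_fixtures()["toy1"]
peptides = digest_proteome(toy1.proteome_fasta)
print(f"tryptic digest of the toy proteome: {len(peptides)} peptides")

panel = select_panel(peptides, 5, lengths=5, seed=0)
print(f"5-residue panel: {panel.sequences()}")

aa = {"A": np.array([0.4, 0.6, 0.0]), "G": np.array([0.9, 0.1])}
pep = peptide_mdv("AAG", aa)
print(f"MDV of peptide AAG from Ala={aa['A']}, Gly={aa['G']}:")
print(f"  {np.round(pep, 4)}")
print(f"order-independent: AGA gives {np.round(peptide_mdv('AGA', aa), 4)}")
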