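"""Reference peptide sequences of the INF2 N-terminal extension.

Residue numbering follows full-length human INF2: the 2-19 peptide starts at
residue 2.  The calmodulin-binding site lies in the first N-terminal helix,
with hydrophobic anchors W11, L14 and L18 forming a 1-4-8 motif.
"""

from .motifs import SequenceRecord

#: INF2 residues 2-19, the minimal calmodulin-binding peptide.
INF2_2_19 = SequenceRecord(
    id="human_INF2_2-19", sequence="SVKEGAQRKWAALKEKLG", first_residue_number=2
)

#: INF2 residues 2-36, covering both N-terminal helices (3-17 and 25-31).
INF2_2_36 = SequenceRecord(
    id="human_INF2_2-36",
    sequence="SVKEGAQRKWAALKEKLGPQDSDPTEANLESADPE",
    first_residue_number=2,
)
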