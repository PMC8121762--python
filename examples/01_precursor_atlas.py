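"""Map a peptide onto its prepropeptide and align the mouse/human pair.

Builds the gastrin-like precursor pair from the shipped synthetic study,
locates a peptide by exact match, and projects its interval onto the
human homolog across a global alignment.
"""

from gutpeptidomics import synthetic
from gutpeptidomics.atlas import (
    align_homologs,
    interval_identity,
    map_peptide,
    peptide_name,
    project_interval,
)

cfg = synthetic.SyntheticConfig()
mouse, human = synthetic.generate_precursor_pair(cfg, "Gast")

# the planted candidate occupies prepro positions 59-79
peptide = mouse.sequence[58:79]
((prec, start, end),) = map_peptide(peptide, [mouse])
print(f"peptide maps to {prec.accession} at {start}-{end}"
      f" -> named {peptide_name(prec.gene, start, end)}")

al = align_homologs(mouse, human)
print(f"\nglobal alignment: {len(al.match_line)} columns, "
      f"identity {al.identity:.2f} (| identical, : similar)")
print("mouse", al.aligned_a[:60])
print("     ", al.match_line[:60])
print("human", al.aligned_b[:60])

interval, coverage = project_interval(al, start, end)
ident = interval_identity(al, start, end)
print(f"\nprojection of {start}-{end} onto human: {interval}, "
      f"coverage {coverage:.2f}, identity over span {ident:.2f}")
# coverage 1.0 and high identity mean the human precursor carries an
# equivalent peptide at the same prepro coordinates.
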