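"""Rank peptides as candidate bioactive hormones.

Runs the full pipeline on the shipped synthetic study: ladder filtering,
then scoring of every unique mouse peptide against the four hormone-like
criteria (basic-flanked termini, abundant in both species, conserved,
regulated secretion).  The three planted candidate analogues score 4/4.
"""

from gutpeptidomics import synthetic
from gutpeptidomics.processing import filter_minor_fragments
from gutpeptidomics.scoring import score_candidates, scores_to_frame
from gutpeptidomics.stats import secretion_table

study = synthetic.generate_study()
filtered = filter_minor_fragments(study.mouse_observations)
secretion = secretion_table(study.secretion)
scores = score_candidates(
    study.atlas, filtered, study.human_observations, secretion
)
df = scores_to_frame(scores)

print("rank  peptide            flank abund consv secr  composite")
for _, r in df.head(8).iterrows():
    flags = "".join("x" if r[c] else "." for c in
                    ("basic_flanked", "abundant_both_species",
                     "conserved", "regulated_secretion"))
    print(f"{r['rank']:>4}  {r.peptide_id:<18} {flags[0]:^5} {flags[1]:^5} "
          f"{flags[2]:^5} {flags[3]:^5} {r.composite:^9}")

print("\ncomposite 4 =", sorted(df.loc[df.composite == 4, "peptide_id"]))
print("ground truth =", sorted(study.truth["candidates"]))
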