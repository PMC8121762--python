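"""Classify cleavage termini, cluster exoprotease ladders, filter fragments.

Simulates convertase-style processing of the gastrin-like precursor,
annotates each observed peptide's termini against mono-/dibasic cleavage
rules, groups ladder variants, and applies the 10 %-of-most-abundant
filter per propeptide.
"""

from gutpeptidomics import synthetic
from gutpeptidomics.processing import (
    annotate_observations,
    cluster_ladders,
    filter_minor_fragments,
)

cfg = synthetic.SyntheticConfig()
mouse, _human = synthetic.generate_precursor_pair(cfg, "Gast")
obs = synthetic.simulate_processing(mouse, cfg)
print(f"{len(obs)} observations from {mouse.accession} "
      f"({len(mouse.sequence)} aa, signal 1-{mouse.signal_end})")

for rec in annotate_observations(mouse, obs)[:6]:
    o = rec["observation"]
    print(f"  p{o.start}-{o.end}  N:{rec['n_term_class']:<15} "
          f"C:{rec['c_term_class']:<15} amide:{rec['amidation_status']:<13} "
          f"cluster {rec['cluster_id']}  area {o.peak_area:.3g}")

clusters = cluster_ladders(obs)
print(f"\n{len(clusters)} ladder clusters; canonical members:")
for c in clusters:
    k = c.canonical
    print(f"  cluster {c.cluster_id}: span {c.span}, {len(c.members)} members, "
          f"canonical p{k.start}-{k.end} area {k.peak_area:.3g}")

survivors = filter_minor_fragments(obs, frac=0.10)
print(f"\n10% filter: {len(obs)} -> {len(survivors)} observations "
      f"(minor exoproteolytic fragments removed)")
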