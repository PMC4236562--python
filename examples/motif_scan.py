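"""Scan proteins for diagnostic degenerate motifs.

FADH2-dependent halogenases carry a FAD-binding motif (GxGxxG) and a
tryptophan-binding motif (WxWxIP); Rieske oxygenases carry the [2Fe-2S]
CxH-x(15,17)-CxxH motif; aromatic prenyltransferases of the ABBA family
*lack* the Mg-dependent (N/D)DxxD motif — absence is evidence too.
"""

from hapalocompare import builtin_motifs, scan
from hapalocompare.synthetic import study_preset_config, simulate_cluster_set

records, truth = simulate_cluster_set(study_preset_config(seed=0))
wel = records[5]
patterns = builtin_motifs()

for gene in wel.genes:
    hits = [h for p in patterns for h in scan(gene.protein, p, gene.feature_id)]
    for h in hits:
        print(f"{h.protein_id:<22}{h.motif_name:<14}pos {h.start:<5}"
              f"{h.matched_subsequence}")

p1 = next(g for g in wel.genes if g.product == "P1")
prenyl = next(p for p in patterns if p.name == "prenyl_PP")
print(f"\n(N/D)DxxD in {p1.feature_id}: {scan(p1.protein, prenyl) or 'absent'}")
# the halogenase H reports both FAD- and Trp-binding motifs at the
# positions the generator spliced them in; P1 lacks (N/D)DxxD, consistent
# with a Mg-independent ABBA prenyltransferase.
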