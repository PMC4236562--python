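"""Predict co-transcribed gene blocks from gene orientation.

A maximal run of consecutive same-strand genes is taken as one predicted
transcript; cluster classes differ in how their marker genes attach to
the conserved transcript that starts at C1.
"""

from hapalocompare import predict_transcripts
from hapalocompare.synthetic import study_preset_config, simulate_cluster_set

records, truth = simulate_cluster_set(study_preset_config(seed=0))
for record in (records[0], records[5]):  # an hpi and a wel cluster
    print(f"\n{record.cluster_id} ({truth.class_of[record.cluster_id]}):")
    for t in predict_transcripts(record):
        genes = ",".join(t.gene_labels)
        print(f"  {t.transcript_id}  [{t.strand}] {t.start}..{t.end}  {genes}")
# the conserved 15-gene block C1..C3 stays on a single predicted
# transcript in every class; the wel cluster extends it with orf1/M2 and
# carries its marker genes on the opposite strand.
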