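"""Predict each cluster's product class from its gene complement.

P3 implies ambiguines; any of the wel markers (M1-3, R3, E4, O11-19,
U7/U8) implies welwitindolinones; a cluster with only the shared core is
called hpi.  Missing conserved core genes flag a cluster as putatively
non-functional.
"""

from hapalocompare import classify
from hapalocompare.synthetic import study_preset_config, simulate_cluster_set

records, truth = simulate_cluster_set(study_preset_config(seed=0))
for record in records:
    labels = {g.product for g in record.genes}
    result = classify(record.cluster_id, labels)
    mark = "ok" if result.predicted_class == truth.class_of[record.cluster_id] else "MISMATCH"
    evidence = ",".join(lab for lab, _ in result.evidence) or "-"
    print(f"{record.cluster_id:<18}{result.predicted_class:<5}"
          f"evidence: {evidence:<28}[{mark}]")

# a truncated wel cluster loses core genes and picks up the flag:
partial = {"O18", "O19", "R3", "M2", "T1", "T2", "T3", "T4", "T5",
           "C1", "C2", "C3", "I1", "I2", "I3", "P1", "D1", "D2", "D3"}
result = classify("truncated_wel", partial)
print(f"\ntruncated cluster -> {result.predicted_class}, flags: "
      f"{sorted(result.flags)}, missing core: {list(result.missing_core)}")
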