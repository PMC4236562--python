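"""Homolog families across clusters by the >90% identity rule.

Takes three synthetic clusters (one of each class), aligns every protein
against every other, links pairs above 90% identity (single linkage) and
prints each named family with its identity summary — the quantitative
backbone of a cluster comparison table.
"""

from hapalocompare import assign_families, identity_matrix, name_families
from hapalocompare.pipeline import catalog_from_labels
from hapalocompare.synthetic import study_preset_config, simulate_cluster_set

records, truth = simulate_cluster_set(study_preset_config(seed=0))
subset = [records[0], records[2], records[5]]  # one hpi, one amb, one wel

proteins, cluster_of, products = {}, {}, {}
for record in subset:
    for gene in record.genes:
        proteins[gene.feature_id] = gene.protein
        cluster_of[gene.feature_id] = record.cluster_id
        products[gene.feature_id] = gene.product

matrix = identity_matrix(proteins)
families = assign_families(matrix, threshold_pct=90, cluster_of=cluster_of)
families = name_families(families, catalog_from_labels(subset), matrix,
                         products=products)

print(f"{'family':<8}{'members':>8}{'min%':>8}{'mean%':>8}")
for fam in sorted(families, key=lambda f: f.family_label):
    print(f"{fam.family_label:<8}{len(fam.members):>8}"
          f"{str(fam.min_identity_pct):>8}{str(fam.mean_identity_pct):>8}")
# families present in all three clusters at >92% identity are the shared
# biosynthetic core; P3 (amb only) and the M/R3/E4/O12 block (wel only)
# appear as class-restricted families ('n/a' marks singletons).
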