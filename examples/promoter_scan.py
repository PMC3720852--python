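"""Plant a sigma-28 promoter upstream of a flagellin gene and recover it.

Builds a 30 kb genome with one dispersed fliC gene, writes a sigma-28
-35/-10 pair (17 bp spacer, 69 bp from the -10 element to the start codon)
and an AGGAAA ribosome binding site 9 bp before the start, then scans the
upstream region the way the promoter report does.  The printed spacings
should be exactly the planted ones; the summary table at the end restates
the published per-sigma promoter-to-start distances for the reference
flagellin set.
"""

import flagmet as fm
from flagmet.promoter import LENIENT_POLICY

genome, features = fm.make_genome("demo", 30_000, [], seed=1,
                                  dispersed_genes=[("fliC", 900)])
gene = features[0]
genome = fm.plant_promoter(genome, gene, "taaa", 17, "tcgatat", 69,
                           "AGGAAA", 9, policy=LENIENT_POLICY, seed=2)

up = fm.extract_upstream(genome, gene, 400)
calls = fm.scan_promoters(up.sequence, policy=LENIENT_POLICY, gene_id=gene.id)
rbs = fm.scan_rbs(up.sequence, max_mismatch=2, gene_id=gene.id)

report = fm.promoter_report({gene.id: calls}, {gene.id: rbs})
print(report.to_string(index=False))
print()
print("Planted: -35 taaa, spacer 17, -10 tcgatat, 69 bp to start, RBS AGGAAA at 9 bp.")
print("Every column above should match those values; mismatch columns count")
print("deviations from the Butyrivibrio fibrisolvens consensus (TAAA / MCGATAa).")
print()
print("Published reference flagellins, -10-to-start distances by sigma factor:")
print(fm.summarize_promoter_spacings(fm.load_reference_promoters()).round(1))
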