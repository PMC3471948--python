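"""Summarize similar/different classifications within gene sets (pathways).

Gene sets are defined on mouse identifiers; only members with a mouse-rat
ortholog pair in the translation table contribute rows, mirroring how
pathway-level comparisons are restricted to mappable genes.
"""

import crossexpr as cx

mouse, rat, omap, gene_sets, truth = cx.simulate(cx.SimulationConfig(n_pairs=500, seed=1))
paired, _ = cx.pair_fold_changes(
    cx.compute_fold_changes(mouse), cx.compute_fold_changes(rat), omap
)
labeled = cx.classify_table(paired)

summary = cx.gene_set_summary(labeled, gene_sets, omap)
cols = ["set", "comparison", "measured_size", "similar", "different", "neither"]
print(summary[cols].to_string(index=False))
# 'different' counts the discordantly regulated ortholog pairs inside each
# set; the bundled 'discordant_enriched' set should show many more of them
# than the random set of the same scale.
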