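"""Simulate a two-species embryo study and compute stage-wise fold changes.

The generator emulates the study design: mouse and rat, three cell
populations (morula, blastocyst, ICM), two pooled replicate samples per
stage, log2 intensities on an RMA-like scale. Fold change is the difference
of mean log2 signals between two stages.
"""

import crossexpr as cx
from crossexpr.foldchange import SelectionParams

cfg = cx.SimulationConfig(n_pairs=500, seed=1)
mouse, rat, omap, gene_sets, truth = cx.simulate(cfg)
print(f"mouse: {mouse.n_genes} genes x {len(mouse.samples)} samples; "
      f"rat: {rat.n_genes} genes; ortholog map: {len(omap)} pairs")

fc = cx.compute_fold_changes(mouse)
print(fc.to_frame().head(3).to_string(index=False))

for threshold in (1.5, 3.0):
    for comp in cx.CANONICAL_COMPARISONS:
        n = len(cx.select_genes(fc, comp, SelectionParams(threshold)))
        print(f"|log2 FC| > {threshold:g} in {comp.name}: {n} mouse genes")
# Each count is the number of genes whose mean log2 signal differs by more
# than the threshold between the two stages — the screening criterion used
# before any cross-species comparison.
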