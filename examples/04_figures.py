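"""Draw the three figure types: clustered heatmap, fold-change scatterplot,
and a per-gene expression profile.

Images (PNG + SVG) land in scratch/example_figs; every figure also has a
data-side spec object holding exactly the plotted numbers.
"""

from pathlib import Path

import crossexpr as cx

out = Path("scratch/example_figs")
mouse, rat, omap, gene_sets, truth = cx.simulate(cx.SimulationConfig(n_pairs=500, seed=1))
fc_mouse = cx.compute_fold_changes(mouse)
fc_rat = cx.compute_fold_changes(rat)

heatmap = cx.build_heatmap(fc_mouse, mouse, n=20, out=out / "heatmap_mouse.png")
print(f"heatmap: {len(heatmap.gene_order)} genes "
      f"(union of three top-20 lists), columns {heatmap.sample_order}")

paired, _ = cx.pair_fold_changes(fc_mouse, fc_rat, omap)
labeled = cx.classify_table(paired)
scatter = cx.build_scatter(labeled, "B_vs_M", out=out / "scatter_B_vs_M.png",
                           species_labels=("mouse", "rat"))
print(f"scatter B_vs_M: {len(scatter.points)} points, colors {scatter.color_counts()}")

pair = labeled[labeled["label"] == "different"].iloc[0]
profile = cx.build_profile(pair["gene_a"], pair["gene_b"], mouse, rat,
                           out=out / "profile.png")
print(f"profile {pair['gene_a']}/{pair['gene_b']}: "
      f"mouse means {['%.2f' % v for v in profile.means_a]} over {profile.stages}")
# Red/green/black points are similar/different/neither pairs; the profile
# shows mean log2 expression of one discordant ortholog pair across stages.
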