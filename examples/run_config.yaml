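# Full-pipeline configuration (paths match `crossexpr simulate --seed 1 --out scratch/sim`).
# Thresholds default to 1.5/3 (selection) and 0.2/0.4/0.2 (pattern heuristic).
expression_a: scratch/sim/expression_mouse.tsv
samples_a: scratch/sim/samples_mouse.tsv
expression_b: scratch/sim/expression_rat.tsv
samples_b: scratch/sim/samples_rat.tsv
ortholog_map: scratch/sim/ortholog_map.tsv
gene_sets: scratch/sim/gene_sets.gmt
output_dir: scratch/run
top_n: 20
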