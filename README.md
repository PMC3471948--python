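# crossexpr

Cross-species comparison of preimplantation-embryo gene expression.

## The problem

Mouse and rat embryos pass through the same preimplantation stages — morula,
blastocyst, and the blastocyst's inner cell mass (ICM, the source of
embryonic stem cells) — but the two species differ markedly in how easily
pluripotent cell lines can be derived from them. A direct way to look for
the regulatory differences behind this is to profile gene expression at each
stage in both species and ask, ortholog by ortholog, where the two species'
stage-wise expression changes agree and where they diverge.

`crossexpr` implements that comparison as a tested, reusable library for a
study design with two species, three cell populations, and two pooled
replicate samples per stage, starting from summarized log2 expression
matrices (e.g. RMA output).

## The method

For each species, the log2 fold change of gene *g* between stages is the
difference of mean log2 signals:

    FC(g, s1 vs s2) = mean_log2(g, s1) − mean_log2(g, s2)

over the three canonical contrasts B vs M, ICM vs B, and ICM vs M. Genes are
screened per species at |FC| > 1.5 and |FC| > 3 (log2 scale), with three-set
Venn overlaps across the contrasts, and the union of the three top-20 lists
by |FC| feeds a hierarchically clustered heatmap (Euclidean distance,
average linkage, row-centered values).

Fold changes are then paired across species through an ortholog translation
table (many-to-many links expand to all pairs) and each pair is labeled per
contrast by a concordance heuristic on the log2 scale:

* **similar** (red): |FC_mouse − FC_rat| < 0.2
* **different** (green): |FC_mouse − FC_rat| > 0.4 with both |FC| > 0.2,
  excluding pairs flat in one species
* **neither** (black): everything else

Labels are summarized globally, within gene sets (GMT pathways restricted to
mappable orthologs), and on fold-change scatterplots and per-gene expression
profiles.

A seeded synthetic-data generator (`crossexpr.simulate`) emulates the study
design with planted concordant / discordant / species-specific genes and
noise-free ground-truth labels, so the whole pipeline is testable without
any array data.

## Worked example

```sh
python examples/02_classify_ortholog_patterns.py
```

prints (seed 1, 500 simulated ortholog pairs):

```
paired 485 ortholog pairs (485 map rows, 0 unpaired)
comparison  similar  different  neither  total
    B_vs_M      248         71      166    485
  ICM_vs_B      262         62      161    485
  ICM_vs_M      260         72      153    485
sensitivity: {'similar': 0.655, 'different': 0.968, 'neither': 0.79}
```

Each row partitions the 485 paired orthologs for one stage contrast: 248
pairs change concordantly between morula and blastocyst in the two species,
71 diverge by more than 0.4 log2 units while being regulated in both. The
sensitivities compare the estimated labels against the planted truth: at the
default replicate noise (sd 0.15 log2 units) discordant genes are recovered
reliably (97%), while the strict 0.2-band "similar" call drops to ~65% —
the expected behavior of a thresholded difference of noisy fold changes.

The other examples cover fold-change screening (`01`), pathway summaries
(`03`), and the heatmap/scatter/profile figures (`04`). The same pipeline is
available from the shell:

```sh
crossexpr simulate --seed 1 --out scratch/sim
crossexpr run --config examples/run_config.yaml
crossexpr plot scatter --labeled out/paired_fc.tsv --comparison B_vs_M --out scatter.png
```

## Layout

```
src/crossexpr/      library (datamodel, io, foldchange, crossspecies,
                    simulate, viz, pipeline, cli)
examples/           narrative scripts, one per capability
tests/              pytest suite, incl. property-based acceptance checks
scripts/            acceptance.py
docs/methods.md     model, parameters, numerical choices, limitations
```
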