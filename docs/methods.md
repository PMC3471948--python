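# Methods

## Model and procedure

`crossexpr` compares stage-wise expression changes between two species
sampled at three preimplantation cell populations — morula (M), blastocyst
(B) and the blastocyst's inner cell mass (ICM) — from gene-level log2
expression matrices. The pipeline assumes its inputs are already summarized
and normalized on the log2 scale (the typical output of RMA-style
summarization); the loaders apply no transformation, and any empty or
non-numeric cell is a hard parse error rather than a silently imputed value.

For each species, the per-gene, per-stage mean log2 signal is the unweighted
arithmetic mean over that stage's replicates. With only two pooled replicate
samples per stage there is no usable per-gene variance estimate, so no
moderated test statistic is attempted; the screening statistic is the log2
fold change itself,

    FC(g, s1 vs s2) = mean(g, s1) − mean(g, s2),

over the three canonical contrasts B vs M, ICM vs B and ICM vs M. Because
all contrasts reuse the same stage means, the algebraic identities hold
exactly (to float epsilon): FC(ICM vs M) = FC(ICM vs B) + FC(B vs M),
reversing a contrast negates the FC, and adding a constant to all of a
gene's samples leaves every FC unchanged. These identities are enforced as
property tests.

Per-species screening selects genes with |FC| strictly above a threshold —
canonically 1.5 and 3 on the log2 scale, applied to the absolute value so
both directions of regulation are kept. Overlaps between the three
contrasts' selections are reported as exact counts of the seven exclusive
regions of a three-set Venn diagram. For the global heatmap, the top 20
genes by |FC| are taken per contrast and their union (first-seen order over
the canonical contrast order) forms the row set.

Cross-species analysis joins the two species' FC tables through an ortholog
translation table. Many-to-many links expand to one row per (gene_a,
gene_b) pair — the table does not adjudicate orthology — and an optional
one-to-one filter can drop all shared-gene links. Each pair gets, per
contrast, a pattern label:

* **similar** if |fc_a − fc_b| < 0.2;
* **different** if |fc_a − fc_b| > 0.4 and |fc_a| > 0.2 and |fc_b| > 0.2,
  so that discordance driven by a gene that is flat in one species does not
  count;
* **neither** otherwise, which includes the deliberate gap band
  0.2 ≤ |fc_a − fc_b| ≤ 0.4.

All three thresholds are strict inequalities; boundary values fall to
`neither`. The conditions are symmetric in the two species, and for any
valid parameters (t_different ≥ t_similar ≥ 0) the three labels partition
the plane. Labels are tallied globally, within GMT gene sets (members are
species-A identifiers; only members with an ortholog pair contribute), and
rendered as red/green/black scatterplots.

## Tunable parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| selection thresholds | 1.5, 3 | log2 | per-species |FC| screening |
| t_similar | 0.2 | log2 | maximum FC gap for "similar" |
| t_different | 0.4 | log2 | minimum FC gap for "different" |
| t_min | 0.2 | log2 | minimum per-species |FC| for "different" |
| top_n | 20 | genes | per-contrast heatmap selection |
| one_to_one | off | — | drop many-to-many ortholog links |

The defaults are the analysis's canonical operating point and are also the
defaults filled in by `validate_config`.

## Synthetic-data generator

`SimulationConfig`/`simulate` emulate the two-species, three-stage,
two-replicates-per-stage design. Per gene: a baseline ~ Normal(8, 2) log2
units (an RMA-like intensity scale), per-species stage-effect vectors
determined by the gene's planted class, and i.i.d. Normal(0, noise_sd)
replicate noise (default sd 0.15 log2 units, a realistic magnitude for
pooled-sample array replicates; no variance estimate exists to anchor it, so
recovery is also reported across noise levels). Classes and default mixing
fractions:

* `null` (0.7) — no stage effects in either species;
* `concordant` (0.1) — identical stage-effect vectors, magnitude
  `effect_size` (1.0);
* `discordant` (0.1) — stage effects built so every contrast satisfies the
  "different" conditions with margin: both true |FC| ≥ `min_abs_fc` (0.5)
  and inter-species FC gap ≥ `discordant_gap` (1.0);
* `species_specific` (0.1) — effects in one randomly chosen species only,
  which under the heuristic yields `neither` (regulated contrasts) or
  `similar` (flat contrasts), never `different`.

The ortholog map covers all but `unpaired_fraction` (0.05) of the base
pairs; `many_to_many_fraction` (0.02) extra species-A genes duplicate an
existing species-B partner with identical planted effects, exercising the
expansion policy. Two gene sets are bundled: one enriched in discordant
genes and one uniform random draw. All randomness flows from one seed;
repeated calls are bit-identical.

Expected labels are defined on the noise-free fold changes, so ground truth
is unambiguous and, with `noise_sd = 0`, the pipeline reproduces it exactly.
At the low-noise operating point (sd 0.05, two replicates) the FC-gap
estimator has sd 0.05·√2 ≈ 0.071, giving analytic recovery
P(|gap| < 0.2 | true 0) ≈ 0.995 for `similar` and ≈ Φ(8.5) ≈ 1 for
`different`; `evaluate_recovery` measures both and the acceptance suite
asserts ≥ 0.99.

What the generator does **not** model: probe-level effects, normalization
artifacts, correlated noise between stages, mean-variance dependence,
batch/array effects, or any biological covariance between genes. Passing
tests therefore demonstrate the correctness of the computations and the
behavior of the heuristic under idealized noise — not performance on real
array data.

## Numerical choices

* Clustering: Euclidean distance, average linkage on row-centered values.
  Centering (rather than z-scoring) removes per-gene baselines while
  preserving relative fold-change magnitudes across rows. The distance and
  linkage are recorded in the heatmap spec; figures assert on the data-side
  spec tables, not image bytes.
* Tie-breaking everywhere: |FC| descending, then gene identifier ascending,
  making all selections and unions deterministic.
* Strict inequalities at every threshold; classification of non-finite FCs
  is an error, never a silent label.
* Heatmap columns stay in fixed design order (M1, M2, B1, B2, ICM1, ICM2);
  columns are not clustered. Profile plots use the stage order morula, ICM,
  blastocyst, the convention of the figure type they reproduce, even though
  it is not temporal order.
* Output TSVs render floats at 6 significant digits and contain no
  timestamps; reruns on identical inputs are byte-identical, verified via
  SHA-256 checksums in the run manifest.
* Problem sizes: the test suite and the acceptance script simulate 100–2,000
  ortholog pairs, which is ample for the planted-class recovery rates being
  measured while keeping any single run under a few seconds.

## Design decisions

* The ortholog TSV dialect requires a header row which is always skipped —
  a documented convention instead of fragile content-based auto-detection.
* Gene identifiers are opaque text; no namespace validation beyond
  non-emptiness.
* A pair measured in only one species is excluded from cross-species tables
  (scatterplots need both coordinates) but its gene remains in all
  within-species outputs; the drop is counted in the coverage report.
* Classification is per contrast, independently; no composite
  multi-contrast label is defined.
* The `species_specific` simulation class plants the asymmetric case the
  `t_min` condition exists for, so tests exercise that exclusion directly.

## Known limitations

* No statistical inference: with two replicates per stage the pipeline
  screens by effect size only; labels carry no error rates, and threshold
  choices are conventions, not estimated operating points.
* The pattern heuristic's strict thresholds make calls near boundaries
  sensitive to noise (see the ~65% `similar` sensitivity at noise sd 0.15 in
  the worked example); the gap band exists precisely to absorb ambiguous
  cases into `neither`.
* Many-to-many ortholog expansion counts a gene once per pair, so summary
  counts are pair counts, not distinct-gene counts.
* The heatmap's dendrogram depends on the adopted distance/linkage
  convention; alternative conventions reorder leaves but leave the row set
  (the asserted surface) unchanged.
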