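# Methods

This note documents the models and numerical choices behind tumortalk:
what each stage assumes, which knobs matter, what the synthetic cohorts
do and do not emulate, and where the design was genuinely open.

## Synthetic cohorts

The generator (`tumortalk.synthetic`) emulates a multi-sample treated
vs. vehicle tumor scRNA-seq study. Each sample draws its cell-type
composition from a multinomial over configured fractions (defaults: a
cancer-cell-dominated mixture of seven types — cancer, CD8⁺ T, Treg,
NK&T, macrophage, cDC, pDC — with treatment raising the CD8⁺/NK&T and
dendritic fractions). Counts are negative binomial,

    mu(g, c) = baseline_mean · marker_fold^[g marks type(c)]
               · program_fold^[g in type(c)'s program]
               · profile fold · effect fold · lib(c),
    Var = mu + dispersion · mu²,

with a per-cell lognormal library factor (E = 1, CV
`library_size_cv`). Defaults: `baseline_mean = 5` (≈1,200 UMIs over the
~250-gene universe, i.e. the per-gene depth of a well-covered targeted
panel), `dispersion = 0.3`, `library_size_cv = 0.2`.

Three layers of structure ride on the baseline:

* **Markers** (`marker_panel`, fold 8): the named identification genes
  (Wnt10a, Cd8a, Foxp3, Cd3e/Klrb1a, C1qc, H2-Aa, Klk1b27), elevated
  only in their own type. These are what the annotator reads.
* **Identity programs** (`program_genes_per_type = 20`, fold 5): each
  type additionally up-regulates a dedicated gene block. Real cell
  types differ by coordinated programs of tens to hundreds of genes,
  not by a lone marker; without this layer no clustering method could
  separate a 2% cell type from sampling noise at realistic depth, and
  the simulation would misrepresent the problem it emulates.
* **Condition-independent type profiles**: checkpoint and cytokine
  genes enriched in their physiological compartments (Pvr/Tgfb1 in
  cancer cells; Cd226, Cd96, Tigit, Ccr5, Tgfbr1, Il15ra in CD8⁺ T
  cells; Il15, Ccl4, Tgfb1 in macrophages; ...). This is what makes
  ligand–receptor pairs *enriched in every group* — the conserved-
  interaction phenomenon — rather than only under treatment.

Treatment effects are multiplicative on the mean (`effect_table`), and
truly coupled ligand–receptor quadruples (`coupled_pairs`) are recorded
in the ground truth. The default effect sizes (Pvr ×2 in cancer cells
and Cd226 ×2, Cd96 ×0.5 in CD8⁺ T cells under treatment) are free
parameters chosen once at qRT-PCR-scale fold changes; no published
per-gene magnitudes exist for them.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` substreams (one per sample), so cohorts are
byte-identical across runs and machines with the same numpy.

**What the generator does not emulate:** genome-scale gene universes,
doublets, ambient RNA, batch effects, spliced/unspliced layers, or
depth gradients between samples. Passing tests therefore show that the
pipeline's logic is correct under its stated statistical model — not
that it is robust to every artifact of real droplet data.

Auxiliary generators produce MAF-like mutation tables (classes drawn
uniformly within the truncating / non-truncating taxonomies),
exponential-growth caliper series with lognormal measurement noise
(diameters back-derived with a = b so V = 0.5ab² is exact), and
exponential survival times with independent exponential censoring
calibrated so the expected censored fraction equals `censor_rate`.

## Single-cell preprocessing

QC keeps cells with total counts ≥ `min_counts_per_cell`, detected
genes ≥ `min_genes_per_cell`, and mitochondrial fraction ≤
`max_mito_fraction`. Defaults (500 / 200 / 0.2) follow droplet-data
practice; the synthetic studies set them explicitly (300 / 100 / 0.5)
to match the generator's depth. The filter is idempotent and reports
per-criterion removal tallies; removing every cell is an error, not an
empty result.

Normalization is per-10⁴ depth scaling followed by log1p. Mitochondrial
content is handled by the QC fraction filter rather than regression.

Clustering: per-gene z-scores (capped at ±10 so no single gene
dominates the metric), PCA to 7 components (deterministic full-SVD
solver), a symmetrized Euclidean 15-NN graph, and Leiden modularity
optimization (RBConfiguration, resolution 1.0, fixed seed, iterated to
convergence). Labels are contiguous from 0 in order of first
appearance. A zero-variance embedding (all cells identical) returns a
single cluster rather than handing a degenerate graph to the
partitioner. Resolution and k are exposed because no principled
defaults exist — over-segmentation is harmless for annotation since
clusters are labelled independently.

Annotation: score(cluster, type) = mean over the cluster's cells of the
mean expression of that type's markers; assignment is the argmax.
Exact ties (≤ 1e-12) yield `unassigned` and a tie flag — never an
arbitrary choice — and markers missing from the gene universe are
excluded with a warning (a type with no present markers is
unscoreable). Re-clustering a subset (e.g. T cells only) reuses the
same operators via the CLI `--subset cell_type=...` flag.

## Interaction scoring

The score is the product of the mean normalized ligand expression over
sender cells and the mean normalized receptor expression over receiver
cells — the unique symmetric scalar combining exactly those two
quantities, and bilinear in each factor's mean. Cell types with fewer
than `min_cells = 10` cells yield a flagged-missing score (NaN), never
zero: absence of evidence is distinguished from evidence of absence.

Significance is a label-permutation null: cell-type labels are shuffled
within each sample, the score recomputed B = 1000 times, and
p = (1 + #{null ≥ observed}) / (1 + B), so p ∈ [1/(B+1), 1] and the
test is exact-level by construction. The batch scorer shares one label
shuffle across all pairs per iteration, which preserves the marginal
null of each pair while making 50+ pairs affordable.

Group aggregation: per-sample scores are averaged within each
(model, condition) group; per-sample p-values combine by Fisher's
method into a group p. Fisher was chosen over alternatives (min-p,
Stouffer) because per-sample permutation p-values are independent and
super-uniform under the null, making the combination conservative and
simple; with a single sample per group it reduces to that sample's p.
A pair is `conserved` when the group p ≤ α and the ligand/receptor are
expressed (detected in ≥ 10% of sender/receiver cells) in every group;
since "conserved" could also mean mere presence everywhere, a
`present_all` flag is emitted alongside. Ranking is by descending group
mean, ties broken by smaller p then lexicographic pair id.

Expression input, the percent-expressed gate, α, B and `min_cells` are
all configuration, not constants.

## Composition

Fractions are exact counts over retained cells, with zero rows for
types absent from a sample. The between-condition test permutes
condition labels across samples (the sample, not the cell, is the
exchangeable unit — cells within a tumor are not independent):
exhaustively when C(n, n_a) ≤ 20,000, with the identity arrangement
counted in both numerator and denominator, otherwise Monte Carlo with
the add-one estimator. With 3 vs 3 samples the smallest attainable
two-sided p is 2/20 = 0.1 — small designs cannot reach 0.05, which is a
property of the design, not the test.

## Cohort metrics

Variant classes follow MAF spellings, matched case-insensitively with
an extensible synonym table. TMB = 2·truncating + 1·non-truncating;
silent/UTR/other classes are excluded (contributing 0) rather than
counted as non-truncating, and the raw weighted count is reported with
no per-megabase denominator. Median stratification sends ties to the
high group, deterministically; constant vectors are an error.

Kaplan–Meier estimation and the two-group log-rank test are delegated
to lifelines and validated in the test suite against independently
coded product-limit and observed-minus-expected oracles. Hazard-ratio
estimation and Cox regression are out of scope.

## Preclinical metrics

V = 0.5ab² with a ≥ b enforced; TGI% per the mean-volume-increment
formula with day 0 anchored at the first measurement day common to both
arms. Animals missing either endpoint are excluded from both means
(complete case, logged). A flat vehicle arm makes TGI undefined and is
raised as an error rather than returned as ±inf. Growth curves convert
to endpoint-survival tables by thresholding at a configurable volume
(default 2000 mm³).

## Validation studies and problem sizes

`tumortalk.validation` fixes the study conditions used by the test
suite and the reproduction script: interaction recovery over 20 seeded
cohorts of 4 samples × 2 conditions × 1,500 cells with one planted
coupling (ligand ×4, receptor ×3) among 50 decoy pairs at B = 1000;
permutation-test calibration over 500 replicates of 200
label-exchangeable cells at B = 199 (a grid where p ≤ 0.05 is exactly
attainable); annotation recovery on the default 6 × 2,000-cell cohort;
log-rank calibration over 500 replicates of 20-per-arm exponential
cohorts at hazard ratio 1. Within each calibration replicate the data
stream and the permutation stream are independent substreams of the
replicate seed, so the null draws are not a function of the data.

## Known limitations

* The interaction score ignores expression covariance within cells and
  complex/multi-subunit ligands; it is a means-only statistic.
* Fisher-combined group p-values assume independent samples; technical
  replicates of one tumor would violate this.
* The Leiden partition is deterministic per seed but not guaranteed
  stable under near-tie modularity landscapes; well-separated types (as
  generated) are unaffected.
* TMB uses mutation counts only — no per-megabase normalization and no
  panel-size correction — so values are comparable only within a
  consistently processed cohort.
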