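# Methods

## The statistic

Animal DNA methylation targets CpG dinucleotides, and methylated cytosines
deaminate to thymine far more often than unmethylated ones.  Over evolutionary
time this erodes CpG sites wherever the germline is methylated, so the
observed/expected CpG ratio of a sequence,

    CpG_o/e = P_CpG / (P_C · P_G),

is a sequence-only proxy for historical methylation: values well below 1 mean
a methylated history, values near 1 an unmethylated one.  TpG_o/e (computed
identically with T in place of C) rises where CpG fell by deamination and is
used as corroboration.

The denominators are not uniquely defined by the formula, so the package
fixes a convention: `P_CpG = N_CpG / W_eff` where `W_eff` counts overlapping
dinucleotide windows whose two bases are both unambiguous, and
`P_C = N_C / L_eff`, `P_G = N_G / L_eff` over unambiguous bases.  This is the
standard window-count convention and behaves exactly on short sequences.
Ambiguous bases (IUPAC codes, N) are masked from every count; U is read as T;
input is uppercased.  A ratio whose preconditions fail (no C, no G, or no
usable window) is *undefined* and the gene is excluded with a recorded
reason — never coerced to 0.

Filters follow the survey design they implement: genes shorter than 300 bp
are excluded ("shorter than 300" read literally, so 300 bp passes); CpG_o/e
values above a ceiling (default 2.0, short-gene tail artifacts) are retained
and flagged in per-gene output but dropped before density estimation,
mixture fitting and binning.

## Modality calling

A species with gene body methylation restricted to part of the gene
complement shows a mixture of a low-CpG_o/e and a high-CpG_o/e gene class.
Two procedures estimate the number of components, and both are always
reported side by side because they are known to disagree on real data:

* **KDE mode counting.**  Gaussian-kernel density on a 512-point grid over
  [0, ceiling], bandwidth by the Silverman rule of thumb
  0.9·min(sd, IQR/1.34)·n^(−1/5).  A local maximum is a mode iff its height
  is ≥ 5% of the global maximum, its basin holds ≥ 5% of the probability
  mass, and it lies ≥ 0.10 CpG_o/e units from a taller retained mode.  All
  three stringency thresholds are parameters, because criteria tuned on one
  clade are routinely too strict or too lax on another; dropping a mode
  merges basins, so the mass criterion is iterated to a fixed point.
* **Gaussian mixtures by EM.**  Univariate mixtures with unequal component
  variances, k = 1..5, each fitted as the best of 20 k-means++-seeded EM
  restarts; BIC = −2·loglik + (3k−1)·ln n selects k, ties broken toward the
  smaller k (parsimony).  The unequal-variance family is fixed because the
  empirical component spreads plainly differ.  Convergence is declared when
  the relative log-likelihood change falls below 1e-6 (the log-likelihood
  scales with n, so an absolute test would never fire); component standard
  deviations are floored at 1e-3 after one re-seed attempt, and every fit
  records its log-likelihood trace, which is non-decreasing by construction.

Labels map component counts as 1 → unimodal, 2 → bimodal, ≥3 → multimodal;
species with fewer than 50 usable values are `not_assessed`.  Per-species
seeds are derived from the master seed and a CRC of the species name, so a
species' call does not depend on which other species are in the panel.

## Cross-species comparison

Each species is summarised as a normalised histogram of per-gene CpG_o/e on
shared edges (default width 0.05 over [0, 2] — fine enough to resolve mode
structure at a few thousand genes) plus the unbinned mean.  Species are
clustered agglomeratively (average linkage) on Euclidean or correlation
distance between histograms; the exact binning and metric of the original
heatmap analysis are unstated, so these are declared defaults, configurable,
and the planted-structure recovery test must pass under both metrics.
Profiles are sorted by species name before the distance matrix is built,
making the dendrogram permutation-invariant with deterministic tie-breaks.
Heatmap rendering is a presentation by-product, not a tested contract.

The packaged `table1.tsv` transcribes the published 76-species survey
(7 classes, 21 ordinal groups, mean gene-body CpG_o/e, 14 repeat means,
methylation-machinery absence flags); `table2.tsv` transcribes the published
ten-species ortholog contrast.  `panel_summary` reports the structural
counts, extremes and the count of species below the conventional 0.75
substantial-methylation cutoff.  Counting the printed (rounded) table means
gives 39 species strictly below 0.75; the survey text reports 41, a
difference attributable to rounding of the underlying per-species means.

## Ortholog contrasts

Orthology is consumed, not inferred, in the Orthofinder `Orthogroups.tsv`
dialect.  "n-way shared" genes are those in orthogroups represented (≥ 1
gene) in every panel species; a single-copy mode (exactly one gene per
species) is provided for pairwise analyses.  Per species, shared vs
remaining passing genes are contrasted with a Welch two-sample t-test
(two-sided, Satterthwaite df, no multiple-testing correction — raw p-values
are the convention for this analysis).  A complementary Fisher exact test
asks whether shared genes are enriched below a CpG_o/e threshold (species
median by default; a fixed threshold such as 0.75 is available), reporting
the sample odds ratio with a Haldane 0.5 correction when a cell is zero.

## Repeats

Repeat elements (BED, 0-based half-open) are scored like gene bodies on the
forward strand (CpG_o/e is reverse-complement invariant, so strand cannot
matter) after three filters, all strict inequalities by a literal reading of
the survey design: length > 50 bp, family copy number > 10, and zero overlap
with any gene interval (one shared base disqualifies).  Copy number is a
property of the family's abundance in the input annotation, counted before
any other filter, which makes the three filters order-independent.  The
per-species mean is an unweighted per-element average (length-weighted is
available); repeat content is the union coverage of intervals divided by
genome length.  Panel contrasts report the per-species sign of
(mean repeat − mean gene body) with ties flagged, and Pearson correlations
(r, t = r·√(n−2)/√(1−r²), two-sided p) with named outlier species excluded
by name before computation and logged.

## The synthetic generator

The generator is the forward model of the process the statistic inverts,
and its defaults are the package's study conditions:

* genes are i.i.d. base strings with P(C) = P(G) = gc/2 (default gc = 0.4,
  typical of invertebrate transcriptomes), lengths lognormal(μ=7.3, σ=0.4)
  truncated to [300, 20000] bp (median ≈ 1.5 kb) or uniform;
* a fraction π (default 0.5) of genes is methylated; each CpG of a gene is
  converted independently with the class decay probability (defaults
  d_m = 0.5, d_u = 0), and a conversion becomes TpG (C→T) or CpA (G→A) with
  equal probability — the two deamination footprints — keeping the statistic
  strand-symmetric while producing the corroborating TpG enrichment;
* the scan is a single left-to-right pass over the CpG positions of the
  input; conversions cannot create CpGs, so re-eligibility never arises, the
  Hamming distance to the input equals the conversion count, and d = 1
  removes every CpG;
* repeat landscapes are assembled from background, planted gene intervals
  and repeat families (a master sequence per family, copies with 5%
  substitution divergence, decayed at the family rate), with copy counts
  rescaled so realized coverage lands within ±0.02 of the target fraction;
* panels tag a configurable fraction of genes into cross-species
  orthogroups, drawing members from the methylated pool with probability
  `bias` (1 plants the conserved-genes-are-methylated association, 0 plants
  independence), and a configurable fraction of orthogroups is complete
  (all species) so n-way recovery has negatives to reject.

Everything is driven by one seed; identical parameters and seed give
byte-identical output.  Per-gene truth (class, conversion count, pre/post
CpG_o/e) is emitted so every planted quantity used in tests comes from the
truth table, not from re-reading sequences.

A consequence of the decay model worth stating precisely: the expected
class-mean post/pre CpG_o/e ratio is *not* (1−d).  Each conversion also
removes a C or a G, shrinking the expectation's denominator, so the ratio is
(1−d)/(1−d·P_CpG/(2·P_C))², ≈ 0.554 at d = 0.5, gc = 0.4 (a 10⁷ bp pilot
run of the generator gives 0.5549).  The decay-recovery test asserts against
this pilot-derived expectation.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: selection on gene content, indels, codon
structure, GC heterogeneity along genes, phylogenetic correlation between
species parameters, and partial or tissue-restricted methylation (the decay
probability is a single per-class constant).  Recovery results on synthetic
panels demonstrate that the estimators invert the stated forward model, not
that the forward model captures any particular genome.

## Pipeline and problem sizes

`run_panel` composes the stages from one YAML config with species-level
fault isolation (a failing species is dropped with a logged reason; panel
stages re-check their minimum counts) and writes a manifest of parameters,
seeds and per-stage attrition sufficient to reproduce every output number.
TSV outputs are deterministic functions of inputs, config and seed.

The shipped verification suite and `scripts/acceptance.py` use desk-scale
problem sizes chosen to make the statistical checks decisive at a few
minutes of CPU: 2000 genes × 1.5 kb for the 20-replicate modality study,
500–800 genes for calibration and ortholog panels, 150 kb genomes for
repeat landscapes, and full Fisher-vs-enumeration agreement for all 2×2
tables with n ≤ 40.

## Known limitations

* The KDE stringency defaults (0.05/0.05/0.10) are this package's
  declarations, not a reconstruction of any published tool's criteria.
* BIC on finite mixtures of non-Gaussian class distributions (the per-gene
  ratio is a ratio of counts) can legitimately prefer k ≥ 3 on very large
  real samples even when two biological classes exist; this is the known
  oversensitivity of mixture-model component counts, and the reason both
  modality verdicts are reported without merging.
* The two-sided Fisher p-value is discrete and conservative; its null
  distribution approaches uniformity only for large margins (the calibration
  test uses 2000 genes per replicate).
* Mean repeat CpG_o/e from the fixture table is compared as printed
  (2 decimals); correlation statistics recomputed from it differ slightly
  from values computed on unrounded per-species means.
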