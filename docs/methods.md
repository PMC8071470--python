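# Methods

## The gene set regularity (GSR) model

For a gene set $G = \{g_1, \dots, g_m\}$ with $m \ge 2$ genes measured in
the expression matrix, each sample $s$ is encoded as the binary vector of
its $\binom{m}{2}$ pairwise order comparisons

$$b_{ij}(s) = \mathbf{1}\{e_{g_i}(s) < e_{g_j}(s)\}, \qquad i < j,$$

where $e_g(s)$ is the expression of gene $g$ in sample $s$.  The **rank
template** of the set is the per-pair majority bit over the control group —
the most common expression ordering of the set in the normal state — with
per-pair *support* equal to the fraction of controls voting 1.  The **GSR
index** of sample $s$ is the fraction of its pair bits that agree with the
template:

$$\mathrm{GSR}(s, G) = \frac{1}{\binom{m}{2}} \sum_{i<j}
   \mathbf{1}\{b_{ij}(s) = t_{ij}\} \in [0, 1],$$

so 1 means the set's internal ordering in $s$ is exactly the control
consensus and 0 means it is exactly opposite.  This is a modification of
the differential rank conservation (DIRAC) framework: the template is
derived from the control phenotype only, and the per-sample matching score
is used directly as the index rather than being folded into DIRAC's
phenotype-vs-phenotype rank-difference classifier.  The **functionome** of
a cohort is the samples × sets matrix of GSR indices over all retained
sets.

Because the encoding only compares values within one sample, the statistic
is invariant to any strictly increasing per-sample transform.  This is the
property that makes multi-platform compendia analyzable without
normalization: harmonization reduces to aligning gene symbols and
column-concatenating (`data_io.harmonize`), and the package deliberately
applies no cross-platform scaling or batch correction.

### Conventions and degenerate cases

- **Ties within a sample** ($e_{g_i} = e_{g_j}$): resolved by ascending
  gene-symbol order, making the comparison a strict total order and the
  whole pipeline deterministic.  Randomized tie-breaking would make
  functionomes irreproducible across runs.
- **Template ties** (support exactly 0.5): the template bit is 1.  The
  choice is arbitrary but fixed; flipping it relabels matched/unmatched
  symmetrically on those pairs.
- **Set retention**: sets with fewer than two genes present in the matrix
  have no pairs and are excluded; every exclusion is recorded in a skip
  log, and the run manifest reports both raw and retained set counts.
- **Control scoring**: controls are scored against the template built from
  all controls, themselves included.  The self-vote biases control indices
  slightly upward on low-support pairs, but the alternative — scoring each
  control against a template rebuilt from the remaining $n-1$ controls —
  makes control and case scores incomparable (they face templates of
  different resolution) and measurably *over*-rejects under the null in
  our calibration test, so self-inclusive scoring is the default and
  leave-one-out is an option flag (`leave_one_out=True`).

## Synthetic cohorts

The generator (`functionome.synthetic`) emulates the structure the
analysis assumes, not microarray physics:

- **Controls**: a latent baseline score per gene, drawn once per cohort
  from $\mathcal{N}(0,1)$, plus i.i.d. per-sample Gaussian noise
  (`noise_sd`, default 0.3).
- **Cases**: identical, except that a fraction `planted_fraction` of gene
  sets is dysregulated.  Because the GSR statistic is purely ordinal, a
  mean shift that preserves ordering is invisible to it; dysregulation is
  therefore planted by *permuting* the latent scores of the set's genes.
  The permutation is drawn uniformly over inversion tables with exactly
  $\mathrm{round}(\texttt{scramble\_strength} \cdot \binom{m}{2})$
  inversions (Lehmer-code construction), so the requested strength is the
  exact pre-noise fraction of inverted pairs: strength 0 is the identity
  and strength 1 the full reversal, which forces GSR = 0 under zero noise.
- **Noise after planting**: per-sample noise is applied after the
  permutation, so the realized inversion fraction seen by the statistic is
  noisier than requested; the exact pre-noise realized fraction per
  planted set is recorded in the truth object.
- **Overlap leakage**: sets are sampled independently from the gene
  universe (default 200 sets × 10 genes from 1000 genes), so genes can
  belong to several sets.  A gene shared between a planted and an
  unplanted set genuinely moves the unplanted set's ordering too — the
  unplanted set *is* partially dysregulated, mirroring how overlapping GO
  definitions propagate real signals.  Significance counts on synthetic
  cohorts therefore exceed the planted count by design; recovery tests
  score recall of planted sets, not precision against them.
- **Platform scales** (`platform_scales=True`): an optional per-sample
  strictly increasing transform $x \mapsto e^{ax+b}$, $a \sim U(0.5, 2)$,
  $b \sim \mathcal{N}(0,1)$, emulating arbitrary intensity scales.  It
  changes no rank statistic, which is itself a tested invariant.
- All randomness flows from one seed through named substreams (collection,
  planting, baseline, control noise, case noise, scales, ontology), so
  each artifact is independently reproducible and cohorts are bit-identical
  under a fixed seed.

What the generator does **not** emulate: realistic intensity
distributions, probe-level effects, batch structure, correlated noise, or
biologically coherent set definitions.  Passing tests on these cohorts
show that the machinery detects and classifies *ordinal* dysregulation at
the configured strengths and sample sizes; they say nothing about effect
sizes in real tumor compendia.

## Dysregulation calling

Per gene set, a two-sided Mann–Whitney U test compares case vs control GSR
indices; per gene, the same test compares expression rows (DEGs).  The
exact null distribution is used when both groups have ≤ 8 observations and
no ties; otherwise the tie-corrected normal approximation with continuity
correction (SciPy's implementation in both branches; the exact branch is
cross-checked against full enumeration in the tests).  Multiplicity is
handled by Benjamini–Hochberg step-up FDR (statsmodels), with significance
declared at $q < \alpha$, $\alpha = 0.05$ by default; a flag thresholds
raw p instead.  Direction (sign of the case−control median difference) is
recorded but never used for filtering.  Under the generator's null
(nothing planted) the realized per-set type-I error at raw $p < 0.05$ sits
near the nominal level (the acceptance suite requires $[0.03, 0.07]$ over
20 seeds × 200 sets).

The immunohistochemistry quantification score is the product
$Q = I \times P$ of staining intensity $I \in \{0,1,2,3\}$ and percentage
of positive cells $P \in [0,100]$, maximum 300.

## Ontology clustering and the cluster weight index

Significant terms are grouped in the is_a DAG (only is_a edges are used;
part_of is ignored).  Each significant term is assigned to the cluster
headed by its **highest significant ancestor**: a significant term with no
significant strict ancestor of its own.  A term with no significant
ancestor heads its own cluster; terms absent from the ontology are
singletons.  In a DAG a term can have several highest significant
ancestors; the one with the smallest raw p (then smallest id) is chosen,
making the partition deterministic and input-order independent.  Cluster
weight is $\sum_{\text{members}} -\log_{10} p$ (p floored at $10^{-300}$),
and the cluster weight index (CWI) is the cluster's share of total weight,
so CWIs sum to 1 and rank clusters by relevance; $1-p$ weighting is
available behind a flag.  Ranking is by descending CWI with ties broken by
the head term's raw p, then id.

These are interpretations: "cluster in the GO tree" and "a weighted ratio
based on the p-values" admit several readings (subsumption groups,
GO-slim mapping; $-\log p$, $1-p$), and the choices here were made for
determinism and simplicity.  The cross-group common-term table intersects
each group's top-k cluster heads (k = 50 by default) and orders the
intersection by ascending mean within-group rank — again one reading of an
underspecified "combined order"; the common-term count is an outcome, not
a parameter.

The package ships a curated category map assigning 41 GO terms recurrently
dysregulated in borderline ovarian tumours to four functional categories
(immune/inflammatory: 3, membrane/transporter: 9, cell cycle/signaling:
16, cell metabolism: 9, plus 4 uncategorized).

## Classification

Case-vs-control classification of functionome rows uses an RBF-kernel SVM
(unit cost, `gamma="scale"`), the scikit-learn analogue of the kernlab
defaults commonly used for this task.  GSR features are used as-is (they
already live in [0,1]).  Folds are stratified by class — the cohorts of
interest are heavily unbalanced (down to 13 cases vs 136 controls) and
unstratified folds could lose a class entirely — and the k-fold split is
repeated (default 5 folds × 10 repeats) with seeded shuffles.  Per repeat,
out-of-fold predictions are pooled into one confusion matrix giving
sensitivity, specificity and accuracy, and one AUC is computed from the
pooled decision scores; the report carries means and SDs (ddof = 1) over
repeats.  Per-repeat-averaged AUC was chosen over pooling scores across
repeats; with constant decision scores the AUC is defined as 0.5.

## Representative-gene selection

For a category of GO terms, genes annotated to the category's sets are
intersected with genome-wide significant DEGs and ranked by repetition —
the number of category sets containing the gene — with ties broken by the
smallest DEG q, then gene id.  DEGs are computed genome-wide once, not per
set.  The size of the reported list is a parameter (`top_k`); fixed-size
published lists of this kind reflect unstated cutoffs, so no cutoff is
hard-coded.

## Problem sizes and runtimes

The shipped analysis uses 92 cases (79 + 13 across two synthetic subtypes)
vs 136 shared controls, 200 sets of 10 genes over 1000 genes — the shape,
scaled to set count, of a mid-sized multi-series compendium.  Calibration
and recovery tests use 30 vs 30 samples over 20 seeds.  Every script and
the full test suite run in seconds on one CPU; the dominant cost, pair-bit
computation, is $O(\text{sets} \times m^2 \times \text{samples})$ and
vectorized per set.

## Known limitations

- The GSR index ignores the magnitude of expression differences entirely;
  sets whose genes move coherently without reordering are invisible.
- Self-inclusive control scoring makes control means depend on control
  heterogeneity; control GSR means below 1 are expected, not an error.
- The clustering rule, cluster weight, and combined-order definitions are
  documented interpretations, configurable but not canonical.
- Gene symbols are matched case-sensitively with no alias resolution;
  probe-to-symbol collapse takes the per-sample maximum.
- The synthetic generator's planted permutations are shared by all case
  samples of a cohort (one dysregulated state per set), which is the
  easiest case for both the set test and the classifier; heterogeneous
  per-sample dysregulation would be harder and is not modelled.
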