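# Methods

`hbxprof` implements a family-level survey of expression specificity for a
panel of genes — designed around the homeobox superclass, whose ~240 human
and ~280 mouse members are annotated into 11 evolutionary classes (ANTP,
PRD, LIM, POU, HNF, SINE, TALE, CUT, PROS, ZF, CERS) — across a mixed set
of adult tissues, cell types and developmental stages. This note records
the model, the defaults and the design choices a maintainer would want to
know.

## Expression calling

The analysis substrate is a genes x samples matrix of FPKM-equivalent
values, all finite and non-negative. Low FPKM values are dominated by
spurious and background read counts, so every value below a threshold is
set to zero and all downstream expressed/silent logic is binary on this
*called* matrix.

- `threshold` (FPKM, default **2.0**): the background cut-off. A gene with
  FPKM exactly 2.0 counts as expressed under the default comparison
  `cmp="ge"`; `cmp="gt"` is available because the literature uses both
  conventions and with values exactly at the boundary they give different
  gene lists. The threshold must be positive.
- Calling is idempotent and monotone in the threshold. No between-sample
  normalization (quantile, TMM, ...) is applied: FPKM is already a
  within-sample rate, and cross-sample comparisons here are only ever of
  the binary expressed/silent calls or of shapes of per-gene profiles.

## Per-gene max-normalization

Each called row is divided by its maximum, mapping profiles into [0, 1]
with row maximum exactly 1 — or all zeros for a silent gene, which is kept
(silent genes form their own expression group downstream) rather than
raising an error. Normalization is applied to the *called* matrix, not the
raw one, so sub-threshold noise cannot shape a profile.

## Profile clustering and expression groups

Genes are clustered agglomeratively on their normalized profiles.
Defaults: **Pearson-correlation distance, average linkage** — the standard
pairing for expression heatmaps, chosen because profile *shape*, not
amplitude, defines an expression group. Euclidean distance and
complete/ward linkage are available.

Correlation is undefined on constant rows. Pairs involving a constant row
are assigned the maximal correlation distance (2.0) unless the two rows
are identical (distance 0); an all-constant matrix is an error directing
the user to euclidean distance. The effect is that silent genes merge at
height 0 and attach to the rest of the tree last — deterministic and
sensible.

The tree is cut with `cut_tree` into exactly `k` groups (or by height).
`k` is a user parameter: heatmap-derived groupings have no canonical cut,
and published analyses of this kind resolve roughly half a dozen
macro-groups on a whole-body panel, hence the workflow default `k = 6`;
the synthetic panel plants 8 archetypes and is analysed at `k = 8`. Cuts
at `k` and `k+1` are nested refinements, and clustering is invariant under
row permutation up to relabelling.

Group labels are assigned after cutting, in order of precedence:

1. all member rows all-zero -> `no_expression`;
2. median member breadth >= 90% of samples -> `widespread` (the labelling
   vocabulary needs a widespread category, but a dominant-peak rule alone
   can never produce one — broad genes peak all over the panel — so a
   breadth rule is used; the 0.9 fraction matches the widespread
   classifier below);
3. otherwise the most frequent sample-annotation group among the members'
   sites of maximal expression; ties go to the lexicographically first
   label and are flagged ambiguous. Duplicate labels get `_2`, `_3`
   suffixes.

## Breadth and class specificity

*Breadth* — the number of samples in which a gene is called expressed —
is the specificity statistic; no tau/Gini/entropy index is computed.
Breadth is invariant under max-normalization and sample permutation, and
its gene-wise sum equals the sample-wise sum of expressed-gene counts
(both count expressed (gene, sample) pairs); that identity is asserted on
every test fixture.

Per-class summaries are **Tukey five-number summaries**: hinges are
medians of the sorted half-samples (each half including the overall
median when n is odd), whiskers extend to the furthest observation within
1.5 x (hinge spread) of the hinges, and observations beyond are listed as
outliers by gene id — the convention of R's `boxplot`. By default breadth
counts span every sample in the matrix, including developmental stages;
an adult-only subset flag restricts to `adult_tissue` samples, since a
"tissues expressing" figure can reasonably be read either way.

Widespread genes are identified by two routes, recorded in the output:
the *cluster route* (members of the `widespread`-labelled cluster,
preferred when a group set is supplied, since it matches reading the
widespread block off the clustered heatmap) and the *threshold route*
(breadth >= `min_fraction` x n_samples, default 0.9).

## Exclusivity filtering

A gene is *exclusive* to a target sample set iff it is expressed in at
least one target sample and silent in every non-target sample — a
deterministic filter, no enrichment statistic. Target sets are defined by
sample-annotation group plus optional manual additions (e.g. re-attaching
ovary to a reproductive/developmental set when expression clustering did
not group it there); additions are logged for provenance, never
hard-coded. The expressed boundary is inherited from the calling module —
one source of truth for the threshold.

Each exclusive gene's peak (maximal called value among targets) is
recorded; ties are resolved to the earliest temporal rank (or first
matrix column among unranked samples) and flagged. `peak_in_window`
selects exclusive genes whose peak rank falls in an inclusive window —
e.g. the 8-cell..morula window of preimplantation development; genes
peaking at unranked samples (adult tissues) are never in a window.

## Temporal phase segmentation

Staged whole-embryo series show "gear changes": stage-to-stage positions
where the expressed-gene set turns over sharply. Published descriptions
of such phases are qualitative (read off a clustered heatmap); the
quantitative statistic here is this package's formalisation:

- *turnover* between consecutive stages = **Jaccard distance** between
  their expressed-gene sets (0 when both empty), chosen because it is
  threshold-consistent with the calling module and in [0, 1];
- *boundaries* = positions of the `n_boundaries` largest turnover scores,
  ties toward the earlier position; `n_boundaries` defaults to **3**
  (four phases, matching the oocyte->zygote / 2-cell / 4-cell->blastocyst
  / post-implantation structure of mouse development), overridable.

Genes never expressed in the series form a reserved `silent` group; the
rest are clustered (same machinery as above) into `k = n_boundaries + 1`
temporal groups, numbered by median onset rank, and each gene is
summarised by onset (first expressed rank) and offset (last expressed
rank); onset <= offset for every expressed gene. Reversing the stage
order reverses the turnover vector. Whether a gradual within-phase shift
(e.g. e8.5->e9.5) deserves a boundary of its own is interpretive; the
statistic simply ranks gaps by turnover, so raising `n_boundaries`
surfaces it.

## Synthetic data: what it emulates and what it does not

The generator plants archetypes at the scale of the real study designs:
a **242-gene x 59-sample** human-style panel (7 preimplantation stages,
testis/placenta, 12 neural, 8 immune, 30 organ samples) and a
**278-gene x 12-stage** mouse-style series. Default archetype counts
mirror the structures the pipeline must resolve: 20 widespread genes
(TALE/ZF/CERS-heavy, with single PRD/SINE/CUT members), neural (60),
immune (25) and organ (70) modules (ANTP/PRD-heavy), 23 genes exclusive
to reproductive/developmental samples — 13 peaking inside the
8-cell..morula window, 10 gonadal/placental including ovary expression so
that the manual ovary addition is exercised — and 44 silent genes. The
mouse series plants maternal (60, PRD-heavy), 2-cell-burst (50,
PRD-heavy), cleavage-to-blastocyst (70) and post-implantation (78,
ANTP-heavy) phases plus 20 silent genes, with boundaries after positions
1, 2 and 6.

Value model: each archetype owns a shape (one value per supported sample,
log-normal with location 3 and scale 1 on log-FPKM, clipped below at the
calling threshold); a gene is its archetype's shape times a per-gene
amplitude >= 1; everywhere else a background floor uniform on [0, 1.5].
Consequences, by construction:

- every planted expressed value survives calling, every background value
  is zeroed: planted truth is exactly recoverable at zero noise, which is
  what makes "ARI = 1.0, zero false positives/negatives" a well-defined
  integration contract rather than a probabilistic one;
- within an archetype, called max-normalized profiles are identical, so
  the planted partition is the unique zero-distance clustering.

`corrupt` degrades a matrix for stress tests: dropout zeroes each nonzero
entry with probability `dropout_rate` (rate 1 gives an all-zero matrix),
and multiplicative log-normal noise (`exp(noise_scale * Z)`) perturbs the
surviving expressed entries. Noise is scoped to expressed entries: the
background floor is itself the noise model for silent measurements, and
the interesting failure modes for the downstream filters are lost calls
and shifted peaks, not background leaping the threshold.

What the generator does **not** emulate — so what passing tests do not
show about real data: continuous specificity gradients (real genes leak
at intermediate levels; archetypes here are crisp), gene-length and
library-size biases inherent to FPKM, correlated noise across samples
from shared processing, replicate structure, and realistic per-sample
expressed-gene counts (a single 70-gene organ module makes every organ
sample express ~90 panel genes, where real tissue atlases of this family
mostly fall between 25 and 65 — organ-specific genes in real data split
into many small organ-wise sets). Recovery results on this generator
certify the algorithms' contracts, not their behaviour on noisy atlases.

## Workflows, determinism, problem sizes

The tissue workflow chains call -> normalize -> cluster -> label ->
specificity -> exclusivity; the staged workflow call -> turnover ->
boundaries -> temporal groups. Each run directory contains the exact
config (YAML), a log with gene/sample counts after each stage, and a
manifest of SHA-256 checksums over the tabular/config outputs (figures
excluded — their bytes depend on the plotting backend); identical config
and inputs give identical manifests. All randomness flows from the single
`seed` in the config; generation is a deterministic function of
(spec, seed).

Recovery rates quoted by the acceptance script use 100 zero-noise and 200
noisy replicates of the full presets, and oracle-equivalence tests use 50
random 200 x 60 fixtures — sizes at which exact brute-force oracles
(nested-loop counts, quadratic scans) run in seconds and binomial
sampling error on a rate over 200 replicates is ~2-3 points.

## Known limitations

- The clustering parameterisation (distance, linkage, cut) behind any
  particular published heatmap grouping is generally unknowable; exact
  membership of clustering-derived groups on real data is therefore not a
  contract of this package, only the properties of the procedure.
- The immune-style groups of real analyses are reported to be sensitive
  to the FPKM cut-off; the threshold is exposed but no canonical
  sensitivity sweep is defined.
- Boundary detection reports the top-n turnover gaps; it does not test
  whether n phases are *supported* (no model selection over n).
- FPKM is consumed, never computed: no read mapping, no replicate
  merging, no FASTQ/SAM handling.
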