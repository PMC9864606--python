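# Methods

## Overview

`screpurpose` chains six stages, each a pure function of its inputs:

1. **QC** — cell and gene filters, library-size log normalization.
2. **Cell typing** — marker-score assignment of immune cell types.
3. **Pseudobulk** — geometric-mean profiles per (cell type, condition).
4. **Pathway activation** — per-pathway PAL from case-to-normal ratios.
5. **Query signatures** — up/down gene lists from top-10 pathways.
6. **Connectivity ranking** — reverse-mode scoring against a drug bank,
   then cross-cell-type aggregation.

A synthetic-data module generates cohorts, pathway databases, marker sets
and drug banks with planted ground truth, so the whole chain is testable
at desk scale.

## QC and normalization

Cells are kept when their detected-gene count lies in
`[min_features, max_features]` (defaults 200 and 2500, both inclusive)
and their mitochondrial and hemoglobin count percentages are **strictly**
below 10% — the thresholds are printed as `< 10%` inequalities, so
exactly 10% fails.  Genes are kept when detected in at least `min_cells`
(default 3) cells.  The pipeline order is fixed: cells first, then genes
(the two compositions genuinely differ, since removing cells changes
per-gene detection counts); a regression test pins this order.
Mitochondrial genes are recognized by the case-insensitive `MT-` prefix
and hemoglobin genes by the symbol pattern `^HB[ABDEGMQZ]` (which
excludes e.g. HBP1); no published gene lists are bundled.

Normalization is library-size scaling to a fixed total (default 10⁴)
followed by log1p: `value = log(1 + scale · count / total)`.  This is a
deliberate stand-in for regularized negative-binomial regression
(SCTransform-style): the downstream pathway scores consume only
case/control *ratios* of per-gene aggregates, which the simple
normalization preserves, and the substitution is recorded in every run
manifest.  Cross-donor integration is likewise omitted — it is an
embedding-level correction for clustering, and this pipeline does not
cluster; donor labels are carried through and pseudobulk pools donors.

## Cell typing

Rather than graph clustering followed by cluster annotation, cells are
annotated directly: for each cell type the score is the mean z-scored
(per gene, across all cells) normalized expression over that type's
markers, and a cell takes the argmax label when the gap to the runner-up
reaches `min_margin` (default 0.1 score units; exact ties resolve to the
lexicographically smallest label and are assigned only when
`min_margin = 0`).  This keeps the cell-type → pathway → drug logic
identical while making ground-truth recovery directly testable; on the
default synthetic cohort the assignment is >99% correct.

Cluster markers use a one-vs-rest two-sided Wilcoxon rank-sum test:
exact by full enumeration of all C(n+m, n) rank assignments when both
groups have ≤ 8 cells (two-sidedness is the permutation-symmetric form
P(|W − μ| ≥ |w − μ|), which remains well-defined under ties), and the
tie-corrected normal approximation with continuity correction otherwise.
Reported genes satisfy log2FC ≥ 0.25 (ε = 10⁻⁹ guards empty means),
p ≤ 0.01 (raw, as is conventional for these thresholds; a
Benjamini–Hochberg flag exists but is off by default) and
max(pct_in, pct_out) ≥ 0.3 — the `min.pct` convention of taking the
larger of the two detection fractions.

## Pathway activation level (PAL)

Pseudobulk profiles are geometric means of `1 + value` over the group's
cells, so gm ≥ 1 always and genes silent in the whole group give exactly
gm = 1 (log-ratio 0 downstream) — the +1 pseudocount is the zero-handling
choice.  The PAL of pathway P in cell type t is

    PAL = 100 · Σ_g ARR_g · log2(CNR_g) / Σ_g |ARR_g|,

summing over pathway genes present in the matrix (absent genes are
skipped, never imputed, and `n_genes_used` is reported so thin pathways
are visible).  Log base 2 is used for consistency with the log2FC marker
threshold; the base only rescales PAL and never changes rankings.  With
all-activator weights the PAL reduces to 100 × mean log2 CNR.  PAL is
exactly antisymmetric under swapping case and control.  The top-10
selection is sign-gated: "activated" requires PAL > 0 and "inhibited"
PAL < 0, because reverse-mode querying needs directional lists; ties
break by pathway ID.  Gene-importance weighting beyond the ±1
activator/repressor role is not implemented.

GMT input accepts the standard dialect plus `gene^+1` / `gene^-1` weight
tokens; within a line duplicate genes keep their first weight, and
duplicate pathway IDs are an error.

## Query signatures

The up (down) query is the union of the genes of the top activated
(inhibited) pathways.  A gene appearing in both unions follows the sign
of its own log2 CNR and is dropped when the ratio is exactly 1 — the
conflict rule that keeps the query self-consistent with the measured
direction.  Genes absent from the CNR vector (filtered out of the
matrix) are dropped: they carry no ordering key and contributed nothing
to the PAL.  Each side is ordered by descending |log2 CNR| (gene ID
breaks ties) and truncated to `max_per_side` (default 2000, a typical
signature-search query cap).  Query genes unmatched in the drug bank's
universe are counted in the run manifest, never silently ignored.

## Connectivity scoring

**Interception (overlap) score** — the default, mirroring reverse-mode
("aggravate = False") signature search:

    reverse: (|q_up ∩ d_dn| + |q_dn ∩ d_up|) / (|q_up| + |q_dn|)
    mimic:   (|q_up ∩ d_up| + |q_dn ∩ d_dn|) / (|q_up| + |q_dn|)

This matched-direction overlap normalized by query size is this
package's definition of the interception statistic.  Ranking is
experiment-level (a molecule may recur across doses/cell lines);
molecule-level deduplication happens only in aggregation, and a
`unique_molecules` flag switches truncation to first-occurrence-per-
molecule.  No minimum-overlap cutoff is applied: zero-score experiments
simply never reach the top when any positive score exists.

**Weighted-KS connectivity** — the classic running-sum enrichment score:
+1/s at hits, −1/(N−s) at misses, ES = the extremum of largest
magnitude, with the positive extremum preferred on an exact magnitude
tie (fixed for determinism).  The implementation tracks extrema as exact
integer numerators over s·(N−s), so the returned float is the correctly
rounded value of the exact rational — the test suite checks bit-for-bit
equality against an exhaustive prefix-scan oracle in rational
arithmetic.  Connectivity = (ES(q_up) − ES(q_dn))/2; reverse-mode
ranking sorts ascending (most negative = strongest reversal).  Bank
experiments store gene sets, not ranked profiles, so the ranked list an
experiment implies is deterministic: UP block, unaffected genes, DN
block, each alphabetical.

All rankings are total orders: score, then experiment ID.

## Aggregation

Occurrence counts are experiment-level by default (a molecule hit by two
experiments within one cell type counts twice), with a molecule-level
mode, because the display convention "occurs more than five times" does
not fix the counting rule; the "more than five" rule (count ≥ 6) is a
display-layer threshold only — full tables are always written.
Intersections use exact-membership (UpSet) semantics: every molecule
belongs to precisely one group, the subset of cell types whose lists
contain it, so group sizes partition the unique-molecule union; this
conservation is asserted on every run.

## Synthetic data: what it emulates, and what it does not

The generator emulates a multi-donor case/control cohort in the style of
a 6-vs-6 patient single-cell study: negative-binomial counts with a
single global dispersion (the simplest scRNA-seq-like overdispersion
model), cell types realized as an 8-fold mean elevation of disjoint
10-gene marker sets (elevation, not exclusive expression, so annotation
is a nontrivial but solvable task), and disease signal planted as a
2^log2_fold mean shift on a chosen pathway's genes in case cells of a
chosen cell type.  QC behaviour is exercised by naming configurable
`MT-`/`HB`-prefixed genes and boosting mitochondrial means in designated
low-quality cells.  Drug banks contain exact set-reversals of the
planted shifts (DN from up-planted genes, UP from down-planted genes,
short sides padded with random non-planted genes, pad fraction recorded)
among uniformly sampled decoys; a corruption fraction can weaken the
reversers into harder positives (default 0).

Defaults — the package's standard study conditions, chosen once:
1000 genes, 5 immune cell types, 6 case + 6 control donors × 100 cells
per type (600 cells per (type, condition)), NB mean 0.5 counts/gene and
dispersion 2.0 (≈ 64% zeros, ~360 detected genes per cell — inside the
QC window), marker fold 8, 40 pathways × 20 genes with zero overlap,
three planted effects at log2_fold +2/+2/−2 in T cells (two up and one
down so both query sides are exercised; the magnitude 2 is a calibration
choice, not an empirical value), and a bank of 5 reversers + 200 decoys
with 50-gene sides.  Under these conditions the planted pathways score
|PAL| ≈ 50–90 against a noise floor of |PAL| ≈ 3, and all five
reversers rank above every decoy.

Not simulated: ambient RNA, doublets, batch and donor random effects,
UMI-level reads, partial pathway overlap between disease and drug
signatures beyond the corruption knob, and realistic pathway topology.
Passing the planted-recovery tests therefore shows the pipeline's logic
is correct and calibrated against its own noise model — not that the
simple normalization or marker scoring would suffice on real data with
strong batch structure.

## Numerical and design choices

- Gene IDs are upper-cased everywhere on ingest; collisions after case
  normalization are an error.
- Generators and the pipeline are pure functions of (config, seed);
  sub-seeds are spawned from a single `SeedSequence`.  Report TSVs are
  written with a fixed float format, so reruns are byte-identical.
- Degenerate inputs fail loudly with stage context: zero-total cells in
  `normalize`, empty (cell type, condition) groups, vacuous queries,
  mismatched gene axes, unknown planted references.
- A pathway with no gene in the matrix is "not evaluable" and excluded
  from ranking rather than raising.
- Test and acceptance runs use the default study conditions above
  (20-seed replication for the end-to-end recovery check) and reduced
  cohorts (~500–600 genes, 40–80 cells per group) for unit-level checks;
  these sizes are the package's own verification choices.

## Known limitations

- The interception score is this package's definition; external
  signature-search services do not publish their exact statistic, so
  absolute scores are not comparable across tools (rankings of exact
  reversals vs decoys are robust to this).
- PAL omits per-gene importance factors; pathways are flat ±1 gene sets.
- One pooled profile per (cell type, condition): no per-donor pseudobulk
  replicates, hence no donor-level uncertainty on PAL.
- Marker-score annotation assumes markers are informative in the
  normalized data; it does not subcluster related states (e.g. T-cell
  subsets).
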