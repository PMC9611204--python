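# Methods

## Overview

`rhizotrn` implements an inference chain from co-expressed protein profiles
to condition-specific transcriptional regulatory networks (TRNs), patterned
on how rhizobial TRNs are deduced from gene-associated DNA motif resources:
each gene carries one to five conserved motif count matrices discovered in
its own upstream region, and a TF gene–target relation is called when a
matrix of a co-expressed transcription factor recognises a site in the
target's upstream region.  The chain is: motif scanning with exact
p-values → stringency tiers and per-relation most-stringent selection →
matrix-clustering filter → rebuilt network → structural characterisation
against random nulls → hierarchy decomposition → KO-multiplicity
(isoenzyme) analysis.

## Motif model and exact p-values

A motif is a 4 × w count matrix (rows A, C, G, T) with identifier
`<gene>_m<k>`.  Counts are regularised with a pseudocount (default 1.0 per
column, split proportionally to the background) and converted to log2-odds
weights against an i.i.d. background (uniform by default, configurable GC).
The site *Weight* is the additive log-odds score; *Significance* is
−log10 of the site p-value (the p-value is the primary quantity; the
Significance column is its log-scale rendering).

The p-value of a score threshold is computed exactly by dynamic programming
over a discretised score lattice: log-odds entries are rounded to the
nearest multiple of the granularity (default 0.01 bits) and the score
distribution of a random background w-mer is built by column-wise
convolution.  Rounding bounds the error: for width w and granularity g the
DP tail at threshold t is bracketed by the exact tails at t ± (w+1)g/2, and
the test-suite asserts this bracket against exhaustive enumeration over all
4^w sequences for w ≤ 6.  The null is single-strand i.i.d. background;
scanning handles the reverse strand by scoring each orientation against the
same null (the per-strand p-value is reported, not a two-strand corrected
one).

Pseudocount scaling: because the pseudocount is distributed proportionally
to the background, the regularised probability is homogeneous — multiplying
counts and pseudocount by the same scalar leaves the log-odds unchanged,
while scaling counts alone (pseudocount fixed) changes the regularisation
mix.  Both behaviours are covered by tests.

## Scanning, tiers, and the most-stringent selection

Every window of a promoter is scored on both strands (D = direct,
R = reverse complement); coordinates are 1-based inclusive on the forward
strand of the upstream region.  Hits are fractionated into stringency
tiers by p-value.  The printed band limits (1.0e-4–9.9e-4, 1.0e-5–9.9e-5,
≤9.9e-6) are two-significant-figure renderings that leave gaps (e.g.
9.95e-5); the implementation uses the gap-free half-open decades
low = [1e-4, 1e-3), medium = [1e-5, 1e-4), high = (0, 1e-5), which contain
the printed ranges.

The `auto` rule keeps, per TF gene–target pair, the single hit with the
lowest p-value across all of the TF's matrices and all windows — i.e. the
relation is reported at the highest stringency the data supports, and the
winning matrix index is retained.  Ties break by smaller start coordinate,
then strand D before R, then lower matrix index.  The rule is applied per
relation (the alternative per-TF-round reading of "each round" is not
implemented).

## Matrix clustering and the clustered-TF filter

Two matrices are compared by the best column-wise Pearson correlation of
their probability matrices over all ungapped offsets and both orientations
(`cor`), with a width-normalised variant
`ncor = cor × aligned_width / max_width`.  Offsets with fewer than two
aligned columns, or with zero variance in either slice, are skipped.
Clustering is agglomerative with average linkage on 1 − cor: groups merge
in order of decreasing average correlation while the merged group's average
`cor` and `ncor` stay at or above the floors (defaults cor ≥ 0.6,
ncor ≥ 0.4, the published defaults of the standard matrix-clustering tool;
no thresholds are stated for the original analysis).  Retained clusters
must contain at least two matrices from at least two different genes.
Clustering is run per condition — profiles are never mixed.

The clustered-TF filter keeps exactly the genes whose matrices share a
cluster with at least one TF matrix.  Its purpose is false-positive
purging: genes whose motifs resemble no co-expressed TF motif owe their
scan hits mostly to chance, and those hits sit predominantly in the
low-stringency band.  This is what produces the observed enrichment of
high-stringency interactions in the rebuilt (step-3) network.

## Three-step network construction

Step 1 scans all TF × target pairs restricted to the profile (self-pairs
included, since the motif resource is built on self-recognition — this is
why inferred networks show elevated self-regulation), applies `auto`, and
drops genes with no relation.  Step 2 clusters the matrices of the step-1
genes and applies the clustered-TF filter.  Step 3 rebuilds the network
exactly as step 1 on the retained genes.  Attrition at each step is logged.
Networks serialise to a 12-column TSV (Condition, Locus tag, K number,
Upstream_region, Matrix_ID, Chain, End_motif, Start_motif, Site, Weight,
p-value, Significance), ordered by decreasing p-value, and to GML.

## Structural properties

Thirteen properties per network: regulator fraction (kout > 0),
self-regulation fraction, maximum out-connectivity and giant weakly
connected component size (all over n); density × regulator fraction with
density m/(n(n−1)) over non-self edges; FFL, complex-FFL and 3-feedback-
loop counts normalised by the potential-motif number
n!/(n−r)! · (TFn/n)^TFm (r = 3; TFm = 3 for feedback loops, 2 for
feedforward; 0^TFm defined as 0); mean directed shortest path over
reachable ordered pairs (unreachable pairs excluded); diameter over (n−2),
clamped at 1 for toy graphs; average clustering coefficient of the
undirected simplification; and adjusted R² of power-law fits to P(k) and
C(k).

Motif census conventions: triples are counted once per unordered node set;
self-loops are ignored; a triple containing a directed 3-cycle is a
3-feedback loop; otherwise a triple containing the transitive pattern
X→Y, Y→Z, X→Z is an FFL, and a *complex* FFL when it carries at least one
edge beyond the three defining ones (the term is not defined in the source
analysis; this operationalisation is isolated behind the `kind` flag).
The census is validated against brute-force triple enumeration.

Degree laws: P(k) uses total degree by default (in/out via a flag — the
original choice is unstated); the robust fit is iteratively-reweighted
(Huber) regression of log10 y on log10 k with
R²adj = 1 − (1 − R²)(N − 1)/(N − 2); the MLE path estimates the discrete
power-law exponent with the generalised-zeta likelihood (R²adj still
reported from the robust fit).  Fits require three distinct positive
degrees; networks too degenerate to fit record R²adj = 0, read as "no
scale-free signal".

The null ensemble is G(n, m): uniform simple directed graphs with exactly
the biological network's node and edge counts (default 1000 replicates,
seeded).  Profiles are min-max scaled per property across networks
(constant columns map to 0), Ward-clustered in both directions, and
correlated with Pearson (scaled profiles by default; the unscaled order is
exposed because the original description is ambiguous).

## Hierarchy

Structural genes (kout = 0) are removed in one pass (iterating would change
the out-connectivities that the classification depends on).  Each remaining
edge (a, b) is top-down iff kout(a) > kout(b); ties — including every
self-loop — are bottom-up and removed, which is guaranteed to leave a DAG
(every edge of a directed cycle would need strictly decreasing kout).  The
DAG is peeled into layers by longest-path-from-roots: each node sits one
layer below its deepest regulator, so every retained edge crosses strictly
downward.  Regulators isolated by the removals carry no ordering
information and are placed in the bottom layer, flagged separately (the
original placement is unstated).  The bottom-up fraction is reported, not
asserted, on synthetic data: it is a property of the network analysed (the
published inferred networks average below 5%, but a synthetic step-1
network with few distinct out-degrees ties more often).

## Isoenzymes

Loci are grouped by KEGG Orthology number across condition profiles.  A KO
with loci in two or more conditions is classified: `identical` (equal
sets — the same gene expressed in both states, not an isoenzyme),
`disjoint` (condition-exclusive sets) or `overlapping`; `disjoint` and
`overlapping` constitute multiplicity (isoenzymes).  Because the borderline
overlapping case is counted ambiguously in published totals, both the
strict (disjoint-only) and inclusive counts are derivable.  A locus with
several KO annotations joins one group per KO.  Pathway coverage is the
distinct-pathway union over isoenzyme KOs.  The differential-regulator join
collects, per group and condition, the (TF, matrix index, p-value) triples
targeting the member loci in that condition's network and flags the group
when the TF sets differ.

The packaged reference table (`data/retli_mm_bacteroid_multiplicity.tsv`)
is the published *R. etli* CFN42 minimal-medium/bacteroid multiplicity
table; on it the classifier yields 45 KOs, of which 5 identical
(K00390, K01609, K01916, K02968, K16147), 1 overlapping (K01768) and 39
disjoint.  The wider published study counts (34 isoenzyme groups over 48
KOs, 60 pathways, 101/74 proteins) derive from supplementary tables with
pathway annotations that are not shipped here; they are not recomputable
from the printed table alone.

## Synthetic worlds

The generator emulates the pipeline's inputs with full ground truth.
Defaults and rationale:

| parameter | default | why |
| --- | --- | --- |
| promoter length | 250 bp | fixed window ending at the gene start; region bounds of the emulated resource are unstated |
| background | uniform (GC configurable) | 0-order i.i.d. null matching the scoring model |
| motif width | 14 bp | typical of dyad-derived bacterial motifs |
| site strength | 0.9 consensus-base probability per column | "strong sites": sampled sites score ~19 bits, comfortably inside the scanable range |
| regulon sizes | Zipf(1.5) truncated at n/4 | heavy tail induces hubs so degree-law fitting is exercised |
| matrices per gene | uniform 1..5 | matches the one-to-five multiplicity of the emulated resource |
| profile overlap | 0.3 | a free stand-in: the real membership noise model is unknown |
| study scale | 200 genes, 20 TFs | desk-scale analogue of the profile sizes, used by tests and the acceptance script |

Every regulator recognises a site in its own promoter (self-regulation is a
construction property of the emulated resource); a regulated gene's first
matrix is a mildly Dirichlet-perturbed copy of a regulator's matrix, extra
matrices are noisier copies.  Implanted sites are placed at non-overlapping
offsets so no planted site destroys another.  Profiles share each gene
across all conditions with probability `overlap`, otherwise assign it to
one condition.  KO planting creates exactly the requested number of
disjoint multiplicity groups from condition-exclusive loci, a configurable
number of identical-locus KOs, and private KOs elsewhere, with the planted
groups covering exactly the requested number of pathway labels.

What the generator does **not** emulate: mass-spectrometry intensities and
missingness, ortholog promoter sets across genomes, operonic structure,
correlated or overlapping motif sites, or asymmetric profile sizes.
Passing tests therefore demonstrate correctness of the inference machinery
under a clean planted model, not performance on real proteome profiles.

A measured consequence of the study conditions worth knowing: at the
default scan cutoff (9.9e-4) step-1 networks carry a large majority of
marginal low-stringency edges, so *raw* step-1 regulon sizes do not track
the planted regulon sizes (rank correlation is near zero or negative);
restricted to high-stringency edges the correlation is strong (Spearman
≳ 0.9 at study scale).  The regulon-size check is therefore defined on the
high-stringency regulons.

## Numerical choices and degenerate inputs

* p-value lattice granularity 0.01 bits; halving it changes any p-value by
  less than the previous bracket width (tested).
* Observed window scores are achievable by construction, so a threshold
  that rounds past the lattice maximum snaps to the smallest positive tail
  rather than reporting 0.
* Matrix similarity requires width ≥ 2 and ≥ 2 aligned columns; zero-
  variance slices are skipped.
* Agglomeration order is deterministic (max average cor, first index on
  ties), which makes cluster refinement monotone in the cor floor.
* Empty profiles, infeasible ER edge counts, n < 3 property profiles and
  sub-3-degree fits raise errors rather than returning silent defaults.

## Reproducibility

One integer seed pins every stochastic stage (world generation, profile
assignment, KO planting, ER ensembles).  `simulate` runs with the same seed
produce byte-identical output directories; run logs carry the package
version, seed and attrition counts and no timestamps.
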