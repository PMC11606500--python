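# Methods

`tcrfirst` analyzes paired single-cell data (gene expression plus T cell
receptor sequencing) from the receptor side first: cells are organized by
their clonotype, clonotypes by sequence similarity, and transcriptional
questions are asked of those receptor-defined groups. This note documents the
models and procedures, their assumptions, the parameters that matter, and
what the synthetic-data tests do and do not establish.

## Repertoire construction

Contig tables (10x `filtered_contig.csv` or AIRR rearrangement TSVs) are
standardized to one record per assembled chain. Only the four T cell loci
(TRA/TRB/TRG/TRD) are kept. Cells are resolved to at most one chain per chain
group — alpha/gamma (AG) and beta/delta (BD) — by highest UMI support, with
ties broken lexicographically on the junction so resolution is deterministic
and order-independent. Cells with more than two distinct productive contigs
in one group are excluded as likely multiplets. When separately delivered
alpha/beta and gamma/delta files are merged, barcodes appearing in both are
flagged dual-lineage and excluded by default (their identity is ambiguous);
they can be retained with a flag. The clone identity key is
`Vag.Jag_CDR3ag|Vbd.Jbd_CDR3bd`.

A repertoire keeps exactly the cells present in both modalities (TCR and a
count-matrix barcode). Barcode suffix dialects ("AAAC" vs "AAAC-1") are
handled by optional symmetric suffix stripping; a zero overlap raises an
error that points at this mismatch rather than silently returning nothing.
Cell quality filtering uses detected-gene count (default >= 200) and
mitochondrial fraction (default <= 10%, genes with the `MT-` prefix); both
thresholds are conventions, not measured values, and are configurable.

## CDR3 clustering

Unique (locus, V gene, CDR3) items are compared within one chain class only
(A, B, G, D), so a gamma junction can never join an alpha cluster. Candidate
pairs at Hamming distance <= 1 are found by wildcard hashing: each length-L
junction emits L masked keys plus one exact key, and only items sharing a key
are verified — expected cost linear in total sequence length, never the
quadratic all-pairs scan. Edges require equal length and Hamming distance
<= 1 but not equal V gene (identical junctions on different V genes join at
distance zero); a stricter same-V variant is available behind a flag.

Communities come from Markov clustering (MCL) of the similarity graph:
column-normalize the adjacency-with-self-loops matrix, then alternate
expansion (matrix square) and inflation (element-wise power 2.0, then column
renormalization), pruning entries below 1e-5, until the matrix changes by
less than 1e-8 or 100 iterations. Each node joins the attractor with the
largest mass in its column, ties to the smallest attractor id, making output
deterministic. Clusters of size >= 2 are reported; singletons are returned
separately. Clusters are named by the multiplicity-weighted modal V and J
genes and summarized by a per-position residue-frequency motif; consensus
positions at >= 95% frequency are rendered uppercase.

## Neighbor enrichment

The distance between two junctions is a tcrdist-family mismatch score:
`3 x (sum of per-position substitution costs + 4 x |length difference|)`,
where the substitution cost is `min(4, 4 - BLOSUM62(x, y))` for a mismatch
(floored at 0) and the shorter sequence is padded by a central gap block.
Under these weights the conventional neighbor radius is 12.5; because the
per-position cost is an integer and the chain weight is 3, "distance <=
12.5" is equivalent to "distance <= 12", i.e. at most one arbitrary
substitution, or several jointly cheap (biochemically conservative) ones.
The radius is applied inclusively. Symmetry and identity of indiscernibles
hold; the triangle inequality is not claimed.

Each clone is tested for having more neighbors (distance <= 12.5) among the
other unique clones than expected by chance. The null is a 50x shuffled
background: candidates recombine the V-proximal prefix of one clone with the
J-proximal tail of another, equal-length clone at a random cut, inheriting
the first parent's V gene and the second's J gene, stratified on (V gene,
length) so the background's joint marginal matches the input's exactly up to
rounding. When a generation-probability source is available, candidates are
additionally quota-matched to the input's pgen-decile profile per stratum;
without one, matching is on (V, length) only and the report says so.

Two generator details matter at desk scale and are deliberate choices:

* **Cut placement.** Cuts keep at least 4 residues from each parent
  (`[4, L-4]`; `[2, L-2]` for junctions shorter than 9). Cuts hugging either
  end produce chimeras that are near-copies of a single parent — J-proximal
  two-residue tails are nearly degenerate across J genes — which is
  resampling, not shuffling, and inflates every clone's expected neighbor
  count.
* **Near-parent rejection.** A candidate within the neighbor radius of
  either parent is discarded, as is a candidate equal to any observed
  junction. A draw that never left its parent's similarity neighborhood
  would let any genuine sequence cluster partially reconstruct itself inside
  its own null: in a 1,000-clone repertoire a 10-member cluster is 1% of the
  input and would otherwise contribute visibly to its own background. The
  rejection restores the independence an external reference repertoire would
  provide. It is mildly anti-conservative (the null slightly under-counts
  chance neighbors); the type-I error of the full procedure is measured
  directly on null repertoires in the test suite and stays well under the
  nominal 0.05.

For clone i among N unique clones with an M-sequence background, k is the
neighbor count among the other N-1 clones and K = k plus the clone's
background neighbors. The p-value is the hypergeometric tail P(X >= k) for
drawing N-1 from the pooled N-1+M with K successes — the probability of
seeing so many repertoire neighbors if neighbors were distributed at random
between repertoire and background. Bonferroni multiplies by N (the per-run
family of clones tested); significance is p_adj < 0.05, and a significant
call requires at least one observed neighbor.

## Toy V(D)J model and generation probability

The generative model is amino-acid level: a V segment contributes a CDR3
prefix, a J segment a suffix; both may be trimmed (0-2 residues); an insert
of i.i.d. residues (length 0-6, mode 3) joins them. There is no nucleotide
layer, no D segment, and no selection — it is a desk-scale stand-in for
IGoR/OLGA-class machinery, adequate for exercising background
stratification, pgen banding, and fixture generation, and nothing more. The
default 12 V / 8 J segment table is loosely shaped like human beta-chain
usage (most-used V near 17%) and is illustrative, not biological truth. The
substantial insert length is load-bearing: with short inserts the model
emits so few distinct junctions that chance Hamming-1 neighbors swamp any
planted structure.

`path_probability` records the product of choice probabilities along one
sampled path; a sequence's full pgen sums over all paths and is available
two ways: Monte-Carlo (fraction of sampled junctions equal to the target,
with binomial SE) and, on miniature models, exact enumeration over all
(V, J, trims, insert) combinations — the oracle the MC estimator is tested
against, including the total-probability check that reachable sequences sum
to 1. Pgen banding works on log10 values: the geometric mean and the SD of
logs, flagging values within one SD inclusively.

Synthetic repertoires plant sequence clusters as a seed junction plus
variants at (by default) one substitution. Variants substitute only residues
with a BLOSUM62 similarity >= 2 partner, emulating the biochemical
conservatism of epitope-driven convergence; this also keeps all member pairs
within the 12.5 radius, which double low-similarity substitutions would
violate. A `background_singletons` mode rejects generated junctions adjacent
(Hamming <= 1) to any accepted junction or planted member, producing the
"planted clusters among singletons" world in which cluster-recovery metrics
(ARI against planted labels) are well defined. Clone sizes follow a
geometric distribution (p = 0.7); per-sample frequency multipliers produce
paired pre/post designs. Synthetic expression counts are negative binomial
(default mean 0.3, dispersion 2.0 — sparse, dropout-like) with the cell's
own phenotype markers boosted by a fold-change `effect`; at effect 1 the
matrix is exchangeable across phenotypes by construction.

## Annotation

TCR rules are ordered by priority and the first match wins: MAIT cells are
TRAV1-2 joined to TRAJ33/TRAJ20/TRAJ12 on the AG chain; gamma-delta cells
carry any TRG/TRD chain; the TRAV13-2 x TRBV4-1 pairing is flagged
`CD1bc_candidate` (a literal reading of the reported association —
candidate, not a confirmed restriction); everything else is `alpha_beta`.
Rules are total and deterministic.

Signature gating scores each cell-signature pair with a rank-based capped-U
statistic (UCell-style): genes ranked by decreasing count with average tie
ranks, capped at r_max + 1 (r_max = 1500), score
`1 - (R - n(n+1)/2) / (n x r_max)` clipped to [0, 1]. The score is invariant
to monotone transformations of counts and needs no normalization. A cell
passes a gate when some positive signature reaches tau_pos (default 0.2) and
every negative signature stays below tau_neg (default 0.2); descent follows
the best-scoring passing child, and the label is the deepest gate passed,
with cells failing the root labeled `non-T/unknown`. Cells are processed in
batches for memory only; results are independent of batch size. With sparse
counts an unexpressed signature scores near (n-1)/(2 r_max) — effectively
zero — while an off-phenotype but noisily expressed signature sits near
0.10-0.15: negative gates are therefore most useful against genuinely
expressed lineage markers, and the shipped example tree uses positive-only
children with best-child descent. All shipped gene sets are placeholders;
real analyses must supply curated signatures.

External epitope annotations (exports of third-party predictors) join on the
clone key; rows at or below score 0.2 are dropped. The package does not
predict epitopes.

## Clonal dynamics

Expansion is always a within-sample frequency. Across a pre/post pair, a
clone is selected when it reaches >= 1% of the repertoire in either sample
and changes >= 2-fold; for clones absent at one timepoint the fold change
uses a one-count pseudo-frequency (raw zero counts are reported alongside),
while the 1% filter uses raw frequencies only. Expansion bins (single 1,
small 2-5, medium 6-20, large 21-100, hyperexpanded > 100) are labeled
conventions recorded in the output metadata.

Marker tables compare a cell group against a background with a two-sided
Wilcoxon rank-sum test per gene on log1p counts-per-10k. For tiny
comparisons (group-assignment space <= ~20,000) the permutation distribution
is evaluated exactly; the normal approximation with tie correction — the
conventional choice at realistic sizes — is measurably off (~0.1 in p) at
8+8 cells with the heavy zero-ties of count data. The log2 fold change uses
mean normalized expression with a 1e-9 floor; reported genes satisfy |lfc|
>= 0.25 and p < 0.05, top 30 by significance. Groups below 3 cells are
refused as statistically insufficient.

The pipeline runs io -> clustering -> enrichment -> annotation -> dynamics,
writes each stage's TSV plus a manifest (version, seed, thresholds,
per-stage counts), and is byte-reproducible for a fixed config and seed;
stage errors propagate with the stage name.

## What the synthetic tests establish — and what they do not

Green tests establish that the implementation is internally correct (hashing
equals brute force; MCL matches an independent dense implementation;
hypergeometric tails match combinatorial summation and resampling; MC pgen
matches exact enumeration) and that the full procedure behaves as designed
in the stated synthetic world: planted conservative clusters of size >= 8
among ~1,000 clones are detected at a 50x background with Bonferroni 0.05,
the type-I error on null repertoires stays under 5%, and rank-based gating
recovers 8-fold-boosted phenotypes at >= 95% accuracy. They do not establish
performance on real repertoires: the toy model lacks nucleotide-level
biases, D segments, thymic selection, allele diversity, realistic clone-size
tails, batch effects, or ambient RNA, and real marker programs are noisier
and overlapping. Thresholds shown to work here (radius 12.5, tau 0.2,
fold-change filters) are the field's conventions, and their operating
characteristics on real data must be assessed there.

## Known limitations

* The shuffled background is built from the input repertoire; for very small
  or highly clonal inputs even the near-parent rejection cannot fully
  decouple null and signal. An external reference repertoire would be the
  better null and can be supplied as the "background" side directly.
* Bonferroni over all tested clones is deliberately conservative; correlated
  tests (cluster members share neighbors) make it more so.
* The gating engine is a scoring rule plus a tree; it ships without a
  validated signature library.
* Generation probabilities from the toy model are not comparable to
  OLGA-scale values; only relative banding within one model is meaningful.
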