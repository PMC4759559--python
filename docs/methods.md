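# Methods

## Problem and model

A phage collection's pan-genome is described at the protein-family level.
Two proteins are homologous when their local alignment passes fixed
cutoffs with *either* sequence as query (a reciprocal hit); the resulting
undirected similarity graph is clustered into families by flow simulation
(MCL); a family is *core* when at least one member occurs in every genome
and *variable* otherwise.  Genome relatedness is then summarized from the
binary families × genomes presence/absence matrix, not from nucleotide
alignment — the working assumption is that gene complement, rather than
point divergence, carries the population signal for these small
(~30 kb, 50–60 gene) genomes.

## Homology stage

* **Aligner.** Exact Smith–Waterman (and Needleman–Wunsch for global
  identity), computed by `Bio.Align.PairwiseAligner`, BLOSUM62 with the X
  column zeroed, affine gap cost `open + (k−1)·extend` with open = 11,
  extend = 1.  Exact alignment was chosen over a seeded heuristic: scores
  are then a deterministic function of the pair, and the test suite can
  hold them to exhaustive enumeration on short sequences.
* **Statistics.** E = K·m·n·e^(−λS) with the customary gapped BLOSUM62
  constants λ = 0.267, K = 0.041; m is the query length and n the summed
  length of the whole multi-genome proteome (a single pooled database, as
  an all-vs-all search would use).  The same raw score therefore yields
  two E-values per pair, one per query; both must clear the cutoff.
* **Cutoffs.** E ≤ 1e−4, identity ≥ 0.50, coverage ≥ 0.50 of *at least
  one* of the two sequences ("either"; a stricter "both" mode is a
  config switch).  All comparisons are inclusive at the boundary.
* **Edge weight.** −log10 of the worse E-value, E floored at 1e−200 and
  the weight capped at 200 — the transform conventionally fed to MCL.
* **Prescreen.** Pairs sharing fewer than 2 distinct 5-mers are skipped
  before alignment.  Two length-L random sequences over 20 letters share
  ~L²/20⁵ 5-mers (≈ 0.1 for L = 600), while any pair able to reach 50%
  identity over 50% coverage shares dozens, so the prescreen does not
  disturb the graph in any regime the cutoffs accept; `prefilter=False`
  restores the exhaustive scan and a test asserts both give the same
  graph on a divergent synthetic collection.

## MCL stage

Dense column-stochastic matrix over the graph (ample below ~10⁴
proteins).  Self-loops equal each node's maximum incident weight
(standard damping against bipartite oscillation).  One iteration =
expansion (matrix squaring), inflation (elementwise power r, column
renormalization), pruning (entries < 1e−5 zeroed; a column that dies is
reset to its pre-prune argmax, ties to the lowest index), renormalization.
Convergence when the max absolute change is < 1e−8 (cap 100 iterations,
warning on non-convergence).  Clusters are read off the limit matrix:
nodes with non-vanishing diagonal are attractors, attractors joined by
residual flow form seeds, and every other node joins the seed receiving
most of its flow (ties to the lexicographically smallest cluster).
Inflation defaults to 2.0 and is exposed as a CLI flag with a sweep
option, because the optimal granularity is data-dependent.  Proteins with
no hits at all become singleton families, so unique proteins count as
families.

## Pan-genome stage

Core membership is decided at the family level (paralogs collapse to
presence), variable-gene counts at the gene level (each paralog counts) —
the two resolutions answer different questions: "is the function
universal?" versus "how much accessory cargo does this genome carry?".
Group summaries report mean and *sample* (n−1) standard deviation.
Structural classes V1–V5 are decided from gene order around the major
tail protein gene with precedence V5 > V4 > V2/V3 > V1; role labels
(mtp/nps/tpeX/rbp) come from CDS product annotations in the pipeline, or
from `assign_family_roles`, which matches family representatives to any
user-supplied reference FASTA at ≥ 30% global identity.

## Trees

Jaccard distance on binary profiles (two empty profiles are at distance
0 by convention); MeV-style Euclidean on 0/1 vectors would order pairs
almost identically but has no set-theoretic reading, so Jaccard is the
default.  UPGMA agglomeration updates distances with the Lance–Williams
average-linkage rule; ties within 1e−12 are broken by the
lexicographically smallest (min-label, min-label) pair, making every
dendrogram reproducible.  Cutting into k clusters undoes the k−1 highest
merges (heights are provably monotone under average linkage on a metric,
and asserted).  Neighbor joining is the textbook Saitou–Nei construction
with lexicographic Q-matrix tie-breaks; negative branch-length estimates
are clamped to zero with the deficit moved to the sibling edge.  Newick
serialization carries 6-decimal branch lengths; unrooted NJ trees are
written with a trifurcating root.

## RBP typing

The receptor-binding specificity of these phages lives in the C-terminal
region of the RBP; full-length alignment would dilute the signal with the
conserved N-terminal shoulder.  The window is the last 130 aa
(configurable) — about half of a typical 253–268 aa RBP, covering the
receptor-binding head, since no exact domain boundary is published.
Typing is best global identity against references at ≥ 50%, below which
a query is "novel"; distances for the RBP tree are p-distances
(1 − identity), the minimal assumption when the original tree-building
settings are unknown.  The packaged reference set is **synthetic**
(`data/rbp_references_synthetic.fasta`, one generated sequence per group
I–V): it exercises the machinery and fixes the group↔CWPS mapping
(I↔C, II↔B, III↔B&C, IV↔U, V↔A), but carries no biological signal —
real analyses must substitute a curated reference FASTA + group map.

## Frameshift scanner

Detection requires the codon immediately 5′ of the annotated stop to be
CCC and the stop to be TAG (the canonical shifty-stop; TAA/TGA accepted
with a flag, and a `window` parameter can search further upstream codons).
The +1-frame product resumes one base into the stop — after the ribosome
reads CCC with the stop in the A-site, a +1 slip makes the next codon
start at the stop's second base — and is translated to the next in-frame
stop.  Extensions shorter than 30 aa are discarded as noise.  Masses are
average (not monoisotopic) residue masses plus one water, in kDa; mass
additivity (fusion = parts − water) holds to < 1e−9 kDa by construction
and is asserted.  The dotplot operation is exact word matching only
(default word 10): enough to visualize synteny breaks, with no scoring or
stringency model.

## Synthetic generator

Emulates: one random-ancestor protein per family; every genome carries
all core families; accessory family f is present with probability 0.8 in
its home cluster (f mod n_clusters) and 0.1 elsewhere; each present
family contributes an independently substituted copy of the ancestor
(uniform over the 19 other residues, no indels), back-translated with
uniform synonymous codons and laid out with 20-nt spacers; a present
family duplicates (paralog) with probability 0.02.  Defaults — 20
genomes, 4 clusters, 29 core + 89 accessory families, 10% divergence,
proteins 80–600 aa — mirror the pan-genome structure observed in a
~90-genome dairy-phage collection at a desk-runnable scale.  It does
**not** emulate: indels, gene-order modularity, recombination, promoter
or RBS structure, nucleotide composition, or homology *between*
families (uniform random ancestors make cross-family identity near the
50% threshold vanishingly unlikely).  Passing recovery tests therefore
demonstrates the pipeline's correctness under substitution-only
divergence with clean family boundaries, not its robustness to domain
shuffling or fragmented annotations in real data.

## Problem sizes and determinism

The test suite and acceptance script run the generator at its default
scale (20 genomes, ~1100 proteins; under a minute for the full pipeline)
plus a 6-genome collection for the frameshift stage; alignment oracles
use 200 random pairs of length ≤ 8, MCL oracles graphs of ≤ 12 nodes, NJ
recovery random additive trees of 4–8 taxa.  Every random draw flows from
a single integer seed (numpy `default_rng` in the generator, `random.Random`
in tests); there is no hidden randomness, and reruns are byte-identical.

## Known limitations

* Exact SW scores are ≥ heuristic BLAST scores, and the Karlin–Altschul
  constants are nominal, so counts on real deposited collections
  approximate, rather than bit-reproduce, numbers derived from a
  particular BLAST build; the "either/both" coverage reading and the MCL
  inflation are the two settings a reproduction should sweep.
* The dense MCL matrix is O(N²) memory; beyond ~10⁴ proteins a sparse
  implementation would be needed.
* The ORF finder is a deliberately naive fallback (maximal ORFs + a
  Shine–Dalgarno score: best AGGAGG match, one mismatch allowed, ending
  5–15 nt upstream of the start); annotated CDS features are always
  preferred.
* `group_summary` reports sd = 0 for singleton groups (flagged by n = 1)
  rather than NaN.
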