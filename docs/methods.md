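# Methods

This note records the models, parameter choices and known limitations
behind `genustax`, in the order the pipeline runs.

## Pairwise alignment

All protein and nucleotide comparisons are optimal local (Smith–Waterman)
alignments under affine gap costs, computed by a numba-compiled kernel
(`genustax._sw`). A gap of length L costs `gap_open + L·gap_extend` (the
BLAST convention). Defaults: BLOSUM62 with gap 11/1 for proteins; match +1,
mismatch −2, gap 5/2 for nucleotides, with both subject strands tried and
the better kept. The traceback is deterministic: the alignment ends at the
highest-scoring cell (smallest row, then column, on ties) and prefers
diagonal over up over left moves. Ambiguity codes (X/B/Z for proteins, N
for nucleotides) are retained; N scores as a mismatch against everything,
itself included, which keeps identity estimates conservative.

Significance uses the ungapped Karlin–Altschul form,
`bits = (λS − ln K)/ln 2`, `E = m·n·2^(−bits)`, with m the query length and
n the subject length times the number of sequences searched (per-proteome
database semantics). Constants are standard published values — λ = 0.267,
K = 0.041 for gapped BLOSUM62 11/1; λ = 1.28, K = 0.46 for match 1 /
mismatch −2. BLAST's finite-length edge corrections are omitted; E-values
are therefore slightly conservative for short sequences. Since the E ≤ 10⁻⁵
cutoff sits far from the score distribution of unrelated proteins, this
approximation does not move any decision in practice.

**Candidate shortlisting.** Before alignment, subjects are shortlisted by
shared exact k-words (k = 4 for proteins, k = 12 for nucleotide fragments,
indexed on both strands). The low-level `kmer_prefilter` default
(min_shared = 1) guarantees the shortlist is a superset of anything that
can pass the orthology filter at moderate divergence. The pipeline itself
demands ≥ 3 shared words (`PipelineConfig.prefilter_min_shared`): an
alignment able to clear E ≤ 10⁻⁵ needs a raw score around 90, which at any
relevant divergence implies far more than three intact 4-words, while
unrelated ~200-residue proteins share ~0.25 words on average. A test
verifies the shortlisted and exhaustive best-hit tables agree on a
diverged proteome pair. Candidates whose raw score already rules out the
E-value cutoff are discarded without traceback.

## Orthology and pan-genome accounting

Directed best hits take the highest-scoring subject whose alignment passes
identity ≥ 50 %, coverage ≥ 50 % **on both sequences** ("longer than half
of their sequence lengths"), and E ≤ 10⁻⁵; thresholds are inclusive.
Reciprocal best hits over all genome pairs form an undirected graph whose
connected components are the orthologous clusters. Connected components
are a deliberate simplification of spectral-partitioning refinements used
by some orthology tools: they are deterministic, order-invariant and
exactly testable; the cost is that a promiscuous protein can bridge two
families, which at the divergences the demarcation operates on is rare.
Proteins with no reciprocal hit form singleton clusters, so every gene of
every genome is accounted to exactly one cluster — required for
core/accessory/unique percentages to be well defined.

Core = present in all analysis genomes; unique = present in exactly one;
single-copy core = exactly one member per genome. The outgroup genome is
excluded from this accounting. For the tree, however, the usable clusters
are those single-copy in every ingroup genome *and* in the outgroup, since
the outgroup must appear in every supermatrix partition; if the outgroup
is too distant for the 50 % identity filter, no such clusters exist and
the run stops with an explicit error rather than building an unrootable
tree.

## Similarity metrics

- **AAI**: unweighted mean identity over RBH pairs computed at E ≤ 10⁻⁵
  and coverage ≥ 50 % with *no identity floor* — AAI must remain
  measurable below 50 %, where genus boundaries live. Pairs with no RBH at
  all yield a missing value (NaN), never 0; missing values propagate and
  are excluded from correlations and histograms.
- **ANI** (fragment-based orthologous form): assemblies are cut into
  consecutive non-overlapping 1020 bp windows (0-based half-open, trailing
  remainder discarded); fragments are aligned all-vs-all on both strands;
  reciprocal best fragment pairs with ≥ 70 % coverage on both fragments
  are retained and their mean identity is the ANI.
- **POCP** = 100·(C₁+C₂)/(T₁+T₂), where Cᵢ counts genome i's proteins with
  ≥ 1 qualifying one-way hit (identity ≥ 40 %, coverage ≥ 50 %, E ≤ 10⁻⁵)
  in the other genome — any passing hit, not only the best or a reciprocal
  one, matching the original definition of "conserved". An RBH-based
  variant is available but off by default.

All three metrics are symmetric by construction; matrices carry 100 on the
diagonal (0 for the distance matrix) and NaN for missing pairs.

## Core-genome phylogeny

Each tree cluster is aligned progressively: 3-mer count distances feed a
UPGMA guide tree (average linkage), profiles are merged bottom-up by
global profile–profile alignment with affine gaps (expected BLOSUM62
column score; gap symbols inside a profile score 0), and input order
cannot change the result because sequences are sorted by id first.
Columns with gap fraction > 0.2 are removed — a deliberately simple
reliability filter standing in for heuristic auto-trimming. Trimmed
alignments are concatenated into a supermatrix with a recorded
cluster→column-interval partition map.

Distances are Kimura-corrected protein distances,
`d = −ln(1 − p − 0.2 p²)` on the proportion p of mismatching residues over
gap-free columns, capped at d = 5 when p ≥ 0.85 (the correction diverges at
saturation). The tree is Saitou–Nei neighbor joining; negative branch
estimates are clamped to 0 (simple clamp, no transfer to the sibling).
Rooting consumes the outgroup when present (root at the midpoint of the
outgroup's edge, placing it sister to all ingroup taxa); otherwise the
root sits at the midpoint of the longest leaf-to-leaf path, computed
in-repo. Distance-based inference replaces maximum-likelihood here on
purpose: the demarcation consumes topology and relative distances, NJ
recovers both exactly on additive inputs (tested to 1e-9), and the whole
stage stays fast and deterministic. Bootstrap support is not computed.

"Evolutionary distance" between two genomes is the patristic distance on
this tree. The alternative — Kimura distances read directly off the
supermatrix — is available (`distance_source="supermatrix"`); the two
agree closely whenever the distances are nearly additive, and the tree
variant is the default because the demarcation thresholds are tree-scale.

## Genus demarcation

Pre-order traversal from the root; a clade is emitted as a genus when

1. max pairwise evolutionary distance ≤ `dist_max` (default 0.4
   substitutions/site) — a strict maximum; and
2. the fraction of its pairwise AAI values ≥ `aai_min` (default 70 %) is at
   least `aai_pass_fraction` (default 0.95), with missing AAI pairs
   excluded from the denominator.

Failing clades are split into their children and re-tested; leaves pass
trivially, so singleton genera are allowed. The traversal yields *maximal*
compliant clades — the coarsest partition consistent with the thresholds —
and monophyly holds by construction. The AAI criterion is a pass fraction
rather than a strict minimum because a genus-level clade can contain one
aberrant pair (e.g. a single pair at 67 % AAI inside a clade whose other
96.8 % of pairs clear 70 %) that a strict rule would shatter; the distance
criterion stays strict. Tightening either threshold can only refine the
partition, never merge groups (tested). `major_clades` provides a
reproducible n-top clade labeling (repeatedly split the largest remaining
clade at its root) for inter/intra-clade comparisons.

## Statistics

Metric cross-correlations are Pearson product-moment correlations over
shared non-missing upper-triangle entries (Spearman available via
argument); the choice of Pearson is the conventional reading of an
unqualified "correlation coefficient". Inter- vs intra-group separation
uses Welch's unequal-variance two-sample two-sided t-test — the safer
default when group sizes and spreads differ. P-values below 2.2×10⁻¹⁶ are
printed as "<2.2e-16" (the customary double-precision floor) while the
numeric value is kept internally; degenerate zero-variance samples with
different means report infinite t and p = 0.

## Synthetic data

The simulator is built for analytic checkability, not realism. Ancestral
genes (default 100, lengths uniform in 150–300 residues) are i.i.d.
uniform over the 20 amino acids and evolve down a known tree. Amino-acid
substitution events arrive as Poisson(rate·t·L) per gene per branch
(default rate 1 per site per unit branch length, so branch lengths read in
substitutions/site), each event drawing the new residue uniformly — hence
the closed form E[identity] = 100·(e^(−d) + (1−e^(−d))/20) at path
divergence d, against which pipeline AAI is tested. Genes are represented
at the codon level: an event rewrites the affected codon with a uniform
synonymous codon of the new residue, and additional synonymous resampling
events (default 3 per codon per unit branch) make nucleotide identity
decay faster than amino-acid identity, reproducing the synonymous
buffering seen in real genomes. Gene gain (novel random genes, default 0.2
per resident gene per unit branch), loss (0.1 per gene per unit branch)
and duplication (probability 0.02 per gene per branch) create accessory,
unique and multi-copy clusters.

The default tree plants 3 genera × 4 genomes with within-genus path
divergence 0.3 and between-genus 0.6 substitutions/site — bracketing the
0.4/70 % thresholds so recovery is informative but not trivial. Nucleotide
genomes, when requested, lay core genes in a shared ancestral order with
ancestral 50–200 bp spacers (mutated per lineage at the neutral closed-form
rate) on 2–5 contigs, half of which are emitted reverse-complemented; this
preserves synteny so fragment-based ANI is well defined while exercising
windowing and strand handling. All randomness flows from a single seeded
generator; identical config and seed give byte-identical output.

What the simulator does *not* emulate — empirical exchangeability (it is
not WAG/LG), within-gene indels, rate heterogeneity across sites, codon
usage bias, horizontal transfer — bounds what passing tests mean: they
validate the pipeline's algorithms and bookkeeping, not its robustness to
every real-data pathology. In particular, real alignments contain indels
(the MSA and trimming stages are exercised by truncated homologs in unit
tests instead), and real outgroups can be too distant for the 50 %
identity orthology filter, which the pipeline reports as an explicit
error.

## Problem sizes and numerical choices

Tests and the acceptance script run the full chain on 12-genome,
~100-gene-per-genome simulations (about half a minute per seed), which is
where the planted structure is already non-trivial; the pipeline itself
has no size-dependent switches, so behavior at family scale (~75 genomes,
~3000 proteins each) differs only in runtime. Alignment scores are float32
(exact for integer-valued scoring up to 2²⁴); NJ and patristic arithmetic
are float64; matrix symmetry is asserted to 1e-9; the supermatrix/NJ
round-trip tolerance is 1e-9. Ties are broken deterministically
everywhere: best hits by identity, then aligned columns, then subject id;
NJ joins by the Q-criterion, then distance, then index; demarcation group
ids by smallest member.
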