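# Methods

## Scope and model

`zfselect` analyzes selections from degenerate zinc-finger libraries in
which 5 or 6 recognition-helix codons are randomized with the NNS scheme
(N = A/C/G/T at codon positions 1–2, S = C/G at position 3). The scheme's 32
codons encode all 20 amino acids plus one stop (TAG); per-residue degeneracy
d(aa) ranges from 1 (M, W, and several others) to 3 (L, R, S). The standard
genetic code is fixed (NCBI table 1; the constructs are expressed in
E. coli/yeast), taken from biopython. Alternative schemes can be supplied as
a config of three base sets; everything downstream is parameterized by the
scheme.

## Library diversity

The theoretical variant count of a library with `i` variable codons is
`N = 32^i` (exact integer arithmetic). The expected number of distinct
variants among `n` uniform draws is `U(n, N) = N(1 − (1 − 1/N)^n)`,
evaluated as `−N·expm1(n·log1p(−1/N))`. The naive float form loses all
leading digits of `N − U` once `N ≳ 1e9`; the stable form agrees with exact
rational arithmetic to better than 1e-12 relative error up to `N = 1e10`
(tested). Observed-diversity curves are produced by without-replacement
subsampling of the read multiset (multivariate hypergeometric, seeded),
which reproduces the observed unique count exactly at full depth;
`expected_unique` itself is the with-replacement expectation and is what the
curve is compared against. Positional bias is reported as count-weighted
base frequencies per codon slot against the uniform-over-allowed-bases
expectation, with a per-position chi-square over allowed bases.

Two caveats on the diversity invariants: the "all-unique" regime
`U/n ≥ 0.999` at `n = √N` holds only for library-scale `N` (it is
`1 − (n−1)/2N ≈ 1 − 1/(2√N)`), and strict monotonicity of `U` in `N` is not
float-resolvable for unit increments at large `N`; the tests state both
properties in their numerically meaningful form.

## Read processing

Amplicons are treated as barcode + 5′ constant + variable region + 3′
constant/adapter. Demultiplexing is exact-prefix (no error correction — no
tolerance policy is defensible without knowing barcode distances, and the
barcodes in this design are well separated). Structural filtering requires
every constant position to match the template; the mismatch tolerance is a
knob with default 0, the strictest reading of "remove reads with mismatches
in constant regions". Base qualities are ignored: the filter is structural.
Variant extraction slices the variable span and drops variants below a
minimum count (default 1 for helix pools, 2 for 28-bp site pools).

## Coding-entropy filter

DNA variants are translated codon-wise; variants with a codon outside the
scheme are discarded as sequencing artifacts (the S position cannot read A/T
without an error), and in-frame-stop variants are excluded from
protein-level aggregation while remaining in DNA-level diversity counts.
Non-scheme takes precedence over stop so that artifacts are not
misclassified. Per protein, the normalized coding entropy is
`E = −Σ pᵢ ln pᵢ / ln N` over observed encodings (0·ln 0 = 0; natural log —
any base cancels in the ratio). Retention: `E ≥ 0.25` (inclusive) or
`N = 1`. No minimum read count is applied before scoring. E is clamped at 1
against float excursions for exactly uniform counts.

## Clustering

Similarity is ungapped position-wise BLOSUM62, normalized by the geometric
mean of self-scores and clamped at zero: symmetric, identity 1, range
[0, 1]. Geometric-mean normalization was chosen over min–max because it
needs no corpus-dependent score range; it is the package's interpretation of
"normalized to be between 0 and 1" and is isolated in one function should a
different strategy be wanted. Edges require similarity strictly above 0.25.

Clustering is a from-scratch implementation of the SPICi greedy
density-based algorithm with its published defaults (support 0.5, density
0.5): seed at the highest weighted-degree vertex, take the best neighbour
from the highest occupied edge-weight bin as a second seed, then repeatedly
add the unclustered neighbour of maximal support while the support and
density thresholds hold; extracted vertices are removed and the search
repeats. All ties (degree, support) break toward the lexicographically
smaller sequence, making output independent of input order. On disjoint
unions of cliques the output equals the cliques of size ≥ 10 exactly
(oracle-tested); every reported cluster's induced density is ≥ 0.5 by
construction. Clusters below 10 members are not reported, and count shares
are computed over the counts of clustered (reported) sequences — the
denominator choice that matches quoting "sequences that passed the entropy
filter and were found in clusters"; it is configurable in effect because
shares can be recomputed from the emitted member counts.

"Similar cluster at high stringency" is operationalized as
consensus-to-consensus similarity strictly above the same 0.25 edge
threshold; the consensus is the count-weighted modal residue per position
with alphabetical tie-break.

## Binding-site motifs

Sites observed ≥ 2 times are greedily grouped: descending count order (ties
lexicographic), each variant joins the first group — in creation order —
whose representative is within 2 mismatches, else founds a group. Membership
is tested against representatives only, the simplest greedy reading; the
stated sort makes grouping deterministic and order-invariant, and the
founder is by construction the highest-count member.

Motif discovery is a built-in multi-start EM under the OOPS model (exactly
one occurrence per 28-mer, uniform offset prior over offsets 0–18, uniform
zero-order background), fixed width 10. Representatives are weighted by
group counts. Each start seeds the frequency matrix from a random window
(0.55 on the seen base, 0.15 elsewhere); pseudocounts of 0.25 per cell act
as a Dirichlet prior, and the recorded per-iteration objective is the
penalized log-likelihood, which the EM guarantee makes non-decreasing
(asserted per run). Because offset models have phase-shifted local optima, a
converged fit is refined by re-running EM from ±1–2 column shifts of the
matrix until no shift improves the objective — with this step a planted
10-bp motif at 10% per-position noise in 200 sites is recovered at ≥ 9/10
consensus positions in 20/20 seeded replicates. Matches are the best
log-odds offset per original site, given strand only by default (amplicons
are promoter-oriented); a loader for MEME minimal-format motifs lets users
substitute an external finder.

## Logos

Protein logos weight sequences by raw read counts. DNA match logos default
to weight `ln(1 + count)`: "log of the observed frequencies" leaves the
offset unstated, and `log1p` keeps singleton weights positive while
preserving the intended compression of jackpot counts; raw and unit policies
are available. Information content is `log2|alphabet| − H` per position with
no small-sample correction. Output is matrix TSV / transfac-like text;
rendering is left to plotting tools.

## Synthetic pools

The generator produces the three pool types with the statistical structure
the pipeline assumes, under one integer seed with full ground-truth labels:

* **Library pools** — i.i.d. scheme-restricted draws, optional per-slot base
  bias (emulating oligo synthesis bias), optional constant flanks with a
  per-position constant-region error rate.
* **Selection pools** — binder families defined by a center helix, a
  per-position substitution rate, and a read share; each read's protein is a
  substituted center and its DNA encoding is drawn uniformly over the NNS
  encoding set (each residue's codon uniform over its scheme codons), the
  idealized null the entropy filter assumes. Artifact clones are one protein
  pinned to one fixed encoding. The remaining share is uniform library
  background.
* **Site pools** — 28-mers with a motif instance sampled from a frequency
  matrix at a uniform random offset in uniform flanks; read counts are
  geometric so the ≥ 2-count filter is exercised.

Default study conditions for the planted-selection experiments: two families
centered at `QGNKS` and `WLFPM` (cross-similarity 0.0 by enumeration),
substitution rate 0.1 (members of a specificity group typically differ from
the dominant helix at zero or one position), shares 0.45 each, 20
single-encoding artifact clones at 0.005 each, depth 10⁴. These sizes keep
every stage observable at desk scale: well-covered single-substitution
mutants (~15 reads each) populate each family's cluster, while artifact
clones get ~50 reads — abundant enough that an abundance filter would keep
them, which is exactly the failure mode the entropy filter exists to avoid.

What the generator does **not** emulate: PCR amplification bias and
chimeras, base-call errors inside the variable region, selection
thermodynamics (stringency is only a label), and correlated substitution
patterns within a family. Passing tests therefore demonstrate the pipeline's
correctness and its discrimination under the idealized encoding-usage null,
not performance on real sequencing artifacts.

## Problem sizes and numerical choices

Test and demonstration pools use depths of 10³–10⁵ reads and 3-codon
libraries for diversity checks (N = 32³ keeps saturation visible), 10⁴-read
selection pools, and 120–200-site motif pools with 20 replicates — sizes at
which every statistical property being asserted is already resolvable.
EM converges at objective tolerance 1e-8 with ≤ 200 iterations; similarity
and clustering are exact computations with lexicographic tie-breaks;
subsampling and all generators take explicit seeds.

## Known limitations

* Count shares and cluster membership depend on the SPICi-style heuristic;
  different but equally valid clusterings exist near the density threshold.
* The motif finder fits a single motif (OOPS); pools with two motifs will
  return the stronger one only.
* Entropy filtering presumes encoding usage roughly proportional to
  availability; strong codon-usage selection inside one protein could push a
  true binder below 0.25 (the generator's skew knob exists to explore this).
* Diversity comparison assumes a uniform library; it quantifies departure
  from uniformity but does not estimate true richness.
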