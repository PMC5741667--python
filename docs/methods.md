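# Methods

This note records the models behind each computation, the parameters that
matter, and the choices made where the design was genuinely open.

## Transposon copy simulation

Copies of a family are simulated under one of two substitution models, both
built on independent per-site replacement with a uniformly chosen *different*
base (Jukes–Cantor-like single-hit process; a site hit with probability *p*
always changes, so the expected divergence contributed by one branch of
weight *p* is *p* itself, with multiple-hit saturation entering only through
the composition of branches). No indels are simulated by default — the
distances downstream are identity-based, and indel-free copies make
alignment-free oracles (Hamming counts) exact.

* **`lineage` (default).** The active element evolves through time; a copy
  inserted at relative age *a* branches off the lineage state at *a* and then
  accumulates its own substitutions over duration *a* at per-site rate *r*.
  Any two copies with branch ages a₁ ≤ a₂ are separated by the path
  a₁ + (a₂ − a₁) + a₂, so their expected distance is ≈ 2·r·a₂ — distances
  depend on the *older* member of the pair. A two-burst family therefore
  shows a **bimodal** pairwise-distance landscape (a tight young mode at
  2·r·a_young and one merged mode for every pair touching the old burst),
  which is what real divergence landscapes of twice-expanded families look
  like. This is the model the landscape and burst-detection stages are
  validated against.
* **`star`.** Every copy derives independently from a frozen master with
  substitution probability r·a. Within-burst distances are the same as under
  `lineage`, but cross-burst pairs sit at an intermediate distance, and the
  per-column majority of the copies converges to the master itself. This is
  the natural model for validating consensus assembly ("x% per-copy
  divergence" has exactly one meaning here); under `lineage` the majority
  consensus instead reconstructs the burst-age ancestor, which differs from
  the present-day master by the shared lineage mutations (≈ r·a).

A saturation guard rejects specs with r × max(age) ≥ 0.75. Bursts may be
given a temporal half-width (`burst_age_spread`, default 0 so copies of one
burst share an age exactly). Planted ORFs use a fixed one-codon-per-residue
reverse translation so the domain peptide is embedded intact.

Planting fills a contig of exactly `background_length` i.i.d. uniform ACGT
bases and overwrites disjoint uniform-random intervals with the copies,
each on a random strand; coordinates are 0-based half-open and BED6 scores
carry age × 1000. Occupancy is capped at 50% of the background; placement
uses bounded rejection sampling (500 tries per copy).

## Pairwise distances

Distance = 1 − matches / aligned-core columns under a global alignment with
free end gaps, scored match +1, mismatch −1, gap run of length ℓ −(5 + ℓ).
Three engines share this definition:

1. equal-length pairs with position-wise identity ≥ 0.5 are compared
   ungapped — under these gap costs a gap pair must convert ≥ 7 mismatches
   to pay for itself, which substitution divergence below saturation does
   not produce, so the ungapped alignment is the affine optimum (the test
   suite cross-checks this against the full dynamic program);
2. other pairs are aligned within a band around the diagonals voted for by
   shared 13-mers (half-width ≥ 32, widened to cover the voted spread),
   with full traceback, compiled via numba;
3. pairs the band cannot anchor (or with diffuse anchoring, spread > 400)
   fall back to Biopython's exact dynamic program.

The fast path is what makes all-against-all matrices of hundreds of 2 kb
copies affordable; its known limitation is an equal-length pair whose true
alignment contains compensating indels yet whose ungapped identity still
exceeds 0.5 — internally shuffled copies of that kind are not produced by
the generator and are rare in practice.

A pair is *valid* when the aligned core covers ≥ `min_mutual_coverage`
(default 0.8) of **both** copies. Copies are dropped greedily — fewest valid
pairs first, ties broken by shorter copy — until every retained pair is
valid; fewer than three survivors is an error.

## Burst detection

The flattened upper triangle of the distance matrix is fitted with 1-, 2-
and 3-component one-dimensional Gaussian mixtures (scikit-learn; variance
floor 1e-6). Each component count is fitted twice — once from deterministic
quantile-spaced means, once as the best of 20 seeded random restarts — and
scored by **ICL** (BIC plus twice the total assignment entropy). ICL rather
than plain BIC because the question is *how many clusters*, not how many
Gaussians best approximate the density: with thousands of distance values,
BIC detects any non-normality inside a single hump (ΔBIC in the hundreds
for splitting one mode) and systematically overcounts, while ICL's entropy
term cancels exactly those splits whose components overlap. A more complex
model is accepted only when it improves the accepted simpler one by a
margin of 10 (strong-evidence convention). On well-separated Gaussian data
ICL and BIC agree, so the standard invariants (one mode on N(μ, σ); two
modes at ≥ 4σ separation) hold.

## Neighbor joining and midpoint rooting

Saitou–Nei agglomeration with the Studier–Keppler Q criterion; ties in Q
are broken by the smallest (row, column) index pair, and negative branch
lengths are clamped to zero with the deficit moved to the sibling branch so
the joined pair's separation is preserved. The unrooted topology is built
as a weighted graph and rooted at the exact midpoint of the longest
leaf-to-leaf path (root inserted on the covering edge), then converted to a
`Bio.Phylo` tree for Newick output. On additive matrices NJ is exact, which
the suite uses as an oracle (random 4–6 leaf trees; distances and midpoint
balance both within 1e-9). Bootstrap support is out of scope.

## Consensus assembly

Seeds are taken in order of descending canonical k-mer count (ties
lexicographic). Extension appends the majority base; it stops when the best
candidate count falls below `min_count`, when the top two candidates tie
(refusing to guess at branch points rather than risking chimeras), when a
k-mer repeats within the growing contig, when it reaches a k-mer already
consumed by a finished consensus (each family is assembled once), or at
`max_length` (default 20 000 — repeat families are kb-scale and the cap
stops runaway extension through low-complexity sequence). All k-mers of a
finished contig are consumed whether the contig is emitted (≥ `min_length`,
default 1000) or discarded. `min_count` defaults to 10; for divergent
families the useful setting sits above the unique-background depth (1) and
below the expected intact-window depth n_copies × (1 − d)^k — e.g. 30
copies at 5% divergence give 30 × 0.95²⁵ ≈ 8, and `min_count = 2` lets
extension ride through the occasional depth dip.

Classification returns the reference with the longest local alignment
≥ `min_align_length` (ties: higher identity, then lexicographic label),
both orientations considered. Copy recovery clusters exact 15-mer seed hits
by implied copy start and strand, aligns the consensus to each candidate
window, keeps hits with identity ≥ `min_identity` over ≥ `min_length`
columns, and resolves overlaps by identity, then length.

## Domain retention

Copies are translated in all six frames; stops split a frame into ORF
fragments, and fragments ≥ 20 aa are aligned locally (BLOSUM62, gap
−11/−1) to each domain peptide. A copy retains the domain when some
fragment reaches ≥ 60% of the peptide's self-score over ≥ 60% of its
length. The bundled Myb-like and RT-like peptides are synthetic stand-ins
with domain-like composition, not database profiles — adequate because the
generator plants exactly these peptides and the measurement is of ORF
disruption, not remote homology.

## Tau

τ = 1 − (1/n) Σ xᵢ/max(x), the maximal tissue included in the average —
so uniform expression gives exactly 0 and a single-tissue gene 1 − 1/n.
The widespread variant that omits the maximum and divides by n − 1
(reaching exactly 1 for a one-tissue gene) is exposed as
`method="yanai"` for comparison. Genes with maximal expression below
`min_tpm` (default 1) are excluded rather than allowed to produce
noise-driven τ ≈ 1; replicates, when declared, are averaged per tissue
first. Group comparison is the two-sided Mann–Whitney U with normal
approximation and tie correction; an all-tied input short-circuits to the
null (U = n₁n₂/2, p = 1).

## miRNA counting

Scanning compares every genome window (both strands) to the mature with a
vectorized mismatch count; the seed span — AAGUGC where it lies within the
first eight nucleotides, otherwise the canonical positions 2–7 — must match
exactly, with ≤ `max_mismatches` (≤ 3) tolerated elsewhere. Overlapping
hits merge keeping fewer mismatches. "Within the first eight nucleotides"
is read as the hexamer fully inside positions 1–8 (1-based starts 1–3);
the boundary cases are pinned in tests. Hairpin secondary-structure
validation is deliberately out of scope; simulated precursors embed the
(possibly mutated, seed-sparing) mature in a flanked template, and the
default families plant 155 and 66 loci. The simulated hairpin template
carries no complementary star arm — a perfect stem would put the mature's
reverse complement on the same locus and double every count.

## Cytometry

Pure arithmetic: 2C = 2C_ref × peak ratio; haploid Gb = 0.978 × 2C / 2.
All rounding (one decimal pg, two decimals Gb) happens in the reporting
layer only; the printed Gb value is not reproducible from the printed pg
value, which is why the unrounded 2C is carried through.

## Pipeline and determinism

Stages run in dependency order off one flat key = value config (unknown
keys rejected by name; referenced paths must resolve before any stage
runs). Every artifact is a text format (FASTA, BED6, TSV, PHYLIP square
matrix, Newick, JSON manifest); the manifest records parameters and
SHA-256 checksums and no timestamps, so a rerun with the same config is
byte-identical. All randomness descends from the config seed through
per-stage offsets.

## What the generator does and does not emulate

The generator reproduces the statistical structure the analyses key on:
copy-number depth for k-mer assembly, burst-structured divergence for the
landscape, seed-bearing repeated precursors for miRNA counting,
fold-concentrated expression for tau, and a linear peak ratio for
cytometry. It does not emulate sequencing error, assembly fragmentation or
collapse of near-identical repeats, indel mutation, nested/fragmented TE
insertions, GC-biased background composition, hairpin secondary structure,
or count overdispersion beyond log-normal noise. Passing recovery tests on
this synthetic data therefore demonstrates the correctness of the
computations under their stated models, not robustness to every artifact
of real giant-genome data.

## Problem sizes

Defaults are sized so the whole suite runs in well under half an hour on
one core: demo genome 300 kb with ~40 repeat copies per assembled family,
burst detection validated on 50 + 50 copies of 2 kb across 20 seeds per
scenario, miRNA recovery on the full 155 + 66 loci, NJ oracles on 4–6
leaves × 50 matrices. Every stage scales to larger inputs linearly in
genome length (k-mer counting, scanning) or quadratically in copy number
(distance matrices), with the banded aligner keeping the per-pair cost at
milliseconds for kb-scale copies.
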