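# Methods

## Problem and labeling convention

Splicing removes introns from pre-mRNA at a donor site (the exon→intron
boundary, canonically `GT` at the intron start) and an acceptor site (the
intron→exon boundary, canonically `AG` at the intron end). The package
frames splice-site prediction as dense per-base classification of the
sense-strand gene sequence into {non-splice, acceptor, donor}, encoded
one-hot as `[1,0,0] / [0,1,0] / [0,0,1]` with `[0,0,0]` marking padding.
A/C/G/T(U) are encoded as unit vectors and every other symbol as a zero
row; soft-masked lowercase is uppercased first.

The annotation formats are 1-based inclusive; all internal tracks are
0-based; BED output is 0-based half-open. The donor label sits on the last
exonic base upstream of an intron and the acceptor label on the first
exonic base downstream of it. This choice (rather than labeling the
intronic dinucleotides) follows the exon-boundary semantics of the model
family this package belongs to, and is recorded in archive metadata so a
dataset is auditable. Minus-strand genes are reverse-complemented before
encoding, so the model always sees the sense strand; predicted coordinates
are mapped back to the plus strand on output.

## Dataset construction

For each gene locus the longest transcript (genomic span; ties broken by
lexicographically smallest transcript id, for determinism) is the canonical
transcript and the only one labeled. By default only protein-coding genes
enter the dataset; pseudogenes (feature type `pseudogene`, or biotype in
{pseudogene, transcribed_pseudogene, processed_pseudogene}) are removed
from the test side, and test genes aligning to any training gene with
identity > 0.8 and query coverage > 0.8 are removed as paralogs.
The aligner is an interface: the production backend shells out to minimap2
(`-x asm20`, tolerating ~20% divergence) and parses PAF matches /
block-length as identity; an exact Smith–Waterman backend (Biopython's
`PairwiseAligner`) serves short fixtures and acts as the independent oracle
in tests. Whether paralogy should be judged on gene-span DNA or on
transcript sequence is not fully determined by the sources we follow; we
use gene-span DNA.

Genes are segmented into windows of `5000 + flank` nt whose 5,000-nt cores
tile the gene disjointly (`n_segments = ceil(L / 5000)`); the flank/2
context on each side comes from the gene where available and is padded
otherwise (zero feature rows, all-zero label rows). Cores tile disjointly
— the "overlap" between adjacent windows is context only — which is the
only reading under which every base is predicted exactly once.
Archives are HDF5 with batch groups of up to 100 genes (`X{i}` float32
one-hot, `Y{i}` uint8 labels, per-gene ids and segment counts for lossless
reconstruction).

Chromosome-level splits: the fixed human assignment (test chromosomes 1,
3, 5, 7, 9; the rest train) or a seeded random split that shuffles
chromosomes and greedily accumulates them into the training set until at
least the requested fraction (default 0.8) of total length is covered.
The split seed defaults to 10, the first seed of the standard ensemble
convention (seeds 10–14).

## Architecture and training

See the README for the network structure and the CL law. Open details
resolved here: the hidden width L is 32 channels by default (the published
tables omit it; 32 is the predecessor's value) and both convolutions of a
residual unit share that unit's (W, AR) entry. Batch normalization uses
mini-batch statistics in training and running averages at inference, so
evaluation is deterministic; training-mode batch statistics remain an
acknowledged nondeterminism source. Initialization is He-style, seeded.

Losses are averaged over non-pad positions (sum-versus-mean is not fixed
by the printed formulas; the mean keeps magnitudes comparable across batch
sizes), with the conventional leading negative sign and an ε = 10⁻¹⁰ clamp
inside the logarithm. Early stopping counts epochs with *no improvement by
any margin* in validation loss and restores the best-validation
checkpoint. Transfer learning loads a checkpoint into an
architecture-compatible configuration and either unfreezes everything or
only the last *k* parameterized layers; frozen parameters are bit-identical
after training (batch-norm running averages are buffers, not parameters,
and continue to track statistics).

The network and optimizer are a self-contained numpy implementation with
hand-written backpropagation (`spliceworks.nn`): dilated same-padded 1-D
convolutions, batch norm, LeakyReLU, and decoupled-weight-decay Adam.
Gradients are verified against finite differences in the test suite.

## Calibration

Class-wise temperature scaling: logit column c is divided by T\_c before
the softmax. T is fitted on the validation split (scorer frozen) by
full-batch Adam at lr 0.01 with a plateau reduction (factor 0.1 after two
non-improving epochs), early stopping at a minimum improvement of 10⁻⁶,
and projection into [0.05, 5.0] after every step; a coarse grid search over
the box is kept as a test oracle. Diagnostics: NLL; expected calibration
error over 30 uniform-width right-closed confidence bins (empty bins
contribute zero); and per-class one-vs-rest reliability curves with normal
approximation 95% intervals (`p̂ ± 1.96·√(p̂(1−p̂)/n)`, clamped to [0,1]),
cross-checked against scikit-learn's `calibration_curve` binning.

One caveat, asserted in tests rather than assumed: with distinct per-class
temperatures the argmax *can* change, and cross-position ranking by softmax
probability is not invariant (denominators differ per position). What is
preserved is the ordering of positions by each class's logit — hence
per-class top-k accuracy computed on class scores — and the calibration
report counts argmax changes explicitly.

## Prediction

Targets longer than `split_threshold` (default 1,500,000 nt) are chunked
with junction overlaps of flank/2; each chunk reports its interior half of
every overlap, so reassembly covers each position exactly once. Within a
chunk, windows of `5000 + flank` with disjoint 5,000-nt cores are N-padded
at the chunk ends and for a short final core. Member predictions of an
ensemble (which must share one flank/CL) are arithmetically averaged, and
the result is independent of batch size. Sites with class probability
strictly above the threshold (default 0.5) are written to donor and
acceptor BED6 files; with an annotation the coordinates are genomic
(minus-strand sites mapped to plus-strand positions), otherwise
sequence-relative from 0. The streaming ("turbo") path and the
track-storing path share the BED emission code and emit identical files.
Chunking is exact — not merely approximate — whenever the scorer's true
receptive radius is at most a quarter of the flank, which holds for the
standard configurations' junction geometry and for the mock scorer used in
tests. N-padding at gene boundaries is the default; real genomic context
can be substituted by the caller supplying wider targets (boundary
N-padding is a known bias of models trained this way).

## Variant delta scores

Accepted variants are scored on reference and alternate windows spanning
the variant ± (distance + flank/2), distance defaulting to 50 (a
101-position comparison window). Exclusions, each skip logged with a
machine-readable reason: variants outside annotated genes, closer than
`flank` to a chromosome end, deletions longer than 2·distance, and
reference-allele mismatches. For indels the alternate score array is
realigned to the reference frame: slots of deleted bases are masked out of
the comparison; scores across an insertion are collapsed onto the anchor
slot by maximum. The four deltas are the maxima of the signed differences
(donor loss defined by symmetry with the acceptor formulas, as the printed
source's fourth formula is a typographical duplicate of the third);
negative maxima are clipped to 0 in the reported scores with the signed
value kept in a debug field, and delta-position ties resolve to the
smallest absolute offset, then upstream. Minus-strand genes are scored on
the reverse complement and the score arrays flipped back, so delta
positions stay genomic.

## Evaluation and mutagenesis

Top-k accuracy extracts the `k·n_true` highest-scoring positions per class
(score ties broken by position index) and reports the fraction that are
true sites. Thresholded metrics use the standard definitions — precision
TP/(TP+FP), recall TP/(TP+FN), accuracy (TP+TN)/total, F1 the harmonic
mean — because the printed formulas in the source material are internally
inconsistent (an accuracy numerator of TP+FP, a precision denominator of
TP+FN, a recall denominator of TP+TN); zero denominators yield 0 with a
warning, and a score exactly at the threshold is a negative call. AUPRC is
scikit-learn's `average_precision_score`, verified against an exhaustive
threshold sweep on all inputs of ≤ 100 positions.

ISM importance at a position defaults to `S_ref − mean(S over the three
non-reference substitutions)`, which makes a position the scorer ignores
score exactly 0; the 4-base mean that includes the reference (scaling
importances by 3/4) is available behind a flag for literal reproduction of
the alternative convention. Scoring uses real sequence context (no
N-padding) and ensemble averaging precedes the ISM differencing. Logo
matrices are elementwise means of per-site decrease matrices; profile
concordance is Pearson's r, reported as missing for zero-variance profiles.

## Synthetic fixtures

The generator plants multi-exon protein-coding genes (default: 20 genes on
6 chromosomes, 2–4 exons of 100–300 nt, introns of 150–400 nt, both strands
equally likely) with fixed extended consensus motifs — donor `CAG|GTAAGT`,
acceptor `TTTTTC AG|G` with a polypyrimidine run, and GC-AG / AT-AC /
noncanonical variants on request — plus pseudogene decoys (10%), paralog
pairs (10%, 5% per-base divergence with splice motifs conserved, as in real
paralogs), and, in long introns, "cryptic" donor motifs dead at the +2
position so a single substitution can activate them. Background sequence is
uniform i.i.d. ACGT, and exact consensus 9-mers arising by chance outside
planted sites are scrubbed, so the planted sites are the only perfect
motifs. Identical specs produce byte-identical FASTA/GFF3/VCF/truth-table
outputs.

The mock scorer is a weighted consensus matcher (GT/AG dinucleotide
positions weighted 3×) with a declared cropping length of 80: exact matches
score ≈ 0.997 and the best possible near-miss stays below 0.1. It satisfies
the scorer contract exactly and stands in for a trained network wherever
training would be beside the point (prediction plumbing, variant deltas,
mutagenesis).

What the fixtures do *not* emulate — realistic base composition, repeats,
intron-length distributions, degenerate real-world splice-site motifs —
bounds what passing tests show: they demonstrate that the machinery is
correct and that the model class can learn strong, planted signals, not
that desk-scale training approaches published accuracy on real genomes,
which requires genome-scale data and long training.

## Learnability protocol and problem sizes

The end-to-end learnability experiment trains the tiny configuration
(4 residual units, W = 5, 8 channels, CL = flank = 32) on a 120-gene
fixture genome (random 80:20 chromosome split, 90:10 gene-level
validation split), cosine schedule, batch size 2, 25 epochs with early
stopping disabled — warm restarts cause transient validation-loss bumps
that would otherwise trigger the patience rule — and evaluates top-1
accuracy on the validation genes. Because single-seed training on so small
a dataset occasionally settles in a weak optimum, the experiment follows
the standard deep-ensemble convention: three members trained from
staggered seeds, predictions averaged. The ensemble reaches validation
top-1 donor accuracy above 0.9 (typically 1.0) in about two minutes on one
CPU. All other tests run on the 20-gene default fixture in seconds.

## Known limitations

- The numpy implementation is CPU-bound and desk-scale; the four standard
  configurations instantiate and run forward passes, but genome-scale
  training is out of reach by design.
- Only the canonical (longest) transcript is labeled; alternative isoforms
  and intergenic training regions are out of scope.
- The in-memory gene-interval lookup for variants is linear per
  chromosome; adequate for desk scale, an interval tree would be the
  next step for dense VCFs.
- Structural variants and legacy third-party checkpoint formats are not
  supported.
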