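# Methods

## The IEA statistic

For amino-acid category *i* with *nᵢ* ≥ 2 synonymous codons, the information
entropy of amino acid is the base-*nᵢ* Shannon entropy of the observed
synonymous-codon frequencies *pᵢⱼ* in a genome:

IEAᵢ = Σⱼ pᵢⱼ log_{nᵢ}(1/pᵢⱼ).

The logarithm base equals the degeneracy so that every category lies in
[0, 1]: 1 at uniform usage, 0 when one codon is used exclusively. Under the
bacterial code (NCBI translation table 11, the default; configurable) there
are 19 categories — the 18 amino acids with more than one codon plus a
pooled "stop amino acid" covering the three stop codons. Methionine and
tryptophan (single codons) carry no entropy and are excluded.

Conventions:

* 0 · log(1/0) := 0 (zero-frequency codons contribute nothing);
* a category with **no** observed codons is *missing* (NaN), never 0 —
  zero is a meaningful entropy value and must not be conflated with
  absence; missing values are excluded pairwise in group comparisons;
* floating-point overshoot above 1 is clamped (tolerance 1e−12);
* an IEA of exactly 1 requires every one of the *nᵢ* codons to be observed
  equally often; equal frequencies over a *subset* of codons give
  log(k)/log(nᵢ) < 1.

Codon counting uses annotated CDS features when the input provides them
(GenBank). For plain FASTA an ORF fallback reports stop-to-stop open
reading frames on both strands (start codons ATG/GTG/TTG, default minimum
60 codons, stop included); only stop-closed ORFs are used, which discards
open-ended runs and the frame-shift noise they carry. Trailing partial
codons are dropped with a logged warning; codons containing ambiguity
symbols are skipped. Whether to use annotation or prediction is exposed
(`orf_fallback`), not guessed.

Group comparison (`compare_groups`) reports, per category: NaN-excluded
group means, the AUC of that single IEA as a classifier of the two groups
(Mann–Whitney U normalized by the product of group sizes, mid-rank ties),
and the two-sided Wilcoxon rank-sum p-value — exact enumeration when both
groups have ≤ 25 profiles and no ties, otherwise the normal approximation
with tie correction (scipy's `mannwhitneyu` provides both regimes).

## Fragment encodings

A fragment is presented to the classifier in two views.

**Six-frame triplet sequence.** The fragment is read as triplets in all
three offsets of the positive strand and all three offsets of the reverse
complement, in that order; the six runs are concatenated into one
"connected" triplet sequence. Gene prediction on short fragments is
unreliable, so all six candidate reading frames are kept rather than
guessing the coding one. Triplets are one-hot encoded over the 64 codons in
lexicographic order (AAA→0, AAC→1, …, TTT→63 — the unique consistent
extension of the two anchor codes).

**Dual-strand base sequence.** The positive strand followed by the
complementary strand, each base one-hot with A=[0,0,0,1], C=[0,0,1,0],
G=[0,1,0,0], T=[1,0,0,0]. The complementary strand is taken as the reverse
complement read 5′→3′ and concatenated after the positive strand — the same
orientation convention the triplet frames 4–6 use, which is what makes
reverse-complement symmetry exact (below). This view preserves intergenic
signal (e.g. transfer-origin motifs) that codon-space encoding ignores.

Ambiguous bases encode as all-zero rows (not fractional codes), keeping the
row-sum invariants checkable: the matrix total equals the number of
unambiguous symbols. Both matrices are zero-padded at the tail to the fixed
shapes implied by the 400 bp maximum window, with true lengths kept for
masked pooling.

## Network architecture and pooling mask

Each branch applies a length-6, 512-kernel 1-D convolution with ReLU, then
a global average pool to a 512-d vector; the two vectors concatenate to
1024-d and pass through batch normalization → dense (width 1024, ReLU) →
batch normalization, then a single logistic unit. All widths are
configuration, not constants.

Because the inputs are one-hot, the convolution is evaluated as an
embedding-table lookup (sum of per-offset rows) rather than a dense matrix
product — mathematically identical, roughly the one-hot sparsity factor
faster on CPU, which is what makes desk-scale training practical in numpy.
An extra vocabulary row pinned at zero implements padding and ambiguous
symbols.

Two masking decisions shape the pooling:

* **Padding is excluded and the pool divides by the true window count**, so
  a 100 bp fragment padded to 400 bp pools identically to the same fragment
  unpadded; unmasked averaging would make scores length-dependent.
* **No convolution window crosses a segment boundary** of the connected
  input (the six frame boundaries; the strand boundary of the base view).
  Reverse-complementing a fragment permutes the six triplet frames
  (1,2,3,4,5,6 → 4,5,6,1,2,3) and swaps the two strand blocks; with
  segment-respecting windows the valid convolution outputs are exactly
  permuted, so the pooled features — and the score — are exactly invariant
  under reverse complement. Boundary-crossing windows would break this
  symmetry for no modelling benefit, since adjacent frames are unrelated
  sequence contexts.

Training minimizes binary cross-entropy with Adam (learning rate 1e−3,
batch 256, at most 50 epochs, early stopping patience 5 on a 10 %
validation split — package defaults, all configurable). One integer seed
drives weight initialization, shuffling and the validation split; training
is reproducible at same-machine level. The best-validation-loss state is
returned.

## Scan-window scoring and the decision rule

Windows of 400 bp tile a longer sequence without overlap, left to right;
a trailing remainder of at least 100 bp (the encoder minimum) is scored as
a short window, shorter remainders are dropped. The sequence score is the
unweighted mean of window scores (partial windows are not length-weighted;
the choice is deliberate and recorded here because either reading is
defensible). The label is transmissible iff score > 0.5 strictly — a score
of exactly 0.5 is non-transmissible — and with an uncertainty threshold
t ∈ [0, 0.5), scores within |score − 0.5| < t are labelled uncertain and
excluded from recall/precision/F1 (AUC is always computed on all scores,
since thresholding cannot change ranks).

## The synthetic benchmark

The generator emulates the amelioration premise directly. A *host usage
table* holds per-category synonymous-codon probabilities plus an intergenic
GC bias; `sample_usage_tables(k, divergence, seed)` interpolates between a
shared Dirichlet baseline (divergence 0 → identical hosts) and
near-deterministic, mutually distinct preferred codons (divergence 1).
A synthetic genome is a sequence of ATG-initiated, stop-terminated genes
(amino acids uniform over the 20 standard residues, codons from the usage
table, one stop codon from the pooled stop category) separated by i.i.d.
intergenic spacers at the GC bias. Non-transmissible surrogates use one
host table; transmissible surrogates a mixture of ≥ 2.

Mixing acts **per codon** by default: each codon is drawn from the convex
blend of the component tables, so every fragment of a transmissible
surrogate carries the mixed-usage signal — the signature of amelioration
acting genome-wide over a plasmid's host history. The alternative
`mixing="gene"` draws each gene whole from one component (modelling
HGT-acquired genes); it yields the same genome-level entropy contrast but
concentrates the signal at gene boundaries, leaving most short fragments
class-uninformative, and is kept as an option rather than the default.

Defaults chosen once as a realistic plasmid-like scale: 20 genes of
100–300 codons (genomes ≈ 13 kb), 10 % intergenic fraction, GC bias drawn
in 0.35–0.65. Fragment extraction is uniform in position, length and
strand, error-free (the targets are assembled contigs, not raw reads);
overlapping fragments from one genome are allowed, as in read simulators.
Benchmarks are class-balanced per group, with genomes assigned to train or
test by an explicit split column (the generalization of a release-date
split) so no genome leaks across the boundary. Full-scale default counts
are 300 000 training fragments per class and 30 000 (groups A–C) / 10 000
(group D) test fragments per class.

**What the generator does not emulate:** real genomic grammar (actual
protein sequences, operon structure, regulatory motifs, oriT/relaxase
elements), sequencing error, within-class host diversity beyond the table
mixture, and the partial, annotation-driven labelling noise of real
datasets. Passing the benchmark therefore demonstrates that the estimator
and classifier recover a codon-usage mixing signal they are designed for —
not the headline accuracy on real plasmid genomes, which depends on real
amelioration strength and is outside what synthetic data can certify.

## Desk-scale experiment sizes

The package's own verification experiments run on one CPU: 20 genomes per
class (two hosts at divergence 1), 2 000 training fragments per class,
a reduced architecture of 128 kernels per branch and hidden width 128
(same topology as the 512-kernel default), at most 6 training epochs. Under
these conditions the held-out group-A AUC exceeds 0.9 by a wide margin, a
label-shuffled control stays at chance, and the genome-level IEA contrast
is significant in ≥ 15 of 19 categories — the qualitative pattern expected
of the method, at sizes chosen as the package's desk-scale defaults.

## Numerical notes

* IEA uses natural-log ratios (ln p / ln nᵢ); values are clamped to [0, 1]
  at 1e−12 tolerance and −0.0 is normalized.
* The AUC implementation is the mid-rank Mann–Whitney formula via
  `scipy.stats.rankdata`; tests verify it against exhaustive pair counting.
* Batch normalization uses ε = 1e−5 and running-statistic momentum 0.1;
  inference uses running statistics, so scores are deterministic and
  batch-size-independent.
* Model artifacts are versioned npz files; loading verifies the format
  version and the architecture shape before accepting parameters.
* Score equality under reverse complement is exact in the algebra but
  subject to float32 summation order in practice; tests allow 1e−5.
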