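# Methods

## Problem and approach

The package separates protein-coding transcripts (mRNA) from long
non-coding RNA (lncRNA, transcripts > 200 nt that do not encode protein).
Both classes share splicing, poly(A) tails and similar lengths, so the
discriminating signal is compositional: coding transcripts carry one long
open reading frame (ORF) with biased codon usage and a Kozak-like context
around the start codon; lncRNAs carry only incidental short ORFs.

The classifier has two parts: a fixed 84-dimensional feature
representation of each transcript, and a neural network that classifies an
input by *measuring its similarity to reference samples of each class*
rather than by mapping the raw feature vector straight to a label.

## Feature representation (84 dimensions)

| block | dim | definition |
|---|---|---|
| `orf_length` | 1 | nucleotide length of the longest ORF, `l_maxORF` |
| `orf_cov_complete`, `orf_cov_incomplete` | 2 | `[l_maxORF/l_RNA, 0]` when the longest ORF has both start and in-frame stop; `[0, l_maxORF/l_RNA]` otherwise |
| `nucleotide_bias` | 1 | `(1/6) Σ_i log( p_mRNA(x_i) / p_lncRNA(x_i) )` over the six positions flanking the start codon, `i ∈ {−3,−2,−1,4,5,6}` |
| `mono_whole` | 4 | 1-mer frequencies of the whole sequence |
| `tri_orf` | 64 | 3-mer frequencies of the longest-ORF substring |
| `kscore_whole` | 6 | k-mer log-ratio scores, k = 1..6, whole sequence |
| `kscore_orf` | 6 | k-mer log-ratio scores, k = 1..6, longest-ORF substring |

`p_class(x_i)` are class-conditional nucleotide frequencies at the context
offsets, estimated from training sequences whose longest ORF leaves all
six offsets inside the sequence. The k-mer score of a region is
`Σ_i f_seq(K_i) · log( M_mRNA(K_i) / M_lncRNA(K_i) )`, where `M_class` is
the mean k-mer composition vector of the class's training data and
`f_seq` is the region's own k-mer frequency vector. A *literal* variant,
`(1/4^k) Σ_i log(M_mRNA(K_i)/M_lncRNA(K_i))` with no sequence term, is
available behind `kmer_score_mode="literal"`; it is constant across
sequences for a fixed model and therefore carries no per-sequence
information — the weighted form is the package default because the score
is used as a per-sequence feature.

Conventions fixed here (each applied identically to both classes, so the
classifier is unaffected by the choice):

* ORFs are scanned on the three forward frames only — transcripts are
  already stranded. Each ATG pairs with its **first** in-frame stop;
  complete ORF lengths include the stop codon. When no ATG has a stop,
  the longest ATG-to-end run is used with the completeness flag off.
  Length ties break toward the smallest start index.
* Context offsets: {−3,−2,−1} are the three bases immediately 5′ of the
  ATG; {4,5,6} the codon immediately 3′ of it (1-based from the A).
  Offsets falling outside the sequence contribute 0 to the bias sum while
  the divisor stays 6.
* Natural logarithms throughout; a pseudocount (default 1e−3) is added to
  positional frequencies and k-mer means before any ratio, so every log
  is finite.
* `tri_orf` and `kscore_orf` are computed on the ORF substring including
  the stop codon.

Because `orf_length` is unbounded while every other entry is O(1), a
per-feature min–max scaler fitted on the pooled training matrix maps
features to [0, 1] before the network; its parameters serialize with the
model. Constant features map to 0.

## Network

Let x be a scaled 84-vector, treated as a length-84 single-channel 1-D
signal. Three input channels — the class references x′_pos, x′_neg and
the sample x — each pass through a stack of `l` 1-D convolution layers
(defaults: l = 2, kernel 2, stride 1, 32 filters, ReLU, no padding, so
each layer shortens the signal by one). The similarity maps are

    f_ps = Conv(x) − Conv(x′_pos)        f_ns = Conv(x) − Conv(x′_neg)

Each map feeds an independent fully connected branch: dropout r1 = 0.2 →
dense(128, ReLU) → dense(1, sigmoid) gives z2; in parallel dropout
r2 = 0.5 → dense(1, sigmoid) gives z3; the branch's similarity node is
y = z2 + z3 ∈ [0, 2]. The output [y_ps, y_ns] is trained by mean squared
error against a two-node target (positive class [1, 0] by default — the
nodes then read as similarities; [0, 1] flips them to differences) with
Adamax at its original defaults (lr 0.002, β1 0.9, β2 0.999), 60 epochs,
batch 256. Targets are {0,1} per node while y can reach 2; MSE tolerates
this and no squashing is applied.

Design points that were genuinely open:

* **Convolution sharing.** Default `per_channel`: three independent conv
  stacks, because tying all three (as a Siamese network would) conflicts
  with having two reference channels and one contrast channel. A
  `per_class` mode — one stack per class applied to both x and that
  class's reference — is provided; it makes the similarity map exactly
  zero when x equals the reference, a property the tests exploit.
* **Filter count.** Not determined by the published main text; default 32
  per layer (the 84-long signal caps useful width), exposed in config.
* **Conv activation.** ReLU after every conv layer, the standard choice.
* **References.** During training each input row i pairs positionally
  with row i of X′_pos and X′_neg, drawn uniformly with replacement from
  the training classes (sample size k = N). Re-drawing the references
  every n epochs is supported (`resample_every`) but off by default, as
  interval re-resampling is not consistently better. At prediction time
  the references are the training-class mean vectors, making prediction a
  pure function of (model, input).
* **Ensemble.** Because different reference draws give different models,
  the final classifier sums the node scores of `n_ensemble = 3`
  independently seeded models; the label goes to the class whose
  (convention-aligned) summed node is larger, ties to the positive class.
* **Determinism.** All randomness (weight init, reference resampling,
  dropout masks, batch shuffling) derives from one config seed through a
  `numpy` SeedSequence split; everything is float64 NumPy, so identical
  seeds reproduce identical models bit-for-bit.

The network, including backpropagation through the similarity subtraction
and the Adamax update, is implemented in NumPy inside the package
(`csnet._nn`); a finite-difference gradient check in the test suite
guards the analytic gradients.

A plain CNN baseline (same features, one conv stack on x, same dense-head
variants z2 / z3 / z2+z3, two sigmoid output nodes) ships for
ablation-style comparisons (`csnet.baseline`, `csnet.experiments`).

## Evaluation

Sp = TN/(TN+FP), Sn = TP/(TP+FN), Acc, Pre = TP/(TP+FP),
F1 = 2·Pre·Sn/(Pre+Sn), with F1 defined as 0 when Pre+Sn = 0. In the
lncRNA/mRNA literature Sp and Sn are conventionally read as the per-class
accuracies of lncRNA and mRNA respectively — i.e. TP counts the **mRNA**
class even though lncRNA is the training-positive class. The report
function follows that convention by default and additionally emits
`acc_lncRNA` / `acc_mRNA` so nothing rests on the naming. Swapping the
metric-positive class exactly swaps Sp and Sn.

McNemar's paired test uses the continuity-corrected statistic
χ² = (|b−c|−1)²/(b+c) on the discordant counts, floored at 0 when
b+c = 0 or |b−c| ≤ 1, with the p-value from the upper χ²₁ tail. ROC AUC
is the rank statistic with ties counted ½ (trapezoidal over thresholds);
PR AUC is step-wise interpolated average precision. The ensemble's
continuous score is score_pos − score_neg (sign-flipped when the
metric-positive class is mRNA).

## Synthetic data

The generator emulates exactly the contrasts the features measure.
Coding-like sequences embed one complete ORF at a target coverage
(default 0.7) whose codons are a mixture of uniform sense-codon usage and
a fixed preferred-codon set (`codon_bias_strength`, default 0.5, the
mixture weight), with the six start-context positions matching a
Kozak-like consensus with probability 0.25 + 0.75·`kozak_strength`
(default 0.5); flanks are uniform. Noncoding-like sequences are uniform
i.i.d. ACGT. Lengths are uniform on 200–1000 nt (200 nt is the defining
lncRNA length floor). Defaults produce 500 + 500 sequences — the
package's standard training condition; evaluation sets in the shipped
experiments use 200 + 200. All three dials run continuously down to a
null regime (coverage 0, bias 0, context bias 0) in which the classes are
distributionally near-identical and a classifier should sit at chance. In
that limit the coverage target rounds below the minimal ATG+stop of 6 nt
and nothing is embedded at all: the coding-like class then coincides in
distribution with the noncoding-like class. Embedding even a forced
minimal hexamer would hand the classifier a detectable marker (a
guaranteed ATG+stop 6-mer that the k = 4..6 scores pick up) and break the
null.

What the generator does **not** emulate: splicing structure, UTR/CDS
length asymmetries, isoforms, GC heterogeneity between real genes, or any
homology structure. Passing the end-to-end tests therefore shows the
pipeline recovers the ORF/codon/context signal it was built to exploit —
not that it attains its published real-data accuracy, which depends on
genuine transcriptomes.

In rare cases a chance ATG in a flank runs to the sequence end without a
stop and outranks the embedded ORF; such coding sequences are resampled
so every coding-like sequence presents a complete longest ORF. The
resampling applies only when an ORF is embedded — in the null limit it
would condition the two otherwise-identical classes differently.

## Problem sizes in shipped tests and the acceptance script

End-to-end checks train the full default configuration (3-model ensemble,
60 epochs, 32 filters) on the generator's default 1000-sequence training
condition with a 400-sequence held-out set. The reference-resampling
robustness protocol trains 10 single models (the unit that varies with
the reference draw) at a reduced width (16 filters, 30 epochs) on a
600-train / 400-eval split — the protocol studies the *spread* across
reference draws, which does not need the full-width model. These sizes
are the package's standard demonstration scale.

## Known limitations

* Incomplete-ORF spans include any trailing partial codon; `length_nt` is
  a multiple of 3 only for complete ORFs.
* The min–max scaler clamps nothing: prediction-time features outside the
  training range map outside [0, 1]. This is deliberate (monotone,
  information-preserving) but means extreme out-of-distribution inputs
  are extrapolations.
* With very small or single-filter configurations the network can
  under-fit even separable data; the defaults are comfortably above that
  regime.
* `f1 = 0` is reported for degenerate all-negative predictions rather
  than NaN, so downstream tables never contain missing values.
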