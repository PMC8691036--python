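# csnet — coding vs long non-coding RNA classification by class similarity

`csnet` classifies transcript sequences into protein-coding mRNA and long
non-coding RNA (lncRNA, transcripts > 200 nt that do not encode protein).
It is aimed at transcriptomics workflows — bulk or single-cell — where
newly assembled transcripts need a coding-potential call before any
functional follow-up.

## Method

Each transcript is reduced to a fixed 84-dimensional feature vector:
the longest-ORF length `l_maxORF` and its coverage pair
(`[l_maxORF/l_RNA, 0]` for complete ORFs, `[0, l_maxORF/l_RNA]` for
incomplete ones), the start-codon context bias
`(1/6) Σ_{i∈{−3,−2,−1,4,5,6}} log( p_mRNA(x_i) / p_lncRNA(x_i) )`,
whole-sequence 1-mer frequencies, longest-ORF 3-mer frequencies, and
k-mer log-ratio scores `Σ_i f_seq(K_i) · log( M_mRNA(K_i)/M_lncRNA(K_i) )`
for k = 1..6 over both the whole sequence and the longest ORF, where the
`p` and `M` statistics are class-conditional estimates from labelled
training data.

Classification uses a *class-similarity network*: the scaled feature
vector x and reference vectors from each class pass through 1-D
convolution stacks, and the network operates on the similarity maps
`f_ps = Conv(x) − Conv(x′_pos)` and `f_ns = Conv(x) − Conv(x′_neg)`
rather than on x itself. Each map feeds an independent dense branch whose
output node `y = z₂ + z₃` (two sigmoid heads) expresses similarity to
that class; `[y_ps, y_ns]` is trained with MSE against two-node class
targets. During training the references are resampled with replacement
from the training classes; at prediction time they are the class mean
vectors, so predictions are deterministic. The shipped classifier sums
the scores of three independently trained models and assigns the class
with the larger summed node. See `docs/methods.md` for conventions,
defaults and design rationale.

The whole network — convolutions, backprop, Adamax — is implemented in
NumPy inside the package and verified against finite-difference gradients
in the test suite. A synthetic transcript generator with tunable
separability (ORF coverage, codon bias, start-context bias) supports
training-free-of-downloads experiments, and a plain-CNN baseline plus
experiment protocols (reference-set robustness, interval re-resampling,
baseline comparison) round out the toolkit.

## Worked example

`examples/03_train_and_predict.py` trains a reduced configuration on 500
synthetic transcripts and classifies 200 held-out ones:

```text
held-out accuracy: 0.995 on 200 sequences
  coding_0       score_pos=0.332 score_neg=0.739 -> mRNA
  coding_1       score_pos=0.314 score_neg=0.826 -> mRNA
  coding_2       score_pos=0.357 score_neg=0.675 -> mRNA
```

`score_pos` / `score_neg` are the ensemble-summed similarity nodes for
the lncRNA (training-positive) and mRNA classes; each per-model node lies
in [0, 2] and the larger summed node decides the label — here the
coding-like records are correctly called mRNA. The other examples cover
the generator (`01`), the feature representation (`02`), metrics with
McNemar's test (`04`), and reference-set robustness (`05`); each prints a
short explanation with its numbers.

Shell workflow (equivalent thin CLI):

```bash
csnet synth --seed 2 --out data/
csnet train --pos data/pos.fa --neg data/neg.fa --seed 3 --out model/
csnet predict --model model/ --fasta data/pos.fa --out pred.tsv
csnet evaluate --pred pred.tsv --truth data/labels.tsv --out report.json
csnet experiment --mode repeats --out repeats.tsv
```

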