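"""The 84-dimensional transcript feature representation.

Each transcript is converted to a fixed-length vector of 84 numbers:

====================  ===  =========================================================
block                 dim  content
====================  ===  =========================================================
orf_length              1  nucleotide length of the longest ORF (l_maxORF)
orf_coverage            2  [l_maxORF/l_RNA, 0] when the ORF is complete,
                           [0, l_maxORF/l_RNA] when incomplete (both 0 if no ORF)
nucleotide_bias         1  mean log-ratio of class-conditional nucleotide
                           frequencies at the six positions flanking the start
                           codon (Kozak-context signal)
mono_whole              4  1-mer frequencies of the whole sequence
tri_orf                64  3-mer frequencies of the longest-ORF sequence
kscore_whole            6  k-mer log-ratio scores, k = 1..6, whole sequence
kscore_orf              6  k-mer log-ratio scores, k = 1..6, longest-ORF sequence
====================  ===  =========================================================

The bias and score blocks depend on class-conditional statistics estimated
from labelled training data (a :class:`FeatureModel`): positional nucleotide
frequencies around the start codon per class, and mean k-mer composition
vectors per class for both the whole sequence and the longest ORF. All
log-ratios are natural logs of mRNA-over-lncRNA quantities, so positive
values point toward the coding class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .orf import LongestORF, find_longest_orf
from .sequence_io import SequenceRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_ENCODE = np.full(128, -1, dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i

#: Offsets (relative to the A of ATG, 0-based) of the six context positions:
#: the codon immediately 5' of the start codon and the codon immediately 3'
#: of it. In 1-based start-codon coordinates these are {-3,-2,-1} and {4,5,6}.
CONTEXT_OFFSETS = (-3, -2, -1, 3, 4, 5)

KS = (1, 2, 3, 4, 5, 6)
CLASSES = ("mRNA", "lncRNA")
REGIONS = ("whole", "orf")

N_FEATURES = 84


def _kmer_names(k: int) -> list[str]:
    names = [""]
    for _ in range(k):
        names = [n + b for n in names for b in BASES]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(
    ["orf_length", "orf_cov_complete", "orf_cov_incomplete", "nucleotide_bias"]
    + [f"mono_whole_{b}" for b in BASES]
    + [f"tri_orf_{t}" for t in _kmer_names(3)]
    + [f"kscore_whole_k{k}" for k in KS]
    + [f"kscore_orf_k{k}" for k in KS]
)
assert len(FEATURE_NAMES) == N_FEATURES


def encode(seq: str) -> np.ndarray:
    """Map an A/C/G/T string to an int array (A=0, C=1, G=2, T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.min() < 0:
        raise ValueError("sequence contains a letter other than A/C/G/T")
    return arr


def _kmer_counts(encoded: np.ndarray, k: int) -> np.ndarray:
    """Counts of overlapping k-mers in lexicographic (A<C<G<T) order."""
    n = encoded.size
    if n < k:
        return np.zeros(4**k, dtype=np.int64)
    idx = encoded[: n - k + 1].copy()
    for j in range(1, k):
        idx = idx * 4 + encoded[j : n - k + 1 + j]
    return np.bincount(idx, minlength=4**k)


def kmer_frequencies(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer frequency vector of length 4**k.

    Counts stride-1 windows and divides by ``max(len(seq) - k + 1, 1)``;
    sequences shorter than k give an all-zero vector.
    """
    if not 1 <= k <= 6:
        raise ValueError(f"k must be in 1..6, got {k}")
    counts = _kmer_counts(encode(seq), k)
    return counts / max(len(seq) - k + 1, 1)


@dataclass
class FeatureScaler:
    """Per-feature min-max scaler to [0, 1], fitted on training features.

    Constant features map to 0. Needed because orf_length is unbounded
    while every other feature is O(1).
    """

    mins: np.ndarray
    scales: np.ndarray  # 1 / (max - min), 0 for constant columns

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        mins = X.min(axis=0)
        rng = X.max(axis=0) - mins
        scales = np.where(rng > 0, 1.0 / np.where(rng > 0, rng, 1.0), 0.0)
        return cls(mins=mins, scales=scales)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mins) * self.scales

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "scales": self.scales.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(mins=np.asarray(d["mins"]), scales=np.asarray(d["scales"]))


@dataclass
class FeatureModel:
    """Class-conditional training statistics behind the 84 features.

    Attributes
    ----------
    pos_freq:
        ``pos_freq[cls]`` is a (6, 4) array of nucleotide frequencies at the
        six start-codon context offsets, pseudocount-smoothed so each row
        sums to 1. Fitted only on training sequences whose longest ORF has
        all six context positions inside the sequence.
    kmer_mean:
        ``kmer_mean[cls][region][k]`` is the arithmetic mean over the
        class's training sequences of per-sequence k-mer frequency vectors
        (length 4**k), pseudocount-smoothed and renormalised so every entry
        is positive and each vector sums to 1.
    pseudocount:
        Smoothing constant added before ratios are formed, so the
        log-ratios in the bias and score features are always finite.
    kmer_score_mode:
        "weighted" (default): score = sum_i f_seq(K_i) * log-ratio(K_i),
        a per-sequence relative bias. "literal": the sequence-independent
        mean log-ratio (1/4^k) * sum_i log-ratio(K_i).
    scaler:
        Min-max scaler fitted on the training feature matrix (set by the
        training pipeline, not by :func:`fit_feature_model`).
    """

    pos_freq: dict
    kmer_mean: dict
    pseudocount: float = 1e-3
    kmer_score_mode: str = "weighted"
    scaler: FeatureScaler | None = None
    # cached log(M_mRNA / M_lncRNA) per region per k
    _log_ratio: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.kmer_score_mode not in ("weighted", "literal"):
            raise ValueError(f"unknown kmer_score_mode {self.kmer_score_mode!r}")
        self._build_cache()

    def _build_cache(self) -> None:
        self._log_ratio = {
            region: {
                k: np.log(self.kmer_mean["mRNA"][region][k])
                - np.log(self.kmer_mean["lncRNA"][region][k])
                for k in KS
            }
            for region in REGIONS
        }
        self._log_pos_ratio = np.log(self.pos_freq["mRNA"]) - np.log(
            self.pos_freq["lncRNA"]
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kmer_ordering": "lexicographic A<C<G<T, overlapping windows",
            "pseudocount": self.pseudocount,
            "kmer_score_mode": self.kmer_score_mode,
            "context_offsets": list(CONTEXT_OFFSETS),
            "pos_freq": {c: self.pos_freq[c].tolist() for c in CLASSES},
            "kmer_mean": {
                c: {r: {str(k): self.kmer_mean[c][r][k].tolist() for k in KS} for r in REGIONS}
                for c in CLASSES
            },
            "scaler": self.scaler.to_dict() if self.scaler else None,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureModel":
        d = json.loads(Path(path).read_text())
        return cls(
            pos_freq={c: np.asarray(d["pos_freq"][c]) for c in CLASSES},
            kmer_mean={
                c: {r: {k: np.asarray(d["kmer_mean"][c][r][str(k)]) for k in KS} for r in REGIONS}
                for c in CLASSES
            },
            pseudocount=d["pseudocount"],
            kmer_score_mode=d["kmer_score_mode"],
            scaler=FeatureScaler.from_dict(d["scaler"]) if d["scaler"] else None,
        )


def _smooth(v: np.ndarray, pseudocount: float) -> np.ndarray:
    v = v + pseudocount
    return v / v.sum()


def fit_feature_model(
    train_mRNA: Sequence[SequenceRecord],
    train_lncRNA: Sequence[SequenceRecord],
    pseudocount: float = 1e-3,
    kmer_score_mode: str = "weighted",
) -> FeatureModel:
    """Estimate the class-conditional statistics from labelled training data.

    Positional frequencies use only sequences whose longest ORF leaves all
    six context offsets inside the sequence; k-mer means average each
    sequence's frequency vector (whole sequence and longest-ORF substring
    separately). Raises if a class contributes no usable start-codon
    context.
    """
    if not train_mRNA or not train_lncRNA:
        raise ValueError("both training classes must be non-empty")
    pos_freq: dict[str, np.ndarray] = {}
    kmer_mean: dict[str, dict] = {}
    for cls_name, records in (("mRNA", train_mRNA), ("lncRNA", train_lncRNA)):
        counts = np.zeros((6, 4), dtype=float)
        n_ctx = 0
        sums = {r: {k: np.zeros(4**k) for k in KS} for r in REGIONS}
        for rec in records:
            enc = encode(rec.seq)
            orf = find_longest_orf(rec.seq)
            if orf.length_nt > 0:
                s = orf.start
                if s - 3 >= 0 and s + 5 < len(rec.seq):
                    for row, off in enumerate(CONTEXT_OFFSETS):
                        counts[row, enc[s + off]] += 1
                    n_ctx += 1
            enc_orf = encode(orf.orf_seq)
            for k in KS:
                sums["whole"][k] += _kmer_counts(enc, k) / max(len(rec.seq) - k + 1, 1)
                sums["orf"][k] += _kmer_counts(enc_orf, k) / max(orf.length_nt - k + 1, 1)
        if n_ctx == 0:
            raise ValueError(
                f"no {cls_name} training sequence has a start codon with full "
                "six-position context; provide more or longer training sequences"
            )
        pos_freq[cls_name] = np.stack(
            [_smooth(counts[row], pseudocount) for row in range(6)]
        )
        n = len(records)
        kmer_mean[cls_name] = {
            r: {k: _smooth(sums[r][k] / n, pseudocount) for k in KS} for r in REGIONS
        }
    return FeatureModel(
        pos_freq=pos_freq,
        kmer_mean=kmer_mean,
        pseudocount=pseudocount,
        kmer_score_mode=kmer_score_mode,
    )


def nucleotide_bias(seq: str, orf: LongestORF, model: FeatureModel) -> float:
    """Mean log-ratio of class nucleotide frequencies at the six context
    positions flanking this sequence's start codon.

    Offsets falling outside the sequence contribute 0 while the divisor
    stays 6; a sequence without an ORF scores 0.
    """
    if orf.length_nt == 0:
        return 0.0
    enc = encode(seq)
    s = orf.start
    total = 0.0
    for row, off in enumerate(CONTEXT_OFFSETS):
        pos = s + off
        if 0 <= pos < len(seq):
            total += model._log_pos_ratio[row, enc[pos]]
    return total / 6.0


def kmer_score(seq_region: str, model: FeatureModel, k: int, region: str) -> float:
    """Class log-ratio k-mer score of a sequence region.

    In the default "weighted" mode this is the sequence's k-mer frequency
    vector dotted with log(M_mRNA/M_lncRNA) — positive means the region's
    composition is closer to the coding class mean. The "literal" mode is
    the unweighted mean log-ratio, constant across sequences for a fixed
    model. Empty regions score 0 in both modes.
    """
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    if not seq_region:
        return 0.0
    lr = model._log_ratio[region][k]
    if model.kmer_score_mode == "literal":
        return float(lr.mean())
    f = kmer_frequencies(seq_region, k)
    return float(f @ lr)


def featurize(record: SequenceRecord, model: FeatureModel) -> np.ndarray:
    """Convert one transcript to its raw (unscaled) 84-feature vector."""
    seq = record.seq
    orf = find_longest_orf(seq)
    vec = np.zeros(N_FEATURES)
    vec[0] = orf.length_nt
    if orf.length_nt > 0:
        cov = orf.length_nt / len(seq)
        if orf.complete:
            vec[1] = cov
        else:
            vec[2] = cov
    vec[3] = nucleotide_bias(seq, orf, model)
    vec[4:8] = kmer_frequencies(seq, 1)
    vec[8:72] = kmer_frequencies(orf.orf_seq, 3) if len(orf.orf_seq) >= 3 else 0.0
    for j, k in enumerate(KS):
        vec[72 + j] = kmer_score(seq, model, k, "whole")
        vec[78 + j] = kmer_score(orf.orf_seq, model, k, "orf")
    return vec


def featurize_many(records: Sequence[SequenceRecord], model: FeatureModel) -> np.ndarray:
    """Feature matrix (n_records, 84) in input order."""
    if not records:
        return np.zeros((0, N_FEATURES))
    return np.stack([featurize(r, model) for r in records])
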