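"""Synthetic transcript generator with tunable class separability.

Two classes are emulated:

* **coding-like** ("mRNA"): each sequence carries exactly one embedded
  complete ORF (ATG ... in-frame stop) covering a target fraction of the
  sequence, with codons drawn from a distribution whose non-uniformity is
  set by ``codon_bias_strength`` and with the six start-codon context
  positions biased toward a Kozak-like consensus by ``kozak_strength``;
  the flanks are uniform random sequence;
* **noncoding-like** ("lncRNA"): uniform-composition random sequence with
  no constraints — incidental short ORFs occur by chance, as in real
  lncRNA.

All three separability dials run continuously from a null regime (classes
distributionally near-identical; a classifier should sit at chance) to a
strong-signal regime (near-perfect separation). Generation is fully
deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orf import find_longest_orf
from .sequence_io import SequenceRecord

BASES = np.array(list("ACGT"))

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS = [c for c in _CODONS if c not in STOPS]

# A fixed "preferred" codon set loosely imitating the GC3 bias of highly
# expressed human genes; any fixed non-uniform choice separates the classes.
_PREFERRED = ("GCC", "GAG", "CTG", "AAG", "GAC", "GTG", "CAG", "ATC",
              "AAC", "GGC", "TTC", "ACC")

# Kozak-like target context: the codon before ATG and the codon after.
# Consensus gccATGg -> upstream (A at -3 is the strong position), downstream G.
_KOZAK_UP = "ACC"    # positions -3, -2, -1
_KOZAK_DOWN = "GCC"  # positions +4, +5, +6 (the codon after ATG)


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults are the package's study conditions.

    500 + 500 training-scale sequences of 200-1000 nt with the embedded
    ORF covering ~70% of a coding sequence, moderate codon bias and
    moderate start-context bias — a strong-signal but not degenerate
    regime. The 200 nt floor matches the defining length of lncRNA.
    """

    n_coding: int = 500
    n_noncoding: int = 500
    length_range: tuple[int, int] = (200, 1000)
    coding_orf_coverage: float = 0.7
    codon_bias_strength: float = 0.5
    kozak_strength: float = 0.5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if not (200 <= lo <= hi):
            raise ValueError("length_range must satisfy 200 <= min <= max")
        if self.n_coding < 0 or self.n_noncoding < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.coding_orf_coverage <= 1.0):
            raise ValueError("coding_orf_coverage must be in [0, 1]")
        for name in ("codon_bias_strength", "kozak_strength"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


def _codon_probs(bias: float) -> np.ndarray:
    """Mixture of uniform sense-codon usage and the preferred set."""
    p = np.full(len(SENSE_CODONS), (1.0 - bias) / len(SENSE_CODONS))
    for cod in _PREFERRED:
        p[SENSE_CODONS.index(cod)] += bias / len(_PREFERRED)
    return p / p.sum()


def _biased_context(target: str, strength: float, rng: np.random.Generator) -> str:
    """Each position matches the target base with prob 0.25 + 0.75*strength."""
    out = []
    for t in target:
        if rng.random() < 0.25 + 0.75 * strength:
            out.append(t)
        else:
            out.append(str(rng.choice(BASES)))
    return "".join(out)


def _uniform_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=n)) if n > 0 else ""


def _target_orf_len(length: int, coverage: float) -> int:
    """Embedded-ORF length for a sequence: nearest multiple of 3 to
    coverage*length, capped at the sequence; 0 (no embedding) when the
    target rounds below the minimal ATG+stop of 6 nt."""
    orf_len = int(round(coverage * length / 3)) * 3
    orf_len = min(orf_len, length - length % 3)
    return orf_len if orf_len >= 6 else 0


def _coding_sequence(length: int, spec: SyntheticSpec, rng: np.random.Generator) -> str:
    # ORF length: nearest multiple of 3 to coverage*length, capped at the
    # whole sequence. A target below the minimal ATG+stop (6 nt) embeds
    # nothing at all: in the coverage -> 0 null limit the coding class must
    # coincide in distribution with the noncoding class, and any forced
    # hexamer would be a detectable class marker.
    orf_len = _target_orf_len(length, spec.coding_orf_coverage)
    if orf_len == 0:
        return _uniform_seq(length, rng)
    if orf_len > length:
        raise ValueError(
            f"embedded ORF of {orf_len} nt does not fit a {length} nt sequence"
        )
    n_internal = orf_len // 3 - 2  # codons between ATG and stop
    probs = _codon_probs(spec.codon_bias_strength)
    codons = rng.choice(len(SENSE_CODONS), size=n_internal, p=probs)
    orf = "ATG" + "".join(SENSE_CODONS[i] for i in codons) + str(rng.choice(STOPS))
    flank = length - orf_len
    start = int(rng.integers(0, flank + 1))
    up = _uniform_seq(start, rng)
    down = _uniform_seq(flank - start, rng)
    if spec.kozak_strength > 0:
        if len(up) >= 3:
            up = up[:-3] + _biased_context(_KOZAK_UP, spec.kozak_strength, rng)
        ctx = _biased_context(_KOZAK_DOWN, spec.kozak_strength, rng)
        # the codon after ATG lies inside the ORF; keep it non-stop
        if ctx in STOPS:
            ctx = "GCC"
        if n_internal >= 1:
            orf = "ATG" + ctx + orf[6:]
    return up + orf + down


def generate_dataset(spec: SyntheticSpec) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Generate labelled records and an id -> label truth table.

    Coding-like records are labelled "mRNA", noncoding-like "lncRNA".
    Output is fully deterministic under ``spec.seed``. When
    ``coding_orf_coverage`` is so low that the target ORF rounds below
    6 nt, nothing is embedded and the two classes coincide in
    distribution (the null regime).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    for i in range(spec.n_coding):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        if _target_orf_len(length, spec.coding_orf_coverage) == 0:
            # null regime: no embedding, hence no completeness constraint —
            # the coding class must match the noncoding distribution exactly
            seq = _coding_sequence(length, spec, rng)
        else:
            # Rarely a flank ATG with no downstream in-frame stop outranks
            # the embedded ORF, making the longest ORF incomplete; resample
            # those so every coding-like sequence presents a complete
            # longest ORF.
            for _ in range(100):
                seq = _coding_sequence(length, spec, rng)
                if find_longest_orf(seq).complete:
                    break
        records.append(SequenceRecord(id=f"coding_{i}", seq=seq, label="mRNA"))
    for i in range(spec.n_noncoding):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        records.append(SequenceRecord(
            id=f"noncoding_{i}", seq=_uniform_seq(length, rng), label="lncRNA"
        ))
    truth = {r.id: r.label for r in records}
    return records, truth
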