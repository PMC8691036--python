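"""Reading, validating and writing transcript sequences and result tables.

Transcripts are plain nucleotide strings over {A, C, G, T}. FASTA input is
tolerated in RNA alphabet (U is mapped to T) and in soft-masked lowercase;
anything else (N, IUPAC ambiguity codes, ...) is removed by
:func:`filter_atgc`, mirroring the common practice of dropping transcripts
with ambiguous bases before coding-potential analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

VALID_BASES = frozenset("ACGT")

#: Recognised class labels. "unknown" marks records awaiting prediction.
LABELS = ("lncRNA", "mRNA", "unknown")


@dataclass
class SequenceRecord:
    """One transcript: identifier, sequence, optional class label."""

    id: str
    seq: str
    label: str = "unknown"

    def __len__(self) -> int:
        return len(self.seq)


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input."""


def _normalize(seq: str) -> str:
    # uppercase, then RNA -> DNA alphabet
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path, label: str = "unknown") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Sequences are uppercased and U is mapped to T before any validation.
    Record ids (first whitespace-delimited token of the header) must be
    unique within the file.

    Parameters
    ----------
    path:
        FASTA file; multi-line sequences are allowed.
    label:
        Class label attached to every record (use when one file holds one
        class, e.g. a training set of lncRNAs).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        first = handle.read(1)
        if first == "":
            warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
            return []
        if first != ">":
            raise FastaParseError(
                f"{path}: line 1 does not start a FASTA header (expected '>')"
            )
        handle.seek(0)
        for header, seq in SimpleFastaParser(handle):
            rid = header.split()[0] if header.split() else ""
            if not rid:
                raise FastaParseError(f"{path}: FASTA entry with empty header")
            if rid in seen:
                raise FastaParseError(f"{path}: duplicate sequence id {rid!r}")
            seen.add(rid)
            records.append(SequenceRecord(id=rid, seq=_normalize(seq), label=label))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


def filter_atgc(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], list[str]]:
    """Split records into (kept, dropped-ids) by the strict A/C/G/T rule.

    A record is kept iff its sequence is non-empty and contains only
    A, C, G or T. Input order is preserved on both sides.
    """
    kept: list[SequenceRecord] = []
    dropped: list[str] = []
    for rec in records:
        if rec.seq and set(rec.seq) <= VALID_BASES:
            kept.append(rec)
        else:
            dropped.append(rec.id)
    return kept, dropped


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``id<TAB>label`` (with header) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "label"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'id' and 'label'")
    return dict(zip(df["id"], df["label"]))


def attach_labels(records: Sequence[SequenceRecord], labels: dict[str, str]) -> None:
    """Set ``record.label`` in place from an id->label mapping."""
    for rec in records:
        if rec.id in labels:
            rec.label = labels[rec.id]


def write_labels(records: Iterable[SequenceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.id, r.label) for r in records], columns=["id", "label"]
    ).to_csv(path, sep="\t", index=False)


def write_feature_table(ids: Sequence[str], matrix, feature_names: Sequence[str], path: str | Path) -> None:
    """Write an (n, 84) feature matrix as TSV with an ``id`` column."""
    df = pd.DataFrame(matrix, columns=list(feature_names))
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_predictions(results, path: str | Path) -> None:
    """Write prediction results as TSV: id, score_pos, score_neg, predicted_label."""
    pd.DataFrame(
        [(r.id, r.score_pos, r.score_neg, r.predicted_label) for r in results],
        columns=["id", "score_pos", "score_neg", "predicted_label"],
    ).to_csv(path, sep="\t", index=False)
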