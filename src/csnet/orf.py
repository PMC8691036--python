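"""Longest open reading frame detection on stranded transcript sequences.

Transcripts are already-stranded mRNA/lncRNA sequences, so only the three
forward reading frames are scanned; no reverse complement is considered.

Conventions (applied identically to both classes, so the classifier is
unaffected by the choice):

* a *complete* ORF runs ATG ... in-frame stop (TAA/TAG/TGA) and its length
  counts the start codon through the stop codon inclusive;
* if no complete ORF exists, the longest *incomplete* ORF (an ATG running
  in-frame to the sequence end with no stop) is reported with
  ``complete=False``;
* with no ATG at all the result has ``length_nt=0``;
* ties on length are broken toward the smallest start index.
"""

from __future__ import annotations

from dataclasses import dataclass

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class LongestORF:
    """Longest ORF of one transcript.

    Attributes
    ----------
    start:
        0-based index of the A of the start codon (0 when no ORF found).
    length_nt:
        ORF length in nucleotides, stop codon included when complete.
    complete:
        True when the ORF has both an ATG and an in-frame stop.
    orf_seq:
        The ORF substring (empty when ``length_nt`` is 0).
    """

    start: int
    length_nt: int
    complete: bool
    orf_seq: str


_EMPTY = LongestORF(start=0, length_nt=0, complete=False, orf_seq="")


def find_longest_orf(seq: str) -> LongestORF:
    """Locate the longest ORF across the three forward reading frames.

    Complete ORFs always outrank incomplete ones of any length only through
    the maximisation itself: every candidate span competes purely on
    nucleotide length; completeness is recorded, not privileged. Within a
    frame, each ATG is paired with the first in-frame stop at or after it
    (nested ATGs inside a longer same-frame ORF yield shorter spans and are
    dominated automatically).
    """
    n = len(seq)
    best = _EMPTY
    best_key = (0, 0)  # (length, -start); no-ATG default loses to everything
    for frame in range(3):
        # positions of stops in this frame, in order, for first-stop lookup
        stops = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] in STOP_CODONS]
        stop_iter = 0
        for i in range(frame, n - 2, 3):
            if seq[i : i + 3] != "ATG":
                continue
            while stop_iter < len(stops) and stops[stop_iter] < i:
                stop_iter += 1
            # find first stop at or after this ATG (stops list is sorted;
            # stop_iter only moves forward because ATGs are visited in order)
            j = stop_iter
            if j < len(stops):
                stop = stops[j]
                length = stop + 3 - i
                complete = True
            else:
                length = n - i
                # truncate to full codons? No: an incomplete ORF runs to the
                # sequence end, trailing partial codon included in the span.
                complete = False
            key = (length, -i)
            if key > best_key:
                best_key = key
                best = LongestORF(
                    start=i,
                    length_nt=length,
                    complete=complete,
                    orf_seq=seq[i : i + length],
                )
    return best
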