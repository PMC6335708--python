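"""Stop-to-stop open reading frame search over all six frames.

The coding-capacity statistic used by the lncRNA filter is the length (in
amino acids) of the longest *stop-to-stop* codon run: a maximal run of codons
containing no stop codon, bounded by stop codons or by the sequence ends, in
any of the six reading frames (three per strand).  No start codon is required
— this is deliberately conservative toward calling coding potential, and
boundary-truncated runs count.

Stop codons are TAA, TAG and TGA.  Codons containing N are treated as
non-stop (ambiguity must not fragment a genuine ORF into spuriously short
runs).  Ties between frames are broken deterministically: forward strand
before reverse, lower frame first, leftmost run first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_ALLOWED = frozenset(b"ACGTN")
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

#: frame labels in tie-break priority order
FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


@dataclass(frozen=True)
class OrfResult:
    """Longest stop-to-stop run found in a transcript sequence.

    ``start``/``end`` are 0-based half-open positions on the *input* (forward)
    sequence; for reverse-strand frames the interval is the forward-strand
    projection of the run.  ``end - start == 3 * longest_orf_aa``.
    """

    longest_orf_aa: int
    frame: str
    start: int
    end: int
    transcript_id: str | None = None


def _stop_mask(codons: np.ndarray) -> np.ndarray:
    """Boolean mask of stop codons in an (n, 3) uint8 codon array."""
    b0, b1, b2 = codons[:, 0], codons[:, 1], codons[:, 2]
    T, A, G = ord("T"), ord("A"), ord("G")
    taa = (b0 == T) & (b1 == A) & (b2 == A)
    tag = (b0 == T) & (b1 == A) & (b2 == G)
    tga = (b0 == T) & (b1 == G) & (b2 == A)
    return taa | tag | tga


def longest_orf(sequence: str, transcript_id: str | None = None) -> OrfResult:
    """Length in aa of the longest stop-to-stop codon run over all six frames.

    Returns 0 aa (with an empty interval) for sequences shorter than one
    codon.  Raises ``ValueError`` on characters outside {A, C, G, T, N}
    (case-insensitive).
    """
    seq = sequence.upper().encode("ascii", errors="replace")
    bad = set(seq) - _ALLOWED
    if bad:
        raise ValueError(
            f"illegal characters in sequence: {sorted(chr(b) for b in bad)}"
        )
    L = len(seq)
    best = OrfResult(0, "+1", 0, 0, transcript_id)
    if L < 3:
        return best

    fwd = np.frombuffer(seq, dtype=np.uint8)
    rev = np.frombuffer(seq.translate(_COMPLEMENT)[::-1], dtype=np.uint8)

    for strand_idx, arr in ((0, fwd), (1, rev)):
        for off in range(3):
            n_codons = (L - off) // 3
            if n_codons == 0:
                continue
            codons = arr[off : off + 3 * n_codons].reshape(n_codons, 3)
            stops = np.flatnonzero(_stop_mask(codons))
            bounds = np.concatenate(([-1], stops, [n_codons]))
            run_lengths = np.diff(bounds) - 1
            i = int(np.argmax(run_lengths))  # leftmost maximal run
            aa = int(run_lengths[i])
            if aa <= best.longest_orf_aa:
                continue
            first_codon = int(bounds[i]) + 1
            local_start = off + 3 * first_codon
            local_end = local_start + 3 * aa
            if strand_idx == 0:
                start, end = local_start, local_end
            else:  # project the reverse-strand run onto forward coordinates
                start, end = L - local_end, L - local_start
            frame = FRAMES[strand_idx * 3 + off]
            best = OrfResult(aa, frame, start, end, transcript_id)
    return best
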