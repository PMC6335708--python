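"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the code paths they check: the ORF oracle works on
codon strings with plain splitting, the BH oracle implements the step-up loop
directly, the hypergeometric oracle sums exact binomial-coefficient ratios,
and the correlation-null oracle draws fresh bivariate-normal samples.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def brute_longest_orf(sequence: str) -> int:
    """Longest stop-to-stop codon run (aa) over all six frames, by splitting.

    Codons containing N never count as stops.
    """
    seq = sequence.upper()
    best = 0
    for s in (seq, seq.translate(_COMP)[::-1]):
        for off in range(3):
            codons = [s[i : i + 3] for i in range(off, len(s) - 2, 3)]
            run = 0
            for codon in codons:
                if codon in STOPS:
                    best = max(best, run)
                    run = 0
                else:
                    run += 1
            best = max(best, run)
    return best


def brute_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up, written as the textbook double loop."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(prev, p[i] * m / rank_from_top)
        adjusted[i] = min(1.0, value)
        prev = value
    return np.array(adjusted)


def hypergeom_upper_tail(k: int, M: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, N), by exact summation."""
    if k <= 0:
        return 1.0
    total = Fraction(0)
    denom = math.comb(M, N)
    for x in range(k, min(K, N) + 1):
        total += Fraction(math.comb(K, x) * math.comb(M - K, N - x), denom)
    return float(total)


def null_abs_r_tail(r0: float, n: int, draws: int, seed: int) -> float:
    """Monte-Carlo estimate of P(|r| >= r0) under the bivariate-normal null.

    Each draw uses a fresh pair of iid N(0,1) vectors of length n, so the
    estimate targets exactly the distribution the t transform describes.
    """
    rng = np.random.default_rng(seed)
    count = 0
    total = 0
    chunk = 200_000
    while total < draws:
        m = min(chunk, draws - total)
        x = rng.normal(size=(m, n))
        y = rng.normal(size=(m, n))
        x -= x.mean(axis=1, keepdims=True)
        y -= y.mean(axis=1, keepdims=True)
        r = (x * y).sum(axis=1) / np.sqrt((x * x).sum(axis=1) * (y * y).sum(axis=1))
        count += int((np.abs(r) >= r0).sum())
        total += m
    return count / total


def brute_overlap_cells(sets: dict[str, set]) -> dict[tuple[bool, ...], int]:
    """Membership-pattern tabulation for the status-overlap check."""
    labels = list(sets)
    cells: dict[tuple[bool, ...], int] = {}
    for key in set().union(*sets.values()):
        pattern = tuple(key in sets[lab] for lab in labels)
        cells[pattern] = cells.get(pattern, 0) + 1
    return cells


def definitional_pearson(x, y) -> float:
    """Pearson correlation straight from the definition (no numpy reductions
    beyond elementwise sums)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
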