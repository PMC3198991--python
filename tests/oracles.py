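"""Independent oracles used by the test suite.

These deliberately share no code with the package: a top-down memoized
affine-gap DP for optimal global alignment scores, and a full recursive
enumeration of alignments for very short strings (used to validate the DP
oracle itself).
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def affine_score_oracle(
    a: str, b: str, gap_open: float = -10.0, gap_extend: float = -1.0
) -> float:
    """Optimal global affine-gap score by top-down memoized recursion.

    Gap of length L costs gap_open + (L-1)*gap_extend.  States: 'M' last
    column was residue-residue, 'A' last column was a gap in `a`, 'B' last
    column was a gap in `b`.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            # the empty prefix is the start; only the neutral state is real,
            # so a first gap column is charged gap_open, never gap_extend
            return 0.0 if state == "M" else NEG_INF
        options = []
        if i > 0 and j > 0 and state == "M":
            sub = float(_B62[a[i - 1], b[j - 1]])
            options.extend(sub + best(i - 1, j - 1, s) for s in "MAB")
        if j > 0 and state == "A":  # gap in a, consume b[j-1]
            options.append(best(i, j - 1, "A") + gap_extend)
            options.append(best(i, j - 1, "M") + gap_open)
            options.append(best(i, j - 1, "B") + gap_open)
        if i > 0 and state == "B":  # gap in b, consume a[i-1]
            options.append(best(i - 1, j, "B") + gap_extend)
            options.append(best(i - 1, j, "M") + gap_open)
            options.append(best(i - 1, j, "A") + gap_open)
        return max(options, default=NEG_INF)

    return max(best(len(a), len(b), s) for s in "MAB")


def _score_alignment(
    row_a: str, row_b: str, gap_open: float, gap_extend: float
) -> float:
    """Score an explicit gapped alignment under the affine rule."""
    score = 0.0
    prev = "M"
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            score += gap_extend if prev == "A" else gap_open
            prev = "A"
        elif cb == "-":
            score += gap_extend if prev == "B" else gap_open
            prev = "B"
        else:
            score += float(_B62[ca, cb])
            prev = "M"
    return score


def enumerate_alignments(a: str, b: str) -> list[tuple[str, str]]:
    """All global alignments of a and b (no gap-gap columns)."""
    out: list[tuple[str, str]] = []

    def rec(i: int, j: int, ra: str, rb: str) -> None:
        if i == len(a) and j == len(b):
            out.append((ra, rb))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ra + a[i], rb + b[j])
        if i < len(a):
            rec(i + 1, j, ra + a[i], rb + "-")
        if j < len(b):
            rec(i, j + 1, ra + "-", rb + b[j])

    rec(0, 0, "", "")
    return out


def exhaustive_score_oracle(
    a: str, b: str, gap_open: float = -10.0, gap_extend: float = -1.0
) -> float:
    """Optimal score by scoring every possible alignment (tiny inputs only)."""
    return max(
        _score_alignment(ra, rb, gap_open, gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )
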