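"""Independent brute-force oracles used by the test suite.

Deliberately naive and self-contained: these re-derive expected values by
exhaustive enumeration and must not import scanning/alignment code from the
package under test (IUPAC tables and reverse complement are re-declared here
on purpose).
"""

from __future__ import annotations

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def window_mismatches(window: str, code: str, cap: int | None = None) -> int:
    count = 0
    for base, c in zip(window, code):
        allowed = IUPAC[c]
        if base == "N":
            if len(allowed) < 4:
                count += 1
        elif base not in allowed:
            count += 1
        if cap is not None and count > cap:
            return count
    return count


def brute_force_scan(
    seq: str, code: str, budget: int, strands: str = "both"
) -> set[tuple[int, str, int]]:
    """All (position, strand, mismatches) within budget, by full enumeration.

    ``-`` strand windows are enumerated on the reverse complement and mapped
    to the forward coordinate of the base aligned with consensus position 0.
    """
    hits: set[tuple[int, str, int]] = set()
    L, N = len(code), len(seq)
    if strands in ("+", "both"):
        for i in range(N - L + 1):
            m = window_mismatches(seq[i : i + L], code, cap=budget)
            if m <= budget:
                hits.add((i, "+", m))
    if strands in ("-", "both"):
        rc = revcomp(seq)
        for i in range(N - L + 1):
            m = window_mismatches(rc[i : i + L], code, cap=budget)
            if m <= budget:
                hits.add((N - 1 - i, "-", m))
    return hits


def enumerate_global_score(a: str, b: str, score_fn, gap_penalty: float) -> float:
    """Optimal global-alignment score by recursive enumeration of all
    monotone alignments (no DP table). Only for tiny sequences."""

    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, score_fn(a[i], b[j]) + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, -gap_penalty + rec(i + 1, j))
        if j < len(b):
            best = max(best, -gap_penalty + rec(i, j + 1))
        return best

    return rec(0, 0)
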