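"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (dictionaries, plain-Python DP,
concatenate-sort-unique) and shares no code with the package's optimized
paths.
"""

from __future__ import annotations

import itertools

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def naive_kmer_index(ref: str, k: int, buckets: int) -> dict[int, list[int]]:
    """key -> sorted positions, by scanning every k-mer with a dictionary."""
    table: dict[int, list[int]] = {}
    for p in range(len(ref) - k + 1):
        kmer = ref[p : p + k]
        if any(c not in _CODE for c in kmer):
            continue
        code = 0
        for c in kmer:
            code = code * 4 + _CODE[c]
        table.setdefault(code % buckets, []).append(p)
    return table


def naive_merge(runs: list[list[int]]) -> tuple[list[int], list[int]]:
    """Concatenate, sort, unique-with-counts."""
    allpos = sorted(itertools.chain.from_iterable(runs))
    pos_out: list[int] = []
    votes: list[int] = []
    for p in allpos:
        if pos_out and pos_out[-1] == p:
            votes[-1] += 1
        else:
            pos_out.append(p)
            votes.append(1)
    return pos_out, votes


def fitting_affine_score(
    read: str, window: str, match=1, mismatch=4, gap_open=6, gap_ext=1
) -> int:
    """Plain-Python affine-gap fitting alignment score.

    Read aligned end-to-end; leading/trailing window bases free.  Three-state
    DP with O(nm) loops, no vectorization, no traceback.
    """
    n, m = len(read), len(window)
    NEG = float("-inf")
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        H[0][j] = 0
    for i in range(1, n + 1):
        for j in range(m + 1):
            F[i][j] = max(H[i - 1][j] - gap_open - gap_ext, F[i - 1][j] - gap_ext)
            best = F[i][j]
            if j > 0:
                E[i][j] = max(H[i][j - 1] - gap_open - gap_ext, E[i][j - 1] - gap_ext)
                s = match if read[i - 1] == window[j - 1] else -mismatch
                best = max(best, E[i][j], H[i - 1][j - 1] + s)
            H[i][j] = best
    return int(max(H[n]))


def levenshtein(a: str, b: str) -> int:
    """Textbook O(nm) unit-cost edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]
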