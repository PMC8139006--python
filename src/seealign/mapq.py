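"""Mapping quality from the margin between the top two candidates.

Follows the Bowtie2-style idea — confidence grows with the quality of the
best hit and with the gap to the runner-up — recast as a closed form over
the embedded length L_e (2x or 3x the read length, depending on the
embedding variant) and the top-two embedding distances:

    s1   = 1 − d_best / L_e
    diff = (d_second − d_best) / L_e
    MAPQ = round(42 · s1 · min(1, 2·diff)),  clamped to [0, 42]

A read with a single candidate gets d_second = L_e.  In alignment-score
mode the same formula runs on pseudo-distances d_i = s_max − score_i with
the normalizer Z = read_len·(match + mismatch) in place of L_e.
"""

from __future__ import annotations

MAPQ_MAX = 42


def compute_mapq(d_best: float, d_second: float | None, scale: float,
                 mode: str = "embed") -> int:
    """MAPQ in [0, 42] from the top-two distances on scale ``scale`` (L_e or Z).

    ``d_second=None`` means "no second candidate" and is treated as
    ``scale``.  Raises if ``d_best > d_second`` (contract violation).
    """
    if mode not in ("embed", "score"):
        raise ValueError(f"unknown MAPQ mode {mode!r}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if d_second is None:
        d_second = scale
    if d_best > d_second:
        raise ValueError(f"d_best={d_best} > d_second={d_second}")
    d_best = min(max(d_best, 0.0), scale)
    d_second = min(max(d_second, 0.0), scale)
    s1 = 1.0 - d_best / scale
    diff = (d_second - d_best) / scale
    q = MAPQ_MAX * s1 * min(1.0, 2.0 * diff)
    return max(0, min(MAPQ_MAX, int(q + 0.5)))


def mapq_from_scores(best_score: int, second_score: int | None, read_len: int,
                     match: int, mismatch: int) -> int:
    """Alignment-score MAPQ: converts scores to pseudo-distances from the
    perfect score s_max = read_len·match and applies the same formula."""
    z = read_len * (match + mismatch)
    s_max = read_len * match
    d1 = s_max - best_score
    d2 = None if second_score is None else max(s_max - second_score, d1)
    return compute_mapq(d1, d2, z, mode="score")
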