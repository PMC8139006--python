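"""Affine-gap extension of the read at the selected reference window.

The read is aligned end-to-end against a reference window of length
read_len + l (l = the INDEL allowance); unaligned reference bases at either
flank are free (fitting alignment), which lets the alignment absorb the net
INDEL drift the window slack was added for.  Scoring maximizes
match·(#matches) − mismatch·(#mismatches) − Σ_gaps (gap_open + len·gap_ext);
a 1-base gap therefore costs gap_open + gap_ext.  CIGAR uses M for both
match and mismatch (no soft clipping).  Tie-breaking is deterministic:
M over D over I at every cell, and gap closings are preferred to gap
extensions on equal score, with the leftmost end column chosen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .config import Config

NEG = -(1 << 40)

# traceback pointer codes
_PH_M, _PH_E, _PH_F = 0, 1, 2
_CLOSE, _EXTEND = 0, 1


class Alignment(NamedTuple):
    score: int
    cigar: str
    ref_start: int  # leading unaligned (free) reference bases
    ref_end: int  # window offset one past the last aligned reference base


@dataclass
class AlignmentResult:
    """Final mapping of one read (one SAM record's worth of information)."""

    read_id: str
    mapped: bool
    seq: str  # as written to SAM: reverse-complemented for "-" strand hits
    qual: Optional[str] = None
    ref_name: Optional[str] = None
    pos: Optional[int] = None  # 0-based, per-sequence
    strand: str = "+"
    score: Optional[int] = None
    cigar: Optional[str] = None
    mapq: int = 0
    embed_dist: Optional[int] = None
    nm: Optional[int] = None
    ref_span: Optional[int] = None  # reference bases consumed (M+D)
    # pair bookkeeping (filled by align_pair / the SAM writer)
    is_paired: bool = False
    mate: int = 0  # 1 or 2, 0 for unpaired
    proper_pair: bool = False
    mate_mapped: bool = False
    mate_ref_name: Optional[str] = None
    mate_pos: Optional[int] = None
    mate_strand: str = "+"
    tlen: int = 0


def global_affine_align(
    read_seq: str,
    ref_window: str,
    match: int = 1,
    mismatch: int = 4,
    gap_open: int = 6,
    gap_ext: int = 1,
) -> Alignment:
    """Fitting alignment of ``read_seq`` (end-to-end) against ``ref_window``
    (free flanks), maximizing the affine-gap score.

    Returns the score, the CIGAR over {M, I, D}, and the window offsets of
    the aligned reference segment.  Row-vectorized dynamic programming; the
    horizontal (deletion) state is computed with a prefix-maximum, which is
    exact because re-opening a gap out of a gap state never beats extending.
    """
    n, m = len(read_seq), len(ref_window)
    if n == 0 or m == 0:
        raise ValueError("both sequences must be non-empty")
    r = np.frombuffer(read_seq.encode("ascii"), dtype=np.uint8)
    w = np.frombuffer(ref_window.encode("ascii"), dtype=np.uint8)
    go, ge = gap_open, gap_ext

    H = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Ev = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Fv = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    PH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PB = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 = diagonal (M), 1 = Fv

    H[0, :] = 0  # free leading reference flank
    jcol = np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        # vertical state (insertion to the reference = I, consumes read only)
        open_v = H[i - 1, :] - go - ge
        ext_v = Fv[i - 1, :] - ge
        Fv[i, :] = np.maximum(open_v, ext_v)
        PF[i, :] = np.where(open_v >= ext_v, _CLOSE, _EXTEND)
        # best value reachable without a horizontal gap ending at (i, j)
        sub = np.where(w == r[i - 1], match, -mismatch)
        diag = H[i - 1, :-1] + sub
        B = np.maximum(diag, Fv[i, 1:])
        PB[i, 1:] = np.where(diag >= Fv[i, 1:], 0, 1)
        H[i, 0] = Fv[i, 0]
        PH[i, 0] = _PH_F
        # horizontal state (deletion from the read's view = D) via prefix max
        base = np.concatenate(([H[i, 0]], B))  # gap origins at columns 0..m-1
        t = base + jcol * ge
        pref = np.maximum.accumulate(t[:-1])
        Ev[i, 1:] = pref - go - jcol[1:] * ge
        close_val = base[:-1] - go - ge  # close a length-1 hop from column j-1
        ext_val = Ev[i, :-1] - ge
        PE[i, 1:] = np.where(close_val >= ext_val, _CLOSE, _EXTEND)
        # cell value, preferring M over D over I
        Hrow = np.maximum(B, Ev[i, 1:])
        H[i, 1:] = Hrow
        PH[i, 1:] = np.where(
            diag == Hrow, _PH_M, np.where(Ev[i, 1:] == Hrow, _PH_E, _PH_F)
        )

    jstar = int(np.argmax(H[n, :]))  # leftmost end column on ties
    score = int(H[n, jstar])

    # traceback
    ops: list[str] = []
    i, j = n, jstar
    state = "H"
    while i > 0:
        if state == "H":
            p = PH[i, j]
            if p == _PH_M:
                ops.append("M")
                i -= 1
                j -= 1
            elif p == _PH_E:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            closing = PE[i, j] == _CLOSE
            j -= 1
            if closing:
                state = "B"
        elif state == "B":
            if j == 0:
                state = "H"  # gap origin is the column-0 insertion chain
            elif PB[i, j] == 0:
                ops.append("M")
                i -= 1
                j -= 1
                state = "H"
            else:
                state = "F"
        elif state == "F":
            ops.append("I")
            closing = PF[i, j] == _CLOSE
            i -= 1
            if closing:
                state = "H"
    ref_start = j

    # run-length encode (ops were collected in reverse)
    cigar_parts: list[str] = []
    run_op, run_len = None, 0
    for op in reversed(ops):
        if op == run_op:
            run_len += 1
        else:
            if run_op is not None:
                cigar_parts.append(f"{run_len}{run_op}")
            run_op, run_len = op, 1
    if run_op is not None:
        cigar_parts.append(f"{run_len}{run_op}")
    return Alignment(score, "".join(cigar_parts), ref_start, jstar)


def cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(read-consumed, reference-consumed, gap bases) of a CIGAR over M/I/D."""
    read_c = ref_c = gaps = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            length = int(num)
            num = ""
            if ch == "M":
                read_c += length
                ref_c += length
            elif ch == "I":
                read_c += length
                gaps += length
            elif ch == "D":
                ref_c += length
                gaps += length
            else:
                raise ValueError(f"unsupported CIGAR op {ch!r}")
    return read_c, ref_c, gaps


def edit_distance_of_alignment(read_seq: str, ref_segment: str, cigar: str) -> int:
    """NM: mismatches plus inserted plus deleted bases of the reported
    alignment (``ref_segment`` is the aligned reference span only)."""
    nm = 0
    ri = gi = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        length = int(num)
        num = ""
        if ch == "M":
            nm += sum(
                1 for a, b in zip(read_seq[ri : ri + length], ref_segment[gi : gi + length]) if a != b
            )
            ri += length
            gi += length
        elif ch == "I":
            nm += length
            ri += length
        elif ch == "D":
            nm += length
            gi += length
    return nm


def extend_best(
    read_seq: str, pos: int, reference, cfg: Config
) -> tuple[int, Optional[int], Optional[str], Optional[int], int]:
    """Extend the (rectified) best candidate.

    ``read_seq`` must be oriented to the candidate's strand; ``pos`` is the
    global reference offset.  In mode="align" runs the fitting alignment and
    returns (final_pos, score, cigar, nm, ref_span); in mode="map" the
    position alone is reported (cigar None, span assumed = read length).
    """
    read_len = len(read_seq)
    if cfg.mode == "map":
        return pos, None, None, None, read_len
    from .embedding import indel_window

    l = indel_window(read_len, cfg.l_frac)
    window = reference.window(pos, read_len + l)
    if not window:
        return pos, None, None, None, read_len
    aln = global_affine_align(
        read_seq, window, cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_ext
    )
    final_pos = pos + aln.ref_start
    segment = window[aln.ref_start : aln.ref_end]
    nm = edit_distance_of_alignment(read_seq, segment, aln.cigar)
    return final_pos, aln.score, aln.cigar, nm, aln.ref_end - aln.ref_start
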