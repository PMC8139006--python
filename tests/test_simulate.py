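import numpy as np
import pytest

import seealign as sa
from seealign.simulate import (
    apply_edits,
    edit_distance,
    evaluate_mappings,
    measure_distortion,
    read_truth,
    simulate_reads,
    simulate_reference,
    write_truth,
)

from oracles import levenshtein


def test_reference_determinism_and_alphabet():
    a = simulate_reference(100, 1)
    assert len(a) == 100 and set(a) <= set("ACGT")
    assert a == simulate_reference(100, 1)
    assert a != simulate_reference(100, 2)


def test_error_free_reads_are_exact_substrings():
    ref = simulate_reference(5000, 3)
    reads, truth = simulate_reads(ref, 50, sub_rate=0, indel_rate=0, seed=4)
    assert len(reads) == len(truth) == 50
    for r, t in zip(reads, truth):
        seq = r.seq if t.strand == "+" else sa.revcomp(r.seq)
        assert ref[t.pos : t.pos + 100] == seq
        assert t.edits == []


def test_paired_mode_counts_and_orientation():
    ref = simulate_reference(20_000, 5)
    reads, truth = simulate_reads(ref, 100, paired=True, seed=6)
    assert len(reads) == 200
    m1 = {t.read_id: t for t in truth if t.mate == 1}
    m2 = {t.read_id: t for t in truth if t.mate == 2}
    assert len(m1) == len(m2) == 100
    for rid, t1 in m1.items():
        t2 = m2[rid]
        assert (t1.strand, t2.strand) == ("+", "-")
        assert t2.pos >= t1.pos


def test_substitution_rate_recovered():
    """Empirical substitution rate within 3 standard errors of the request."""
    ref = simulate_reference(30_000, 7)
    n, read_len, rate = 1000, 100, 0.02
    reads, truth = simulate_reads(ref, n, read_len=read_len, sub_rate=rate,
                                  indel_rate=0, seed=8)
    n_sub = sum(len(t.edits) for t in truth)
    total = n * read_len
    se = (rate * (1 - rate) * total) ** 0.5
    assert abs(n_sub - rate * total) <= 3 * se


def test_truth_records_reproduce_reads():
    """Replaying each truth record's edits against its origin window yields
    the simulated read exactly (INDELs included)."""
    ref = simulate_reference(50_000, 9)
    reads, truth = simulate_reads(ref, 300, sub_rate=0.05, indel_rate=0.02, seed=10)
    for r, t in zip(reads, truth):
        window = ref[t.pos : t.pos + 124]
        rebuilt = apply_edits(window, t.edits, 100)
        want = r.seq if t.strand == "+" else sa.revcomp(r.seq)
        assert rebuilt == want


def test_truth_tsv_roundtrip(tmp_path):
    ref = simulate_reference(5000, 11)
    _, truth = simulate_reads(ref, 20, sub_rate=0.05, indel_rate=0.02, seed=12)
    p = tmp_path / "truth.tsv"
    write_truth(truth, p)
    back = read_truth(p)
    assert [(t.read_id, t.mate, t.pos, t.strand, t.edits) for t in back] == [
        (t.read_id, t.mate, t.pos, t.strand, [tuple(e) for e in t.edits]) for t in truth
    ]


class _R:
    def __init__(self, read_id, mate, mapped, pos, span=100, ref_name="sim_ref"):
        self.read_id, self.mate, self.mapped = read_id, mate, mapped
        self.ref_name = ref_name if mapped else None
        self.pos = pos
        self.ref_span = span


def _truth(n):
    from seealign.simulate import TruthRecord

    return [TruthRecord(f"sim{i}", 0, "sim_ref", 1000 + 10 * i, "+", []) for i in range(n)]


def test_evaluate_all_exact():
    truth = _truth(10)
    res = [_R(t.read_id, 0, True, t.pos) for t in truth]
    m = evaluate_mappings(res, truth, 100)
    assert m == {"n_reads": 10, "correctly_mapped": 1.0, "unmapped": 0.0}


def test_evaluate_all_unmapped():
    truth = _truth(5)
    res = [_R(t.read_id, 0, False, None) for t in truth]
    m = evaluate_mappings(res, truth, 100)
    assert m["correctly_mapped"] == 0.0 and m["unmapped"] == 1.0


def test_evaluate_overlap_boundary_inclusive():
    truth = _truth(1)
    # reported start = true start + 90 -> overlap exactly 10 = 0.1 * 100
    res = [_R(truth[0].read_id, 0, True, truth[0].pos + 90)]
    assert evaluate_mappings(res, truth, 100)["correctly_mapped"] == 1.0
    res = [_R(truth[0].read_id, 0, True, truth[0].pos + 91)]
    assert evaluate_mappings(res, truth, 100)["correctly_mapped"] == 0.0


def test_evaluate_rejects_unknown_read():
    truth = _truth(2)
    res = [_R("nope", 0, True, 0)]
    with pytest.raises(ValueError):
        evaluate_mappings(res, truth, 100)


def test_edlib_oracle_agrees_with_textbook_dp(rng):
    for _ in range(20):
        n = int(rng.integers(1, 40))
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(1, 40))))
        assert edit_distance(a, b) == levenshtein(a, b)


def test_measure_distortion_small_run():
    rep = measure_distortion(50, 60, 5, variant="2n", rng_seed=1)
    assert rep.n_pairs == 50 and 0.0 <= rep.fraction_ge1 <= 1.0
    assert rep.mean_distortion >= 1.0  # embeddings expand differences
    rep2 = measure_distortion(50, 60, 5, variant="2n", rng_seed=1)
    assert rep2 == rep  # deterministic per seed
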