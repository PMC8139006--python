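"""Seed extraction and candidate gathering.

Reads are cut into non-overlapping k-mers; each seed's index hits are
normalized by subtracting the seed's offset in the read, so every seed of a
correctly placed read votes for the same reference position.  Per-seed runs
arrive sorted (a property of the index layout) and are merged duplicate-free
with a min-heap in O(N_l) heap operations, accumulating a vote count per
position.  No candidate is filtered out — voting only reorders later work.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from .index import ReferenceIndex, UnencodableKmerError, encode_kmer, lookup


@dataclass
class Seed:
    offset: int  # offset of the k-mer within the read
    code: int  # 2-bit packed k-mer


@dataclass
class SeedSet:
    seeds: list
    k: int
    shift: int  # offset of the first seed (0 unless shift-retry engaged)
    n_dropped: int  # seeds skipped because they contain non-ACGT characters

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)


@dataclass
class Candidate:
    """A normalized reference position a read might align to."""

    pos: int
    votes: int = 1
    strand: str = "+"
    embed_dist: int | None = None
    paired: bool = False


@dataclass
class CandidateSet:
    candidates: list = field(default_factory=list)
    n_raw: int = 0  # candidates across seeds after normalization, pre-dedup
    heap_ops: int = 0
    shift: int = 0

    def __len__(self) -> int:
        return len(self.candidates)


def extract_seeds(read_seq: str, k: int, shift: int = 0) -> SeedSet:
    """Non-overlapping k-mers at offsets shift, shift+k, ... within the read.

    Seeds containing non-ACGT characters are dropped (and counted).  A read
    shorter than k yields an empty seed set.
    """
    if not (0 <= shift < k):
        raise ValueError(f"shift={shift} outside [0, {k})")
    seeds, dropped = [], 0
    for off in range(shift, len(read_seq) - k + 1, k):
        try:
            seeds.append(Seed(off, encode_kmer(read_seq[off : off + k])))
        except UnencodableKmerError:
            dropped += 1
    return SeedSet(seeds=seeds, k=k, shift=shift, n_dropped=dropped)


def _merge_runs(runs: list[list[int]], strand: str) -> tuple[list[Candidate], int]:
    """k-way merge of sorted position runs into a duplicate-free ascending
    candidate list with votes.  Returns (candidates, heap op count)."""
    heap = [(run[0], si, 0) for si, run in enumerate(runs) if run]
    heapq.heapify(heap)
    ops = len(heap)  # initial pushes
    out: list[Candidate] = []
    while heap:
        pos, si, i = heapq.heappop(heap)
        ops += 1
        if out and out[-1].pos == pos:
            out[-1].votes += 1
        else:
            out.append(Candidate(pos=pos, strand=strand))
        if i + 1 < len(runs[si]):
            heapq.heappush(heap, (runs[si][i + 1], si, i + 1))
            ops += 1
    return out, ops


def collect_candidates(
    index: ReferenceIndex,
    seedset: SeedSet,
    read_seq: str | None = None,
    strand: str = "+",
) -> CandidateSet:
    """Gather, normalize and merge candidate positions for one read.

    Normalized position = hit position − seed offset; negative values (seed
    hit too close to the reference start) are discarded.  If every seed
    yields zero hits and ``read_seq`` is given, the whole non-overlapping
    seed frame is shifted by one base and re-tried, up to shift k−1, before
    declaring the read candidate-free.
    """
    ss = seedset
    while True:
        runs, n_raw = [], 0
        for seed in ss.seeds:
            hits = lookup(index, seed.code)
            if len(hits) == 0:
                continue
            run = [int(p) - seed.offset for p in hits.tolist()]
            # runs are ascending, so negatives form a prefix
            first = 0
            while first < len(run) and run[first] < 0:
                first += 1
            run = run[first:]
            if run:
                runs.append(run)
                n_raw += len(run)
        if n_raw:
            cands, ops = _merge_runs(runs, strand)
            return CandidateSet(candidates=cands, n_raw=n_raw, heap_ops=ops, shift=ss.shift)
        if read_seq is None or ss.shift + 1 >= ss.k:
            return CandidateSet(candidates=[], n_raw=0, heap_ops=0, shift=ss.shift)
        ss = extract_seeds(read_seq, ss.k, ss.shift + 1)
        if not ss.seeds:
            return CandidateSet(candidates=[], n_raw=0, heap_ops=0, shift=ss.shift)


def pair_candidates(
    set1: CandidateSet, set2: CandidateSet, pair_dist: int
) -> list[tuple[Candidate, Candidate]]:
    """All pairs (c1, c2) with |c1.pos − c2.pos| ≤ pair_dist, by a linear
    two-pointer sweep over the position-sorted sets.  Members of at least
    one pair are flagged ``paired``."""
    a, b = set1.candidates, set2.candidates
    pairs: list[tuple[Candidate, Candidate]] = []
    j0 = 0
    for c1 in a:
        while j0 < len(b) and b[j0].pos < c1.pos - pair_dist:
            j0 += 1
        j = j0
        while j < len(b) and b[j].pos <= c1.pos + pair_dist:
            c1.paired = True
            b[j].paired = True
            pairs.append((c1, b[j]))
            j += 1
    return pairs
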