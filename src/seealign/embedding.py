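"""Randomized edit-to-Hamming embeddings and candidate selection.

The embeddings map DNA strings into longer strings so that the Hamming
distance between two embedded strings tracks the edit distance between the
originals (low distortion, with high probability).  Two variants:

* 3N — walk an output index i = 0..3N−1 with an input cursor j; emit x[j]
  (or the pad once the input is exhausted) and advance j when a random bit
  r(i, x[j]) fires.  Output length exactly 3N.
* 2N — each input character is emitted once, and a second time when the
  random bit r(j, x[j]) fires; the output is padded to exactly 2N.

Both read their bits from one shared random table; every string embedded
within a run MUST use the same :class:`EmbeddingFunctions` instance or the
Hamming distances are not comparable.

Distance computation is pipelined: the candidate's embedded characters are
generated one at a time and compared against the pre-embedded read, so a
candidate can be abandoned (early-stop) the moment its running mismatch
count exceeds the current second-best distance.  Selection visits
candidates in descending vote order (prioritizing), which tightens the
early-stop threshold sooner but — by construction — never changes which two
candidates win, nor their distances.
"""

from __future__ import annotations

import numpy as np

from .config import Config
from .index import revcomp
from .seeding import Candidate

ALPHABET = "ACGTN"
_IDX = {c: i for i, c in enumerate(ALPHABET)}
PAD = "P"

#: embedded length multiplier per variant
FACTORS = {"2n": 2, "3n": 3}


class EmbeddingFunctions:
    """The shared random bit tables r(i, c) driving both embeddings.

    Deterministic for a given ``rng_seed``; covers inputs up to ``max_len``
    characters over {A, C, G, T, N}.  The pad character "P" is outside the
    alphabet: pads never advance the cursor and compare equal only to pads.
    """

    def __init__(self, rng_seed: int = 1729, max_len: int = 512,
                 bits3: np.ndarray | None = None, bits2: np.ndarray | None = None):
        rng = np.random.default_rng(rng_seed)
        if bits3 is None:
            bits3 = rng.integers(0, 2, size=(3 * max_len, len(ALPHABET)), dtype=np.uint8)
        if bits2 is None:
            bits2 = rng.integers(0, 2, size=(max_len, len(ALPHABET)), dtype=np.uint8)
        self.rng_seed = rng_seed
        self.max_len = max_len
        self.pad_char = PAD
        self.bits3 = bits3
        self.bits2 = bits2
        # plain nested lists are markedly faster in the per-character loops
        self._b3 = bits3.tolist()
        self._b2 = bits2.tolist()

    def bit(self, i: int, c: str, variant: str = "3n") -> int:
        table = self._b3 if variant == "3n" else self._b2
        return table[i][_IDX[c]]

    @classmethod
    def constant(cls, value: int, max_len: int = 64) -> "EmbeddingFunctions":
        """All-zeros or all-ones bit tables (for forced, deterministic cases)."""
        full = np.full((3 * max_len, len(ALPHABET)), value, dtype=np.uint8)
        return cls(rng_seed=0, max_len=max_len, bits3=full, bits2=full[:max_len])


def make_embedding_functions(rng_seed: int, max_len: int = 512) -> EmbeddingFunctions:
    return EmbeddingFunctions(rng_seed=rng_seed, max_len=max_len)


def embed_3n(x: str, F: EmbeddingFunctions) -> str:
    """3N embedding: output of length exactly 3·len(x)."""
    n = len(x)
    if n > F.max_len:
        raise ValueError(f"input length {n} exceeds embedding table size {F.max_len}")
    b3, idx = F._b3, _IDX
    out = []
    j = 0
    for i in range(3 * n):
        if j < n:
            ch = x[j]
            out.append(ch)
            if b3[i][idx[ch]]:
                j += 1
        else:
            out.append(PAD)
    return "".join(out)


def embed_2n(x: str, F: EmbeddingFunctions) -> str:
    """2N embedding: each character copied once or twice, padded to 2·len(x)."""
    n = len(x)
    if n > F.max_len:
        raise ValueError(f"input length {n} exceeds embedding table size {F.max_len}")
    b2, idx = F._b2, _IDX
    out = []
    for j, ch in enumerate(x):
        out.append(ch)
        if b2[j][idx[ch]]:
            out.append(ch)
    out.extend(PAD * (2 * n - len(out)))
    return "".join(out)


def embed(x: str, F: EmbeddingFunctions, variant: str) -> str:
    if variant == "3n":
        return embed_3n(x, F)
    if variant == "2n":
        return embed_2n(x, F)
    raise ValueError(f"unknown embedding variant {variant!r}")


def hamming_embedded(a: str, b: str) -> int:
    """Hamming distance between embedded strings; the shorter one is
    conceptually extended with pads (pad==pad matches)."""
    if len(a) < len(b):
        a, b = b, a
    d = sum(1 for x, y in zip(a, b) if x != y)
    d += sum(1 for x in a[len(b):] if x != PAD)
    return d


def embedding_distance(
    embedded_read: str,
    candidate_window: str,
    F: EmbeddingFunctions,
    variant: str,
    threshold: int | None = None,
) -> int:
    """Pipelined Hamming distance between ``embedded_read`` and the embedding
    of ``candidate_window``.

    The candidate's embedded characters are generated one at a time; if the
    running mismatch count exceeds ``threshold`` the computation stops and
    ``threshold + 1`` is returned (a sentinel meaning "worse than the
    threshold").  With ``threshold=None`` the result equals
    ``hamming_embedded(embedded_read, embed(candidate_window))`` exactly.
    Positions past either string's end count as pads.
    """
    n = len(candidate_window)
    if n > F.max_len:
        raise ValueError(f"window length {n} exceeds embedding table size {F.max_len}")
    Lr = len(embedded_read)
    idx = _IDX
    d = 0
    if variant == "3n":
        total = max(Lr, 3 * n)
        b3 = F._b3
        j = 0
        cap = 3 * n
        for i in range(total):
            if i < cap and j < n:
                ch = candidate_window[j]
                if b3[i][idx[ch]]:
                    j += 1
            else:
                ch = PAD
            rc = embedded_read[i] if i < Lr else PAD
            if ch != rc:
                d += 1
                if threshold is not None and d > threshold:
                    return threshold + 1
        return d
    if variant == "2n":
        total = max(Lr, 2 * n)
        b2 = F._b2
        i = 0
        for j in range(n):
            ch = candidate_window[j]
            reps = 2 if b2[j][idx[ch]] else 1
            for _ in range(reps):
                rc = embedded_read[i] if i < Lr else PAD
                if ch != rc:
                    d += 1
                    if threshold is not None and d > threshold:
                        return threshold + 1
                i += 1
        while i < total:
            rc = embedded_read[i] if i < Lr else PAD
            if rc != PAD:
                d += 1
                if threshold is not None and d > threshold:
                    return threshold + 1
            i += 1
        return d
    raise ValueError(f"unknown embedding variant {variant!r}")


def _cand_key(c: Candidate):
    # equal distances -> higher votes, then smaller pos, then forward strand
    return (c.embed_dist, -c.votes, c.pos, 0 if c.strand == "+" else 1)


def select_candidates(
    read_seq: str,
    cands: list[Candidate],
    reference,
    F: EmbeddingFunctions,
    cfg: Config,
    early_stop: bool = True,
    prioritize: bool = True,
):
    """Embed the read once and every candidate window once, tracking the top
    two candidates with least embedding distance.

    Candidates carry a strand: "−" candidates are compared against the
    embedded reverse-complement of the read, so both orientations compete
    on one scale.  All candidates are visited; prioritizing (vote-descending
    order) and early-stop only save work.  The returned ``(best, second)``
    pair — members and distances — is independent of both optimizations: a
    candidate early-stops only when its distance strictly exceeds the
    current second-best, which already bars it from the top two.
    """
    if not cands:
        return None, None
    variant = cfg.embedding
    if prioritize:
        order = sorted(cands, key=lambda c: (-c.votes, c.pos, 0 if c.strand == "+" else 1))
    else:
        order = list(cands)
    ereads: dict[str, str] = {}
    read_len = len(read_seq)
    best: Candidate | None = None
    second: Candidate | None = None
    for c in order:
        strand = c.strand
        er = ereads.get(strand)
        if er is None:
            oriented = read_seq if strand == "+" else revcomp(read_seq)
            er = embed(oriented, F, variant)
            ereads[strand] = er
        window = reference.window(c.pos, read_len)
        thr = second.embed_dist if (early_stop and second is not None) else None
        c.embed_dist = embedding_distance(er, window, F, variant, thr)
        if best is None:
            best = c
        elif _cand_key(c) < _cand_key(best):
            second = best
            best = c
        elif second is None or _cand_key(c) < _cand_key(second):
            second = c
    return best, second


def indel_window(read_len: int, l_frac: float) -> int:
    """Half-width l of the rectification scan: max(1, round(l_frac·read_len))."""
    return max(1, round(l_frac * read_len))


def rectify_position(
    best: Candidate, read_seq: str, reference, F: EmbeddingFunctions, cfg: Config
) -> int:
    """INDEL-aware correction of the selected position.

    Seed-offset normalization can be off by the net INDEL length when an
    INDEL precedes the seed that produced the candidate.  The read's first
    k-mer is embedded once and compared against reference k-mers starting at
    every s in [P−l, P+l] (within the containing record); the minimum-
    distance start wins, ties broken by |s−P| then by smaller s.
    ``read_seq`` must be oriented to match the candidate's strand.
    """
    P = best.pos
    k = cfg.k
    if len(read_seq) < k:
        return P
    l = indel_window(len(read_seq), cfg.l_frac)
    lo, hi = reference.record_bounds(P)
    eseed = embed(read_seq[:k], F, cfg.embedding)
    best_s, best_key = None, None
    for s in range(P - l, P + l + 1):
        if s < lo or s + k > hi:
            continue
        window = reference.seq[s : s + k]
        d = embedding_distance(eseed, window, F, cfg.embedding, None)
        key = (d, abs(s - P), s)
        if best_key is None or key < best_key:
            best_key, best_s = key, s
    return P if best_s is None else best_s
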