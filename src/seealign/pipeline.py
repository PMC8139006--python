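"""Per-read orchestration: seed both strands, embed, rectify, extend, score.

Forward and reverse-complement candidate lists compete inside one selection
pass (their embedding distances are on the same scale because the random
bit table is shared), so strand choice falls out of the top-2 tracking.
Paired-end mates are evaluated jointly over candidate pairs within the
configured distance, with independent single-end alignment as the fallback.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

from .config import Config
from .embedding import (
    EmbeddingFunctions,
    FACTORS,
    embed,
    embedding_distance,
    rectify_position,
    select_candidates,
)
from .extension import AlignmentResult, extend_best, global_affine_align, \
    edit_distance_of_alignment
from .index import ReferenceIndex, Reference, revcomp
from .mapq import compute_mapq, mapq_from_scores
from .seeding import Candidate, collect_candidates, extract_seeds, pair_candidates


@dataclass
class Read:
    """One sequencing read (FASTQ record or mate of a pair)."""

    id: str
    seq: str
    qual: Optional[str] = None
    mate: int = 0  # 1 or 2 for paired input, 0 for unpaired

    def __post_init__(self):
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


def _unmapped(read: Read) -> AlignmentResult:
    return AlignmentResult(
        read_id=read.id, mapped=False, seq=read.seq, qual=read.qual, mate=read.mate
    )


def gather_candidates(read_seq: str, index: ReferenceIndex, cfg: Config):
    """Candidate sets for both orientations of a read: {strand: CandidateSet}."""
    out = {}
    for strand, oriented in (("+", read_seq), ("-", revcomp(read_seq))):
        ss = extract_seeds(oriented, cfg.k)
        out[strand] = collect_candidates(index, ss, oriented, strand=strand)
    return out


def _oriented(read_seq: str, strand: str) -> str:
    return read_seq if strand == "+" else revcomp(read_seq)


def _finalize(
    read: Read,
    best: Candidate,
    second: Optional[Candidate],
    reference: Reference,
    F: Optional[EmbeddingFunctions],
    cfg: Config,
) -> AlignmentResult:
    """Rectify, extend, and score the winning candidate of one read."""
    seq = read.seq.upper()
    oriented = _oriented(seq, best.strand)
    pos = best.pos
    if cfg.embedding != "none" and F is not None:
        pos = rectify_position(best, oriented, reference, F, cfg)
    final_pos, score, cigar, nm, ref_span = extend_best(oriented, pos, reference, cfg)
    read_len = len(seq)

    if cfg.embedding == "none" or cfg.mapq_mode == "score":
        second_score = None
        if second is not None:
            o2 = _oriented(seq, second.strand)
            p2 = second.pos
            if cfg.embedding != "none" and F is not None:
                p2 = rectify_position(second, o2, reference, F, cfg)
            if cfg.mode == "map":
                # score mode needs actual extensions; align both regardless
                cfg2 = dataclasses.replace(cfg, mode="align")
                _, second_score, _, _, _ = extend_best(o2, p2, reference, cfg2)
                _, best_score, _, _, _ = extend_best(oriented, pos, reference, cfg2)
            else:
                _, second_score, _, _, _ = extend_best(o2, p2, reference, cfg)
                best_score = score
        else:
            if cfg.mode == "map":
                cfg2 = dataclasses.replace(cfg, mode="align")
                _, best_score, _, _, _ = extend_best(oriented, pos, reference, cfg2)
            else:
                best_score = score
        mapq = mapq_from_scores(best_score, second_score, read_len, cfg.match, cfg.mismatch)
    else:
        L_e = FACTORS[cfg.embedding] * read_len
        d2 = second.embed_dist if second is not None else None
        if d2 is not None and d2 < best.embed_dist:
            # pairing constraints can promote a locally worse candidate;
            # a runner-up that beats the winner means zero margin
            d2 = best.embed_dist
        mapq = compute_mapq(best.embed_dist, d2, L_e)

    _, ref_name, local_pos = reference.locate(final_pos)
    out_seq = oriented
    out_qual = read.qual if best.strand == "+" else (
        read.qual[::-1] if read.qual is not None else None
    )
    return AlignmentResult(
        read_id=read.id,
        mapped=True,
        seq=out_seq,
        qual=out_qual,
        ref_name=ref_name,
        pos=local_pos,
        strand=best.strand,
        score=score,
        cigar=cigar,
        mapq=mapq,
        embed_dist=best.embed_dist,
        nm=nm,
        ref_span=ref_span,
        mate=read.mate,
    )


def _select_no_embed(seq: str, cands: list[Candidate], reference: Reference, cfg: Config):
    """Ablation path: extend every candidate, best alignment score wins."""
    from .embedding import indel_window

    read_len = len(seq)
    l = indel_window(read_len, cfg.l_frac)
    scored = []
    for c in cands:
        oriented = _oriented(seq, c.strand)
        window = reference.window(c.pos, read_len + l)
        if not window:
            continue
        aln = global_affine_align(
            oriented, window, cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_ext
        )
        scored.append((-aln.score, c.pos, 0 if c.strand == "+" else 1, c))
    if not scored:
        return None, None, None, None
    scored.sort(key=lambda t: t[:3])
    best = scored[0][3]
    best_score = -scored[0][0]
    second = scored[1][3] if len(scored) > 1 else None
    second_score = -scored[1][0] if len(scored) > 1 else None
    return best, second, best_score, second_score


def align_read(
    read: Read,
    index: ReferenceIndex,
    reference: Reference,
    F: Optional[EmbeddingFunctions],
    cfg: Config,
) -> AlignmentResult:
    """Align one single-end read; an unmapped result is a valid outcome."""
    seq = read.seq.upper()
    if len(seq) < cfg.k:
        return _unmapped(read)
    sets = gather_candidates(seq, index, cfg)
    cands = sets["+"].candidates + sets["-"].candidates
    if not cands:
        return _unmapped(read)
    if cfg.embedding == "none":
        best, second, _, _ = _select_no_embed(seq, cands, reference, cfg)
        if best is None:
            return _unmapped(read)
        return _finalize(read, best, second, reference, None, cfg)
    best, second = select_candidates(seq, cands, reference, F, cfg)
    return _finalize(read, best, second, reference, F, cfg)


def _pair_fields(r1: AlignmentResult, r2: AlignmentResult, proper: bool) -> None:
    r1.is_paired = r2.is_paired = True
    r1.mate, r2.mate = 1, 2
    r1.proper_pair = r2.proper_pair = proper and r1.mapped and r2.mapped
    r1.mate_mapped, r2.mate_mapped = r2.mapped, r1.mapped
    r1.mate_ref_name, r1.mate_pos, r1.mate_strand = r2.ref_name, r2.pos, r2.strand
    r2.mate_ref_name, r2.mate_pos, r2.mate_strand = r1.ref_name, r1.pos, r1.strand
    # SAM convention: an unmapped mate is placed at its mapped partner
    if r1.mapped and not r2.mapped:
        r2.ref_name, r2.pos = r1.ref_name, r1.pos
        r2.mate_ref_name, r2.mate_pos = r1.ref_name, r1.pos
    elif r2.mapped and not r1.mapped:
        r1.ref_name, r1.pos = r2.ref_name, r2.pos
        r1.mate_ref_name, r1.mate_pos = r2.ref_name, r2.pos
    if r1.mapped and r2.mapped and r1.ref_name == r2.ref_name:
        lo = min(r1.pos, r2.pos)
        hi = max(r1.pos + (r1.ref_span or 0), r2.pos + (r2.ref_span or 0))
        tlen = hi - lo
        r1.tlen = tlen if r1.pos <= r2.pos else -tlen
        r2.tlen = -r1.tlen


def align_pair(
    read1: Read,
    read2: Read,
    index: ReferenceIndex,
    reference: Reference,
    F: Optional[EmbeddingFunctions],
    cfg: Config,
) -> tuple[AlignmentResult, AlignmentResult]:
    """Jointly align a mate pair.

    Candidate pairs within ``pair_dist`` (opposite strands, FR layout) are
    scored by the sum of the two embedding distances; if none qualifies,
    each mate is aligned independently and the proper-pair flag stays clear.
    """
    seq1, seq2 = read1.seq.upper(), read2.seq.upper()
    pairs = []
    sets1 = sets2 = None
    if len(seq1) >= cfg.k and len(seq2) >= cfg.k:
        sets1 = gather_candidates(seq1, index, cfg)
        sets2 = gather_candidates(seq2, index, cfg)
        for s1, s2 in (("+", "-"), ("-", "+")):
            pairs.extend(pair_candidates(sets1[s1], sets2[s2], cfg.pair_dist))

    if not pairs or cfg.embedding == "none" or F is None:
        r1 = align_read(read1, index, reference, F, cfg)
        r2 = align_read(read2, index, reference, F, cfg)
        _pair_fields(r1, r2, proper=False)
        return r1, r2

    variant = cfg.embedding
    ereads: dict[tuple[int, str], str] = {}

    def dist(which: int, seq: str, c: Candidate) -> int:
        if c.embed_dist is None:
            key = (which, c.strand)
            er = ereads.get(key)
            if er is None:
                er = embed(_oriented(seq, c.strand), F, variant)
                ereads[key] = er
            window = reference.window(c.pos, len(seq))
            c.embed_dist = embedding_distance(er, window, F, variant, None)
        return c.embed_dist

    best_pair = None
    best_key = None
    for c1, c2 in pairs:
        d = dist(1, seq1, c1) + dist(2, seq2, c2)
        key = (d, c1.pos, c2.pos, 0 if c1.strand == "+" else 1)
        if best_key is None or key < best_key:
            best_key, best_pair = key, (c1, c2)
    c1, c2 = best_pair

    def runner_up(which: int, seq: str, sets, winner: Candidate):
        second, skey = None, None
        for cs in sets.values():
            for c in cs.candidates:
                if c is winner:
                    continue
                d = dist(which, seq, c)
                key = (d, -c.votes, c.pos, 0 if c.strand == "+" else 1)
                if skey is None or key < skey:
                    skey, second = key, c
        return second

    s1 = runner_up(1, seq1, sets1, c1)
    s2 = runner_up(2, seq2, sets2, c2)
    r1 = _finalize(read1, c1, s1, reference, F, cfg)
    r2 = _finalize(read2, c2, s2, reference, F, cfg)
    _pair_fields(r1, r2, proper=True)
    return r1, r2
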