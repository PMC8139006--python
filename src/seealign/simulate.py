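"""Synthetic references, error-bearing reads with ground truth, mapping
evaluation, and embedding-distortion measurement.

The simulator emulates an Illumina-like error profile at the level this
aligner exercises: i.i.d. uniform reference bases, uniform read placement
and strand, per-base substitutions, geometrically distributed INDELs, and
Normal paired-end insert sizes.  It records, before error injection, the
exact origin window of every read, which drives the "reported alignment
overlaps the true one by at least 10% of read length" correctness metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import edlib
import numpy as np

from .embedding import EmbeddingFunctions, embed, hamming_embedded
from .index import revcomp
from .pipeline import Read

BASES = "ACGT"
_SLACK = 24  # extra window bases so deletions cannot run out of template


@dataclass
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    mate: int
    ref_name: str
    pos: int  # 0-based start of the originating window
    strand: str
    edits: list = field(default_factory=list)  # (op, window offset, payload)


@dataclass
class DistortionReport:
    n_pairs: int
    max_edits: int
    fraction_ge1: float  # share of pairs with d_H / d_E >= 1
    mean_distortion: float


def simulate_reference(length: int, seed: int) -> str:
    """I.i.d. uniform A/C/G/T string; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _random_bases(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate(window: str, read_len: int, sub_rate: float, indel_rate: float, rng):
    """Inject errors into ``window`` left to right; returns (read, edits).

    At each template position an INDEL starts with probability
    ``indel_rate`` (insertion or deletion equally likely, geometric length
    with p=0.7); surviving bases substitute with probability ``sub_rate``.
    """
    out: list[str] = []
    edits: list[tuple] = []
    j = 0
    while len(out) < read_len:
        if j >= len(window):
            pad = _random_bases(rng, read_len - len(out))
            edits.append(("I", j, pad))
            out.extend(pad)
            break
        if indel_rate > 0 and rng.random() < indel_rate:
            glen = int(rng.geometric(0.7))
            if rng.random() < 0.5:
                ins = _random_bases(rng, glen)
                edits.append(("I", j, ins))
                out.extend(ins)
            else:
                edits.append(("D", j, glen))
                j += glen
                continue
        if len(out) >= read_len:
            break
        ch = window[j]
        if sub_rate > 0 and rng.random() < sub_rate:
            ch = BASES[(BASES.index(ch) + 1 + int(rng.integers(0, 3))) % 4]
            edits.append(("S", j, ch))
        out.append(ch)
        j += 1
    return "".join(out[:read_len]), edits


def apply_edits(window: str, edits: list, read_len: int) -> str:
    """Replay a truth record's edits against its origin window, reproducing
    the simulated read (pre strand flip)."""
    out: list[str] = []
    j = 0
    qi = 0
    q = list(edits)
    while len(out) < read_len and j < len(window):
        if qi < len(q) and q[qi][1] == j and q[qi][0] == "D":
            j += q[qi][2]
            qi += 1
            continue
        if qi < len(q) and q[qi][1] == j and q[qi][0] == "I":
            out.extend(q[qi][2])
            qi += 1
            continue
        ch = window[j]
        if qi < len(q) and q[qi][1] == j and q[qi][0] == "S":
            ch = q[qi][2]
            qi += 1
        out.append(ch)
        j += 1
    while qi < len(q) and len(out) < read_len:
        if q[qi][0] == "I":
            out.extend(q[qi][2])
        qi += 1
    return "".join(out[:read_len])


def simulate_reads(
    reference: str,
    n: int,
    read_len: int = 100,
    sub_rate: float = 0.01,
    indel_rate: float = 0.001,
    paired: bool = False,
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    seed: int = 0,
    ref_name: str = "sim_ref",
) -> tuple[list[Read], list[TruthRecord]]:
    """Draw ``n`` fragments (``n`` reads single-end, ``2n`` paired) from
    ``reference`` with substitution/INDEL errors and ground truth."""
    if read_len > len(reference):
        raise ValueError("read_len exceeds reference length")
    if not (0 <= sub_rate < 0.5 and 0 <= indel_rate < 0.5):
        raise ValueError("error rates must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    ref_len = len(reference)
    span = read_len + _SLACK
    reads: list[Read] = []
    truth: list[TruthRecord] = []
    qual = "I" * read_len

    def one_read(name: str, mate: int, pos: int, strand: str):
        window = reference[pos : pos + span]
        seq, edits = _mutate(window, read_len, sub_rate, indel_rate, rng)
        if strand == "-":
            seq = revcomp(seq)
        reads.append(Read(id=name, seq=seq, qual=qual, mate=mate))
        truth.append(TruthRecord(name, mate, ref_name, pos, strand, edits))

    if paired:
        max_insert = ref_len - _SLACK
        for i in range(n):
            insert = int(np.clip(round(rng.normal(insert_mean, insert_sd)),
                                 read_len, max_insert))
            p1 = int(rng.integers(0, ref_len - insert - _SLACK + 1))
            p2 = p1 + insert - read_len
            name = f"sim{i}"
            one_read(name, 1, p1, "+")
            one_read(name, 2, p2, "-")
    else:
        hi = ref_len - span
        for i in range(n):
            pos = int(rng.integers(0, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            one_read(f"sim{i}", 0, pos, strand)
    return reads, truth


def write_truth(truth: list[TruthRecord], path) -> None:
    """Tab-separated truth table: read_id, mate, ref, pos, strand, edits."""
    with open(path, "w") as fh:
        fh.write("#read_id\tmate\tref_name\tpos\tstrand\tedits\n")
        for t in truth:
            ed = json.dumps([[op, off, payload] for op, off, payload in t.edits])
            fh.write(f"{t.read_id}\t{t.mate}\t{t.ref_name}\t{t.pos}\t{t.strand}\t{ed}\n")


def read_truth(path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rid, mate, rname, pos, strand, ed = line.rstrip("\n").split("\t")
            edits = [(op, off, payload) for op, off, payload in json.loads(ed)]
            out.append(TruthRecord(rid, int(mate), rname, int(pos), strand, edits))
    return out


def evaluate_mappings(results, truth: list[TruthRecord], read_len: int) -> dict:
    """Correct-mapping and unmapped fractions under the >=10%-overlap rule.

    ``results`` is an iterable of objects with read_id/mate/mapped/ref_name/
    pos/ref_span attributes (one per truth record).  A read counts as
    correctly mapped when its reported reference interval overlaps the true
    origin interval by at least 0.1·read_len bases (boundary inclusive).
    """
    tmap = {(t.read_id, t.mate): t for t in truth}
    if not tmap:
        raise ValueError("empty truth set")
    n = correct = unmapped = 0
    seen = set()
    for r in results:
        key = (r.read_id, r.mate)
        t = tmap.get(key)
        if t is None:
            raise ValueError(f"result {key} has no truth record")
        if key in seen:
            continue  # primary records only
        seen.add(key)
        n += 1
        if not r.mapped:
            unmapped += 1
            continue
        if r.ref_name != t.ref_name:
            continue
        span = r.ref_span if r.ref_span else read_len
        overlap = min(r.pos + span, t.pos + read_len) - max(r.pos, t.pos)
        if overlap >= 0.1 * read_len:
            correct += 1
    if n != len(tmap):
        raise ValueError(f"{len(tmap) - n} truth records had no result")
    return {
        "n_reads": n,
        "correctly_mapped": correct / n,
        "unmapped": unmapped / n,
    }


def edit_distance(a: str, b: str) -> int:
    """Exact (unit-cost) Levenshtein distance."""
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


def _random_edits(x: str, n_edits: int, rng) -> str:
    y = list(x)
    for _ in range(n_edits):
        op = rng.integers(0, 3)
        if op == 0 and y:  # substitution
            i = int(rng.integers(0, len(y)))
            y[i] = BASES[(BASES.index(y[i]) + 1 + int(rng.integers(0, 3))) % 4]
        elif op == 1:  # insertion
            i = int(rng.integers(0, len(y) + 1))
            y.insert(i, BASES[int(rng.integers(0, 4))])
        elif y:  # deletion
            i = int(rng.integers(0, len(y)))
            del y[i]
    return "".join(y)


def measure_distortion(
    n_pairs: int,
    str_len: int,
    max_edits: int,
    variant: str = "3n",
    rng_seed: int = 1729,
) -> DistortionReport:
    """Empirical distortion d_H(f(x), f(y)) / d_E(x, y) over random pairs.

    x is uniform random of ``str_len``; y applies 1..``max_edits`` random
    edits to x.  Pairs with exact edit distance 0 are regenerated (the
    applied edit count only upper-bounds the distance).  One shared bit
    table embeds every string.
    """
    if n_pairs < 1 or max_edits < 1:
        raise ValueError("n_pairs and max_edits must be >= 1")
    rng = np.random.default_rng(rng_seed)
    F = EmbeddingFunctions(rng_seed=rng_seed, max_len=str_len + max_edits + 8)
    n_ge1 = 0
    total = 0.0
    for _ in range(n_pairs):
        while True:
            x = _random_bases(rng, str_len)
            e = int(rng.integers(1, max_edits + 1))
            y = _random_edits(x, e, rng)
            de = edit_distance(x, y)
            if de > 0:
                break
        dh = hamming_embedded(embed(x, F, variant), embed(y, F, variant))
        D = dh / de
        n_ge1 += D >= 1.0
        total += D
    return DistortionReport(
        n_pairs=n_pairs,
        max_edits=max_edits,
        fraction_ge1=n_ge1 / n_pairs,
        mean_distortion=total / n_pairs,
    )
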