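"""Reference k-mer hash index.

The index is a chained hash table flattened into two arrays:

* ``key_prefix`` — M+1 cumulative counts (32-bit), ``key_prefix[K]`` being
  the number of stored positions whose key is smaller than ``K``;
* ``positions`` — every encodable k-mer start offset in the reference,
  grouped by key in ascending key order and sorted ascending within a key.

The positions for key ``K`` therefore occupy
``positions[key_prefix[K] : key_prefix[K+1]]``.  Keys are the 2-bit packed
64-bit k-mer codes reduced modulo a prime bucket count, so distinct k-mers
may share a key; the embedding stage resolves such collisions.
"""

from __future__ import annotations

import struct
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .config import Config

MAGIC = b"SEEIDX1\x00"

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# byte -> 2-bit base code, 4 for anything that is not an upper-case A/C/G/T
_BYTE_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _BYTE_CODE[ord(_b)] = _c

# uppercase and squash unknown characters to N
_NORM = bytes(
    (ord("N") if chr(c).upper() not in "ACGTN" else ord(chr(c).upper()))
    for c in range(256)
)

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_RC)[::-1]


class UnencodableKmerError(ValueError):
    """A k-mer contains a character outside {A, C, G, T} (e.g. N)."""


def encode_kmer(seq: str) -> int:
    """Pack a k-mer into a 64-bit integer, 2 bits per base, first base in
    the most significant bit pair (A=00, C=01, G=10, T=11)."""
    code = 0
    for ch in seq:
        b = _BASE_CODE.get(ch)
        if b is None:
            raise UnencodableKmerError(f"k-mer {seq!r} contains non-ACGT character {ch!r}")
        code = (code << 2) | b
    return code


def hash_key(code: int, buckets: int) -> int:
    """Modulo hash of a 64-bit k-mer code into one of ``buckets`` keys."""
    return code % buckets


class Reference:
    """A (possibly multi-record) reference genome in one coordinate space.

    Records are concatenated; ``starts``/``lengths`` record where each named
    sequence lives so global offsets convert back to per-sequence SAM
    coordinates.  Bases are uppercased and anything outside {A,C,G,T,N}
    becomes N.  k-mers never span two records (the index builder works
    record by record).
    """

    def __init__(self, records):
        names, seqs, starts, lengths = [], [], [], []
        pos = 0
        for name, seq in records:
            norm = seq.encode("ascii", errors="replace").translate(_NORM).decode("ascii")
            names.append(name)
            seqs.append(norm)
            starts.append(pos)
            lengths.append(len(norm))
            pos += len(norm)
        self.names = names
        self.starts = starts
        self.lengths = lengths
        self.seq = "".join(seqs)

    @classmethod
    def from_fasta(cls, path) -> "Reference":
        from .seqio import read_fasta

        return cls(read_fasta(path))

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def seq_table(self):
        return list(zip(self.names, self.starts, self.lengths))

    def locate(self, pos: int):
        """Global offset -> (record index, record name, local 0-based offset)."""
        if not (0 <= pos < len(self.seq)):
            raise IndexError(f"position {pos} outside reference of length {len(self.seq)}")
        i = bisect_right(self.starts, pos) - 1
        return i, self.names[i], pos - self.starts[i]

    def record_bounds(self, pos: int):
        """(start, end) global bounds of the record containing ``pos``."""
        i = bisect_right(self.starts, pos) - 1
        return self.starts[i], self.starts[i] + self.lengths[i]

    def window(self, pos: int, length: int) -> str:
        """Slice of up to ``length`` bases starting at ``pos``, clamped to
        the containing record (never spans a record boundary)."""
        lo, hi = self.record_bounds(pos)
        return self.seq[max(pos, lo) : min(pos + length, hi)]


@dataclass
class ReferenceIndex:
    """Flat-array k-mer hash index (see module docstring for the layout)."""

    k: int
    buckets: int
    ref_len: int
    key_prefix: np.ndarray  # uint32, length buckets+1
    positions: np.ndarray  # uint32, grouped by key, sorted within key
    seq_table: list = field(default_factory=list)

    def __eq__(self, other):
        return (
            isinstance(other, ReferenceIndex)
            and self.k == other.k
            and self.buckets == other.buckets
            and self.ref_len == other.ref_len
            and np.array_equal(self.key_prefix, other.key_prefix)
            and np.array_equal(self.positions, other.positions)
            and self.seq_table == other.seq_table
        )


def _record_kmer_positions(seq: str, k: int, chunk: int = 1 << 18):
    """Vectorised scan of one record: (start offsets, 64-bit codes) of every
    k-mer made only of A/C/G/T."""
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes2 = _BYTE_CODE[b]
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    pos_out, code_out = [], []
    for lo in range(0, n - k + 1, chunk):
        hi = min(lo + chunk, n - k + 1)
        win = np.lib.stride_tricks.sliding_window_view(codes2[lo : hi + k - 1], k)
        valid = (win < 4).all(axis=1)
        if not valid.any():
            continue
        vw = win[valid].astype(np.uint64)
        codes = (vw * powers).sum(axis=1, dtype=np.uint64)
        pos_out.append(np.nonzero(valid)[0].astype(np.int64) + lo)
        code_out.append(codes)
    if not pos_out:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    return np.concatenate(pos_out), np.concatenate(code_out)


def build_index(reference, cfg: Config) -> ReferenceIndex:
    """Index every encodable k-mer start position of ``reference``.

    ``reference`` may be a :class:`Reference` or a plain DNA string (treated
    as one record named "ref").  A reference shorter than k yields an empty
    index.
    """
    if isinstance(reference, str):
        reference = Reference([("ref", reference)])
    k, M = cfg.k, cfg.buckets
    all_pos, all_keys = [], []
    for name, start, length in reference.seq_table:
        seq = reference.seq[start : start + length]
        pos, codes = _record_kmer_positions(seq, k)
        if len(pos):
            all_pos.append(pos + start)
            all_keys.append(codes % np.uint64(M))
    if all_pos:
        positions = np.concatenate(all_pos)
        keys = np.concatenate(all_keys)
        order = np.lexsort((positions, keys))
        positions = positions[order].astype(np.uint32)
        keys_sorted = keys[order]
        uniq, counts = np.unique(keys_sorted, return_counts=True)
        key_prefix = np.zeros(M + 1, dtype=np.uint32)
        key_prefix[uniq.astype(np.int64) + 1] = counts.astype(np.uint32)
        key_prefix = np.cumsum(key_prefix, dtype=np.uint32)
    else:
        positions = np.empty(0, dtype=np.uint32)
        key_prefix = np.zeros(M + 1, dtype=np.uint32)
    return ReferenceIndex(
        k=k,
        buckets=M,
        ref_len=len(reference),
        key_prefix=key_prefix,
        positions=positions,
        seq_table=reference.seq_table,
    )


def lookup(index: ReferenceIndex, code: int) -> np.ndarray:
    """Sorted run of reference positions stored under the key of ``code``.

    Hash collisions mean the run may also contain positions of other k-mers
    sharing the key; the embedding stage resolves them.
    """
    key = hash_key(code, index.buckets)
    lo = int(index.key_prefix[key])
    hi = int(index.key_prefix[key + 1])
    return index.positions[lo:hi]


class IndexFormatError(ValueError):
    """The on-disk index file is not a valid SEE index."""


def serialize_index(index: ReferenceIndex, path) -> None:
    """Write the index in the little-endian flat binary layout:
    magic, u32 k, u32 M, u32 ref_len, u32 sequence-table block length,
    the block, key_prefix (M+1 u32), positions (u32 run)."""
    table = bytearray(struct.pack("<I", len(index.seq_table)))
    for name, start, length in index.seq_table:
        nb = name.encode("utf-8")
        table += struct.pack("<I", len(nb)) + nb + struct.pack("<II", start, length)
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<III", index.k, index.buckets, index.ref_len))
        fh.write(struct.pack("<I", len(table)))
        fh.write(table)
        fh.write(index.key_prefix.astype("<u4").tobytes())
        fh.write(index.positions.astype("<u4").tobytes())


def deserialize_index(path) -> ReferenceIndex:
    """Read an index written by :func:`serialize_index` (round-trip exact)."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[: len(MAGIC)] != MAGIC:
        raise IndexFormatError(f"{path}: not a SEE index (bad magic bytes)")
    off = len(MAGIC)

    def take(n):
        nonlocal off
        if off + n > len(data):
            raise IndexFormatError(f"{path}: truncated index file")
        chunk = data[off : off + n]
        off += n
        return chunk

    k, buckets, ref_len = struct.unpack("<III", take(12))
    (table_len,) = struct.unpack("<I", take(4))
    table_bytes = take(table_len)
    toff = 0
    (n_seqs,) = struct.unpack_from("<I", table_bytes, toff)
    toff += 4
    seq_table = []
    for _ in range(n_seqs):
        (name_len,) = struct.unpack_from("<I", table_bytes, toff)
        toff += 4
        name = table_bytes[toff : toff + name_len].decode("utf-8")
        toff += name_len
        start, length = struct.unpack_from("<II", table_bytes, toff)
        toff += 8
        seq_table.append((name, start, length))
    key_prefix = np.frombuffer(take(4 * (buckets + 1)), dtype="<u4").copy()
    n_positions = int(key_prefix[-1])
    positions = np.frombuffer(take(4 * n_positions), dtype="<u4").copy()
    if off != len(data):
        raise IndexFormatError(f"{path}: trailing bytes after index payload")
    return ReferenceIndex(
        k=k,
        buckets=buckets,
        ref_len=ref_len,
        key_prefix=key_prefix,
        positions=positions,
        seq_table=seq_table,
    )
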