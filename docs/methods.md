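# Methods

`seealign` is a short-read mapper/aligner built on the *seed–embed–extend*
strategy: instead of filtering candidate locations and paying for an
edit-distance extension at each survivor, it ranks **all** candidates by a
cheap Hamming-space proxy for edit distance and extends only the winner.

## Model and procedure

**Index.** The reference genome (one concatenated coordinate space over all
FASTA records, with a name/start/length table for SAM conversion) is scanned
at every position for k-mers (default k = 32, so a k-mer packs into one
64-bit integer at 2 bits/base; k-mers containing N, or spanning a record
boundary, are skipped). Each k-mer code is hashed by `code mod M` into one
of M buckets, M a prime below 2³². The index is two flat 32-bit arrays: a
cumulative-count key array of M+1 entries and a position array grouped by
key and sorted within each key, so key K's postings are
`positions[key_prefix[K] : key_prefix[K+1]]`. Distinct k-mers may share a
key; such collisions are tolerated and resolved downstream by embedding.

**Seeding.** Each read (and its reverse complement, which competes on equal
terms) is cut into non-overlapping k-mers. Every index hit is normalized by
subtracting the seed's offset in the read; negative normalized positions are
dropped. The per-seed sorted runs are merged duplicate-free with a
min-priority queue in O(N_l) heap operations (N_l = total candidates),
recording per-position *votes* — the number of seeds that produced the
position. Nothing is filtered. If every seed of an orientation yields zero
hits, the whole seed frame is shifted by one base and re-tried, up to shift
k−1.

**Embedding.** A randomized one-to-one transform maps strings from the edit
regime into the Hamming regime. Two variants, both driven by one random bit
table r(i, c) built once per run from `rng_seed`:

* **3N**: walk output index i with input cursor j; emit x[j] (pad `P` after
  the input is exhausted) and advance j when r(i, x[j]) = 1; output length
  exactly 3N.
* **2N** (default): emit each x[j] once, and once more when r(j, x[j]) = 1;
  pad to 2N.

With edit distance d_E(x, y) < K, the Hamming distance of the embedded
strings stays within a small factor of d_E with high probability
(empirically, distortion d_H/d_E ≥ 1 in ≥ 99% of random pairs — recomputed
by `scripts/acceptance.py`). Embedded strings of unequal length are
compared after conceptually pad-extending the shorter one (pad matches only
pad); reference windows clamped at a record edge therefore pay one mismatch
per missing base.

**Candidate selection.** The read is embedded once per orientation; each
candidate's reference window is embedded character by character, updating
the running Hamming distance (*pipelining*) and abandoning the candidate as
soon as it exceeds the current second-best distance (*early-stop*, sentinel
value threshold+1). Candidates are visited in descending vote order
(*prioritizing*), which tightens the threshold sooner. The top-2 bookkeeping
uses the order-independent comparator (distance, −votes, position, forward
strand first); because a candidate early-stops only when strictly worse
than the incumbent second, the selected pair and its distances are provably
identical to naive full embedding — the test suite asserts this.

**Rectification.** An INDEL ahead of the seed that produced the winning
candidate shifts its normalized position by the net INDEL length. The
read's first k-mer is embedded and compared to reference k-mers starting at
every s in [P−l, P+l], l = max(1, round(0.05·read_len)); the
minimum-distance start wins (ties: smallest |s−P|, then smallest s).

**Extension.** In `align` mode the full read is aligned end-to-end against
the reference window `[P, P + read_len + l)` by affine-gap dynamic
programming with match +1, mismatch −4, gap open 6, gap extend 1 (a gap of
length g costs 6 + g; BWA-MEM's convention). Window flanks are free
(fitting alignment): pure global alignment of a read against a longer
window would force spurious end gaps, and the free flanks are what absorb
the net INDEL drift the slack exists for. CIGAR uses M/I/D only — no soft
clipping or local alignment. Tie-breaks are fixed (M over D over I per
cell, gap close over extend, leftmost end column), making CIGARs
deterministic; scores are tie-invariant. The DP is row-vectorized in
numpy; the horizontal gap state is computed by a prefix maximum, which is
exact because re-opening a gap out of a gap state never beats extending
it. In `map` mode the rectified position is reported with CIGAR `*`.

**MAPQ.** Bowtie2's idea — confidence from best-hit quality and the margin
to the runner-up — recast as a closed form so results are reproducible
without replicating Bowtie2's internal threshold table:

    s1 = 1 − d₁/L_e,  diff = (d₂ − d₁)/L_e,
    MAPQ = round(42·s1·min(1, 2·diff)) ∈ [0, 42]

with L_e the embedded length (2·read_len or 3·read_len) and d₁ ≤ d₂ the
top-two embedding distances (d₂ = L_e for unique hits). The form is
monotone in both arguments, hits 42 for perfect unique hits and 0 for
ties. In `--mapq-mode score` both top candidates are extended and
pseudo-distances dᵢ = read_len·match − scoreᵢ with normalizer
Z = read_len·(match+mismatch) replace the embedding quantities. Because
embedding distance overstates edit distance, the default mode is the more
conservative of the two, consistent with the method's design.

**Paired ends.** Candidate pairs (FR orientation) within `pair_dist`
(default 1000 bp) found by a linear two-pointer sweep are scored jointly by
the sum of the two embedding distances; the winning pair sets the
proper-pair flag. With no qualifying pair, each mate is aligned
independently and the flag stays clear (no mate rescue). When the joint
choice promotes a mate candidate that is locally worse than its runner-up,
the margin is treated as zero (MAPQ 0) rather than negative.

**No-embed ablation.** `--embedding none` forwards every candidate straight
to extension; the best alignment score wins and MAPQ comes from scores.
This isolates the contribution of embedding exactly as the method's
ablation study does.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `k` | 32 | seed length (bases); 4–32 so a seed fits 64 bits |
| `buckets` (M) | 1,073,741,789 | hash buckets; prime < 2³². The default sizes a whole-genome run; desk-scale runs should pass a prime giving load factor ≲ 1/10 (tests use 2²⁴−3 for 10⁵–10⁶ bp references), since a high collision rate creates spurious candidates that suppress the shift-retry rule |
| `pair_dist` | 1000 bp | max separation of paired candidates |
| `l_frac` | 0.05 | INDEL allowance as fraction of read length; sets the rectification scan radius and extension window slack |
| `match/mismatch/gap_open/gap_ext` | 1/4/6/1 | affine scoring |
| `embedding` | `2n` | `2n`, `3n`, or `none` |
| `rng_seed` | 1729 | seed of the shared embedding bit table; identical seeds give byte-identical SAM output |
| `mapq_mode` | `embed` | `embed` or `score` |
| `mode` | `align` | `align` (CIGAR) or `map` (position only) |

## Synthetic data

`seealign.simulate` stands in for a full read simulator: i.i.d. uniform
references; uniform fragment placement and strand; per-base substitutions
(default 1%); per-base INDEL initiation (default 0.1%) with geometric
lengths (p = 0.7, mean ≈ 1.4 bp); paired inserts ~ Normal(350, 50) bp,
mates FR; constant `I` qualities. Ground truth (origin window, strand, and
the exact edit list) is recorded before error injection, and replaying the
edit list reproduces each read exactly (tested). It does **not** model
position-dependent quality, GC bias, adapter read-through, repeat structure
of real genomes, or known-variant (VCF-driven) divergence — so passing the
recovery tests demonstrates correctness of the machinery on this error
model, not genome-scale accuracy on real data.

## Numerical and scale choices

* Test/benchmark problem sizes: 1 Mb reference, 10,000 paired 100 bp reads
  (1% sub, 0.1% INDEL) for end-to-end recovery; 10,000 mixed
  unique/repetitive/garbage reads for the MAPQ stress suite; 1,000 pairs of
  100-nt strings with 1–10 edits for distortion. These exercise every code
  path at interpreted-Python-friendly scale.
* The distortion denominator is the exact edit distance (edlib), not the
  number of applied edits, which only upper-bounds it; pairs at distance 0
  are regenerated.
* DP scores use int64 with a large negative sentinel; no floating point in
  alignment. MAPQ rounding is half-up.
* Reads shorter than k are reported unmapped; a read whose candidates all
  normalize negative or whose seeds never hit is unmapped. Windows past a
  record end are clamped and the missing tail counts as mismatches.

## Known limitations

* No soft clipping / local alignment; reads overhanging a contig edge pay
  mismatches rather than clipping.
* No mate rescue; an unpaired mate falls back to single-end placement.
* A single hash-collision hit can satisfy the "any candidate found" test
  and suppress shift-retry; at sensible load factors this is rare, and it
  mirrors the method's design (collisions are resolved by embedding, and
  essentially every read is reported mapped, possibly at MAPQ 0).
* Single-threaded by design.
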