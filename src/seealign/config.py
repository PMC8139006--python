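"""Validated run configuration.

Every tunable of the aligner lives in one immutable :class:`Config` object
that is created once (from defaults, a ``key=value`` config file, and/or
command-line flags) and passed read-only to every stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import sympy

#: Default number of hash buckets: a prime just below 2^30, sized for a
#: whole-genome key array of 32-bit cumulative counts.  Desk-scale runs
#: (tests, simulations) pass much smaller primes explicitly.
DEFAULT_BUCKETS = 1_073_741_789

EMBEDDING_VARIANTS = ("2n", "3n", "none")
MAPQ_MODES = ("embed", "score")
RUN_MODES = ("map", "align")


@dataclass(frozen=True)
class Config:
    """Aligner configuration.

    Attributes
    ----------
    k:
        Seed (k-mer) length in bases.  Must lie in [4, 32] so a k-mer packs
        into one 64-bit unsigned integer at 2 bits per base.
    buckets:
        Number of hash buckets ``M``; a prime that fits a 32-bit unsigned
        integer.  The modulo hash maps 64-bit k-mer codes onto [0, M).
    pair_dist:
        Maximum separation (bases) between paired-end candidate positions.
    l_frac:
        INDEL drift allowance as a fraction of read length; drives position
        rectification (scan window P±l) and the extension window slack.
    match, mismatch, gap_open, gap_ext:
        Affine-gap scoring: a gap of length g costs ``gap_open + g*gap_ext``;
        defaults 1/4/6/1 follow the BWA-MEM convention.
    embedding:
        Which randomized embedding ranks candidates: "2n", "3n", or "none"
        (ablation: every candidate goes straight to extension).
    rng_seed:
        Seed for the shared random bit table behind the embeddings.
    mapq_mode:
        "embed" derives MAPQ from the top-two embedding distances; "score"
        extends both top candidates and uses alignment scores.
    mode:
        "align" reports base-level CIGAR alignments; "map" reports the
        candidate position only (extension-free).
    """

    k: int = 32
    buckets: int = DEFAULT_BUCKETS
    pair_dist: int = 1000
    l_frac: float = 0.05
    match: int = 1
    mismatch: int = 4
    gap_open: int = 6
    gap_ext: int = 1
    embedding: str = "2n"
    rng_seed: int = 1729
    mapq_mode: str = "embed"
    mode: str = "align"

    def gap_cost(self, length: int) -> int:
        """Cost of a gap of ``length`` bases (positive number)."""
        return self.gap_open + length * self.gap_ext

    @property
    def indel_slack(self) -> float:
        return self.l_frac


class ConfigError(ValueError):
    """Raised when a configuration violates an invariant."""


def validate_config(cfg: Config) -> Config:
    """Check every invariant of ``cfg`` and return it unchanged.

    Idempotent; raises :class:`ConfigError` on the first violation.
    """
    if not (4 <= cfg.k <= 32):
        raise ConfigError(f"k={cfg.k} outside [4, 32]; a k-mer must fit 64 bits")
    if not (2 <= cfg.buckets <= 2**32 - 1):
        raise ConfigError(f"buckets={cfg.buckets} must fit a 32-bit unsigned integer")
    if not sympy.isprime(cfg.buckets):
        raise ConfigError(f"buckets={cfg.buckets} is not prime")
    for name in ("match", "mismatch", "gap_open", "gap_ext"):
        v = getattr(cfg, name)
        if not isinstance(v, int) or v < 0:
            raise ConfigError(f"{name}={v!r} must be a non-negative integer")
    if not (0.0 < cfg.l_frac < 1.0):
        raise ConfigError(f"l_frac={cfg.l_frac} outside (0, 1)")
    if cfg.pair_dist < 0:
        raise ConfigError(f"pair_dist={cfg.pair_dist} must be non-negative")
    if cfg.embedding not in EMBEDDING_VARIANTS:
        raise ConfigError(f"embedding={cfg.embedding!r} not one of {EMBEDDING_VARIANTS}")
    if cfg.mapq_mode not in MAPQ_MODES:
        raise ConfigError(f"mapq_mode={cfg.mapq_mode!r} not one of {MAPQ_MODES}")
    if cfg.mode not in RUN_MODES:
        raise ConfigError(f"mode={cfg.mode!r} not one of {RUN_MODES}")
    return cfg


_INT_FIELDS = {"k", "buckets", "pair_dist", "match", "mismatch", "gap_open",
               "gap_ext", "rng_seed"}
_FLOAT_FIELDS = {"l_frac"}
_FIELD_NAMES = {f.name for f in dataclasses.fields(Config)}


def load_config_file(path) -> dict:
    """Parse a ``key=value``-per-line config file into a field dict.

    Blank lines and ``#`` comments are ignored; unknown keys are rejected.
    """
    values: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in _FIELD_NAMES:
                raise ConfigError(f"{path}:{lineno}: unknown option {key!r}")
            if key in _INT_FIELDS:
                values[key] = int(val)
            elif key in _FLOAT_FIELDS:
                values[key] = float(val)
            else:
                values[key] = val
    return values


def make_config(file_values: dict | None = None, **overrides) -> Config:
    """Build and validate a Config from file values and explicit overrides.

    ``overrides`` entries that are ``None`` are treated as unset, so CLI
    flags override the file only when the user actually passed them.
    """
    merged = dict(file_values or {})
    merged.update({k: v for k, v in overrides.items() if v is not None})
    return validate_config(Config(**merged))
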