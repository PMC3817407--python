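"""Low-level DNA utilities used throughout the package.

Sequences are plain upper-case strings over {A,C,G,T} (N tolerated only in
genome context). Integer encodings follow the fixed base order A,C,G,T.
"""
from __future__ import annotations

import hashlib

import numpy as np

from .errors import ValidationError

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def validate_dna(seq: str, *, allow_n: bool = False, context: str = "sequence") -> str:
    """Upper-case ``seq`` and reject characters outside the DNA alphabet."""
    seq = seq.upper()
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValidationError(
            f"{context}: illegal character(s) {sorted(bad)} (allowed: {sorted(allowed)})"
        )
    return seq


def encode(seq: str) -> np.ndarray:
    """Integer-encode a DNA string (A=0, C=1, G=2, T=3). Rejects N."""
    try:
        return np.fromiter((BASE_INDEX[b] for b in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValidationError(f"ambiguous or illegal base {exc.args[0]!r} in sequence") from None


def decode(idx) -> str:
    return "".join(BASES[i] for i in idx)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(1 for b in seq if b in "AT") / len(seq)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. random DNA at the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p))


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive a named, reproducible random substream from one global seed.

    Stage-level substreams let partial pipeline reruns reproduce the same
    data per stage. The stage name is hashed stably (sha256, not Python's
    salted hash).
    """
    digest = hashlib.sha256(name.encode()).digest()
    child = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), child]))
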