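"""Small sequence helpers shared across modules.

All pipeline-internal sequences use the DNA alphabet (ACGT), matching what a
sequencer emits; the duplex-energy module converts to RNA at its boundary.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space (U treated as T)."""
    return seq.translate(_COMP)[::-1]


def to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random sequence with a target GC fraction."""
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    return "".join(rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at]))


def encode(seq: str) -> np.ndarray:
    """Encode ACGT(U) to uint8 codes 0..3; anything else becomes 4 (N)."""
    table = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    table[ord("U")] = 3
    table[ord("u")] = 3
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
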