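"""Small sequence utilities shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Byte-encode a DNA string for vectorized comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def validate_dna(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{name} is empty")
    if set(seq.upper()) - set("ACGTN"):
        bad = sorted(set(seq.upper()) - set("ACGTN"))
        raise ValueError(f"{name} contains non-DNA characters: {bad}")
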