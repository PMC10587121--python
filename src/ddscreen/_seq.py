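"""Small shared sequence utilities (DNA validation, encoding, complements)."""

from __future__ import annotations

import numpy as np

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte -> base index (A=0, C=1, G=2, T=3, anything else=4)
BASE_INDEX = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(DNA_BASES):
    BASE_INDEX[ord(_b)] = _i
    BASE_INDEX[ord(_b.lower())] = _i

INDEX_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> str:
    """Uppercase and check a DNA string over {A, C, G, T}."""
    s = seq.upper()
    if not s:
        raise ValueError(f"{name} must be non-empty")
    bad = set(s) - set(DNA_BASES)
    if bad:
        raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    return s


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 index array (A=0, C=1, G=2, T=3, other=4)."""
    return BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(idx: np.ndarray) -> str:
    """Index array -> DNA string (4 decodes to N)."""
    return INDEX_BASE[idx].tobytes().decode("ascii")
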