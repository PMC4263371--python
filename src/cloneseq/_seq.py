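"""Low-level 2-bit DNA encoding helpers shared by the simulator and mapper."""

from __future__ import annotations

import numpy as np

# A=0 C=1 G=2 T=3; 4 is reserved as a sentinel/padding code
SENTINEL = np.uint8(4)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 code array (A=0 C=1 G=2 T=3)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGTN characters")
    return arr


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def decode_rows(matrix: np.ndarray) -> list[str]:
    """Decode each row of an (n, L) code matrix to a string."""
    chars = _BASES[matrix]
    return [row.tobytes().decode("ascii") for row in chars]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis; sentinel codes are preserved."""
    comp = np.where(codes < 4, 3 - codes, codes)
    return comp[..., ::-1]
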