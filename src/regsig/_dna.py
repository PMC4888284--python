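"""Small DNA helpers shared across modules (encoding, complement)."""

from __future__ import annotations

import numpy as np

# Base order used by every matrix in the package.
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
N_INDEX = 4  # any ambiguous base is treated as N

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN.-acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN.-tgcayrswmkvhdbn",
)

# 0..3 = ACGT, 4 = N/other; lookup table over raw bytes (upper+lower case).
_ENC = np.full(256, N_INDEX, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes 0..4 (4 = N / anything else)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
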