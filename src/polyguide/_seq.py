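"""Nucleotide-string helpers shared across modules.

Sequences are plain Python strings over {A,C,G,T,N}, uppercased on load.
numpy uint8 encodings (A=0, C=1, G=2, T=3, N=4) back the vectorised scan
and Hamming verification paths.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

N_CODE = 4


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes; anything outside ACGT becomes N (4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase and map non-ACGT letters (IUPAC ambiguity codes) to N."""
    up = seq.upper()
    return "".join(c if c in "ACGTN" else "N" for c in up)
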