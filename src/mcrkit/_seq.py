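"""Nucleotide codec shared across modules.

Sequences are stored as python strings over {A,C,G,T,N} and, where speed
matters, as numpy uint8 code arrays with A=0, C=1, G=2, T=3, N=4.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGTN"
CODE = {b: i for i, b in enumerate(BASES)}

# complement in code space; N maps to N
COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANTGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes; raises on other letters."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENC[raw]
    if codes.size and codes.max() == 255:
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"illegal base {seq[bad]!r} at position {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMP_CODE[codes][::-1]
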