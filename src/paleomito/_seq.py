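"""Nucleotide encoding helpers shared across modules.

Bases are encoded as uint8 codes A=0, C=1, G=2, T=3, N=4. N never matches
any base (including another N) in alignment mismatch counts.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement: A<->T, C<->G, N->N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes; raises on illegal characters."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        pos = int(np.argmax(codes == 255))
        raise ValueError(
            f"illegal character {seq[pos]!r} at position {pos + 1} (1-based)"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def complement(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))
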