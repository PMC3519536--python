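"""Low-level nucleotide encoding shared by the simulator and the matcher.

Bases are coded A=0, C=1, G=2, T=3; anything else (including N) is 4 and
never matches any base, itself included.
"""
from __future__ import annotations

import numpy as np

N_CODE = 4

_BASE_TO_CODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
    _BASE_TO_CODE[_b + 32] = _i  # lower case

_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: widest seed key that fits 2 bits/base in uint64; longer segments are keyed
#: by their 32-base prefix and resolved during full-window verification
MAX_KMER = 32


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_TO_CODE[raw]


def decode(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = (3 - codes[::-1]).astype(np.uint8)
    out[codes[::-1] == N_CODE] = N_CODE
    return out


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit pack every length-``k`` window of ``codes``.

    Returns ``(keys, valid)`` where ``keys[i]`` encodes the window starting at
    ``i`` and ``valid[i]`` is False when the window contains an N.  For
    ``k > MAX_KMER`` only the first MAX_KMER bases enter the key (callers must
    verify candidates anyway).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = codes.size - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    k_eff = min(k, MAX_KMER)
    keys = np.zeros(n, dtype=np.uint64)
    safe = np.where(codes == N_CODE, 0, codes).astype(np.uint64)
    for j in range(k_eff):
        keys <<= np.uint64(2)
        keys |= safe[j : j + n]
    is_n = (codes == N_CODE).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cum[k_eff:k_eff + n] - cum[:n]) == 0
    return keys, valid
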