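"""2-bit k-mer encoding, reverse complementation and canonicalization.

Every k-mer (16 <= k <= 32 in the marker database; the counter alone accepts
14-32) is packed into a single ``uint64``: two bits per base, A=0, C=1, G=2,
T=3, most significant bits first.  All identity comparisons in the package --
uniqueness testing against the expanded reference, index lookup, read
counting -- happen in *canonical* space, where a k-mer is represented by the
lexicographic minimum of itself and its reverse complement.  Reads come off
both strands, so without canonicalization counts would halve and uniqueness
testing would be unsound.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BASE_CODES",
    "seq_to_codes",
    "codes_to_seq",
    "encode_kmer",
    "decode_kmer",
    "kmer_codes",
    "encode_kmer_matrix",
    "revcomp_codes",
    "canonical_codes",
    "revcomp_seq",
    "hamming1_neighbor_codes",
]

# byte -> 2-bit code; 4 marks anything that is not A/C/G/T (case-insensitive)
BASE_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODES[_b] = _i
    BASE_CODES[_b + 32] = _i  # lowercase

_CODE_TO_BASE = "ACGT"

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")

_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Map a sequence to its per-base codes (uint8; non-ACGT -> 4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return BASE_CODES[np.frombuffer(seq, dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(_CODE_TO_BASE[c] for c in codes)


def encode_kmer(kmer: str) -> int:
    """Pack one k-mer string into its uint64 code. Raises on non-ACGT."""
    codes = seq_to_codes(kmer)
    if (codes > 3).any():
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_CODE_TO_BASE[(int(code) >> shift) & 3])
    return "".join(out)


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All positional k-mer codes of a base-code array, with validity mask.

    Returns ``(window_codes, valid)`` where ``window_codes[i]`` encodes
    ``codes[i:i+k]`` and ``valid[i]`` is False when the window contains a
    non-ACGT base (those codes are meaningless and must be skipped).
    """
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - k + 1
    base = (codes & np.uint8(3)).astype(np.uint64)
    out = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | base[j : j + m]
    bad = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(codes > 3, out=bad[1:])
    valid = (bad[k:] - bad[:-k]) == 0
    return out, valid


def encode_kmer_matrix(mat: np.ndarray) -> np.ndarray:
    """Encode an (n, k) uint8 base-code matrix into n uint64 codes."""
    k = mat.shape[1]
    weights = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    return (mat.astype(np.uint64) * weights).sum(axis=1, dtype=np.uint64)


def revcomp_codes(codes: np.ndarray | int, k: int) -> np.ndarray | int:
    """Reverse complement of packed k-mer codes (vectorized)."""
    scalar = np.isscalar(codes) or isinstance(codes, (int, np.integer))
    x = np.asarray(codes, dtype=np.uint64)
    x = ~x  # complement: every base code maps to 3 - code
    # reverse the 32 2-bit fields of the 64-bit word
    x = ((x >> np.uint64(2)) & _M2) | ((x & _M2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & _M4) | ((x & _M4) << np.uint64(4))
    x = x.byteswap()
    x = x >> np.uint64(64 - 2 * k)
    return int(x) if scalar else x


def canonical_codes(codes: np.ndarray | int, k: int) -> np.ndarray | int:
    """Canonical form: minimum of a code and its reverse complement."""
    rc = revcomp_codes(codes, k)
    if np.isscalar(codes) or isinstance(codes, (int, np.integer)):
        return min(int(codes), int(rc))
    return np.minimum(np.asarray(codes, dtype=np.uint64), rc)


def revcomp_seq(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming1_neighbor_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """All 3k Hamming-distance-1 neighbors of each code.

    Returns an (n, 3k) uint64 array (non-canonical orientation).
    """
    codes = np.asarray(codes, dtype=np.uint64)
    n = codes.shape[0]
    out = np.empty((n, 3 * k), dtype=np.uint64)
    col = 0
    for pos in range(k):
        shift = np.uint64(2 * (k - 1 - pos))
        for d in (1, 2, 3):  # XOR on the 2-bit field hits the other 3 bases
            out[:, col] = codes ^ (np.uint64(d) << shift)
            col += 1
    return out
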