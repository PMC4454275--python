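"""Small DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def kmers(seq: str, k: int) -> list[str]:
    """All k-mers of ``seq`` containing only ACGT."""
    out = []
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            out.append(km)
    return out


def kmer_set(seq: str, k: int, canonicalize: bool = True) -> set[str]:
    if canonicalize:
        return {canonical(km) for km in kmers(seq, k)}
    return set(kmers(seq, k))


def pack_kmer(km: str) -> int:
    """2-bit packing of a k-mer (A=0, C=1, G=2, T=3), k <= 31."""
    v = 0
    for ch in km:
        v = (v << 2) | _BASE_CODE[ch]
    return v


def pack_kmers_array(seq: str, k: int) -> np.ndarray:
    """2-bit packed values for every k-mer of ``seq`` as a uint64 array.

    Positions whose k-mer contains a non-ACGT character are marked with the
    sentinel ``2**63`` (which never collides with a packed k-mer for k<=31).
    """
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for b, c in _BASE_CODE.items():
        lut[ord(b)] = c
        lut[ord(b.lower())] = c
    vals = lut[codes]
    bad = vals == 255
    vals64 = vals.astype(np.uint64)
    vals64[bad] = 0
    packed = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        packed = (packed << np.uint64(2)) | vals64[j : j + n]
    # flag windows containing any bad base
    badwin = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64), "valid") > 0
    packed[badwin] = np.uint64(1) << np.uint64(63)
    return packed
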