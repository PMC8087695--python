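"""Integer k-mer encoding helpers shared by the placement and variant engines.

Sequences are handled as uint8 code arrays (A=0, C=1, G=2, T=3); k-mers up to
k=31 pack into int64 (2 bits per base). Positions containing non-ACGT bases
yield no k-mer.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as a uint8 array (255 marks non-ACGT)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return bytes(np.array([65, 67, 71, 84, 78], dtype=np.uint8)[
        np.where(codes > 3, 4, codes)]).decode("ascii")


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq.upper()))


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All packed k-mers of a code array.

    Returns (values, positions); positions whose window contains a non-ACGT
    base are dropped. values[i] is the big-endian 2-bit packing of
    codes[positions[i] : positions[i]+k].
    """
    if k > 31:
        raise ValueError("k must be <= 31 for int64 packing")
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        vals = (vals << 2) | np.where(window > 3, 0, window).astype(np.int64)
        bad |= window > 3
    pos = np.nonzero(~bad)[0]
    return vals[pos], pos


class KmerIndex:
    """Sorted k-mer lookup over one or more named sequences.

    Supports multiplicity queries and position retrieval; used for unique-seed
    placement (GMAP-style rescue) and anchor finding.
    """

    def __init__(self, sequences: dict[str, str], k: int):
        self.k = k
        self.names: list[str] = list(sequences)
        vals_all, pos_all, chrom_all = [], [], []
        for ci, name in enumerate(self.names):
            codes = encode(sequences[name])
            vals, pos = kmer_codes(codes, k)
            vals_all.append(vals)
            pos_all.append(pos)
            chrom_all.append(np.full(len(pos), ci, dtype=np.int32))
        vals = np.concatenate(vals_all) if vals_all else np.empty(0, np.int64)
        order = np.argsort(vals, kind="stable")
        self._vals = vals[order]
        self._pos = (np.concatenate(pos_all) if pos_all else np.empty(0, np.int64))[order]
        self._chrom = (np.concatenate(chrom_all) if chrom_all else np.empty(0, np.int32))[order]

    def counts(self, queries: np.ndarray) -> np.ndarray:
        lo = np.searchsorted(self._vals, queries, side="left")
        hi = np.searchsorted(self._vals, queries, side="right")
        return hi - lo

    def lookup_unique(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """For each query k-mer occurring exactly once, its location.

        Returns (query_index, chrom_index, position).
        """
        lo = np.searchsorted(self._vals, queries, side="left")
        hi = np.searchsorted(self._vals, queries, side="right")
        sel = np.nonzero(hi - lo == 1)[0]
        at = lo[sel]
        return sel, self._chrom[at], self._pos[at]
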