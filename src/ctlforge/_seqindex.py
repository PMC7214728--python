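"""Exact-occurrence search over a whole assembly.

A multiplicative rolling hash (mod 2**64, vectorised with numpy) indexes
every window of a given length across the concatenated chromosomes; query
hits are confirmed by direct byte comparison so hash collisions and windows
spanning chromosome boundaries can never produce a false positive.  Per
window-length hash tables are cached, so repeated queries of the same
length (e.g. many 400 bp flanks) cost one binary search each.
"""

from __future__ import annotations

import bisect

import numpy as np

_B = np.uint64(0x9E3779B97F4A7C15)  # odd -> invertible mod 2**64
_B_INV = np.uint64(pow(int(_B), -1, 2**64))

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.encode()[::-1].translate(_COMPLEMENT).decode()


class SequenceIndex:
    """Genome-wide exact substring locator with both-strand counting."""

    def __init__(self, assembly) -> None:
        parts: list[bytes] = []
        self._chrom_offsets: list[int] = []
        self._chrom_names: list[str] = []
        self._chrom_lens: list[int] = []
        cursor = 0
        for name, seq in assembly.sequences.items():
            self._chrom_offsets.append(cursor)
            self._chrom_names.append(name)
            self._chrom_lens.append(len(seq))
            parts.append(seq.encode())
            parts.append(b"\x01")  # separator byte, never matches a query
            cursor += len(seq) + 1
        self._concat = b"".join(parts)
        arr = np.frombuffer(self._concat, dtype=np.uint8).astype(np.uint64)
        n = arr.size
        bpow = np.full(n, _B, dtype=np.uint64)
        bpow[0] = np.uint64(1)
        np.multiply.accumulate(bpow, out=bpow)
        binv = np.full(n, _B_INV, dtype=np.uint64)
        binv[0] = np.uint64(1)
        np.multiply.accumulate(binv, out=binv)
        self._bpow = bpow
        self._binv = binv
        self._prefix = np.cumsum(arr * bpow, dtype=np.uint64)
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _table(self, length: int) -> tuple[np.ndarray, np.ndarray]:
        """Sorted window hashes of a given length with their start offsets."""
        if length not in self._cache:
            n = self._prefix.size
            if length > n:
                empty = np.empty(0, dtype=np.uint64)
                self._cache[length] = (empty, empty.astype(np.int64))
                return self._cache[length]
            h = self._prefix[length - 1 :].copy()
            h[1:] -= self._prefix[: n - length]
            h *= self._binv[: n - length + 1]
            order = np.argsort(h, kind="stable")
            self._cache[length] = (h[order], order.astype(np.int64))
        return self._cache[length]

    def positions(self, query: str) -> list[tuple[str, int]]:
        """Forward-strand exact-match positions, as (chrom, 0-based start)."""
        q = query.encode()
        length = len(q)
        if length == 0:
            raise ValueError("empty query")
        hashes, starts = self._table(length)
        qarr = np.frombuffer(q, dtype=np.uint8).astype(np.uint64)
        qh = np.sum(qarr * self._bpow[:length], dtype=np.uint64)
        lo = int(np.searchsorted(hashes, qh, side="left"))
        hi = int(np.searchsorted(hashes, qh, side="right"))
        out = []
        for off in starts[lo:hi]:
            off = int(off)
            if self._concat[off : off + length] != q:
                continue  # hash collision
            ci = bisect.bisect_right(self._chrom_offsets, off) - 1
            local = off - self._chrom_offsets[ci]
            out.append((self._chrom_names[ci], local))
        out.sort()
        return out

    def count_both_strands(self, query: str) -> int:
        """Occurrences of ``query`` on either strand, deduplicated by locus.

        A palindromic query (its own reverse complement) matches the same
        locus on both strands and is counted once.
        """
        hits = set(self.positions(query))
        hits.update(self.positions(revcomp(query)))
        return len(hits)
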