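"""Test-scale internal read mapper.

Exact k-mer seeding with gapless full-length verification and unique-best
placement.  It exists so the whole pipeline is exercisable on synthetic data
without an external aligner; alignments are emitted in the same record shape
as SAM ingest, so the detection stages are agnostic to provenance.  It is
not a production mapper: no indels, no clipping, no quality awareness.

The seed index packs each k-mer (k <= 32) into a 2-bit-encoded uint64 and
keeps a sorted array of (kmer, contig, position), so lookups are two binary
searches and the index stays a few tens of bytes per contig base.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import Contig, InputError, reverse_complement
from .pe import MateAlignment

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _rolling_kmers(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """(kmers, valid) for every start position; invalid where a non-ACGT base occurs."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (np.uint64(1) << (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)))
    valid = (win != 255).all(axis=1)
    kmers = (win.astype(np.uint64) * powers).sum(axis=1)
    return kmers, valid


class _ContigIndex:
    def __init__(self, contigs: Sequence[Contig], seed_len: int = 31):
        if not 1 <= seed_len <= 32:
            raise InputError("seed_len must be in [1, 32]")
        self.seed_len = seed_len
        self.powers = np.uint64(1) << (
            np.uint64(2) * np.arange(seed_len - 1, -1, -1, dtype=np.uint64)
        )
        self.contigs = list(contigs)
        self.arrays = [np.frombuffer(c.seq.encode(), dtype=np.uint8) for c in contigs]
        kmer_parts, ci_parts, pos_parts = [], [], []
        for ci, c in enumerate(self.contigs):
            kmers, valid = _rolling_kmers(_encode(c.seq), seed_len)
            idx = np.nonzero(valid)[0]
            kmer_parts.append(kmers[idx])
            ci_parts.append(np.full(len(idx), ci, dtype=np.int32))
            pos_parts.append(idx.astype(np.int32))
        if kmer_parts:
            kmers = np.concatenate(kmer_parts)
            order = np.argsort(kmers, kind="stable")
            self.kmers = kmers[order]
            self.cis = np.concatenate(ci_parts)[order]
            self.positions = np.concatenate(pos_parts)[order]
        else:
            self.kmers = np.empty(0, dtype=np.uint64)
            self.cis = np.empty(0, dtype=np.int32)
            self.positions = np.empty(0, dtype=np.int32)

    def _lookup(self, kmer: np.uint64):
        # keep the scalar uint64: a Python int forces a slow casting path
        lo = int(np.searchsorted(self.kmers, kmer, side="left"))
        hi = int(np.searchsorted(self.kmers, kmer, side="right"))
        return zip(self.cis[lo:hi].tolist(), self.positions[lo:hi].tolist())

    def place(self, read: str, max_mismatch: int) -> Optional[Tuple[int, int, str, int]]:
        """Unique-best gapless placement: (contig_idx, pos, strand, mismatches).

        Seeds are taken at the read start, middle and end on both strands;
        every anchored full-length placement is scored by mismatch count.
        Returns None when unmapped or when the best score is tied across
        distinct placements.
        """
        k = self.seed_len
        if len(read) < k:
            return None
        best: Optional[Tuple[int, Tuple[int, int, str]]] = None
        tied = False
        seen: set = set()
        for strand, oriented in (("+", read), ("-", reverse_complement(read))):
            codes = _encode(oriented)
            if (codes == 255).any():
                continue
            rarr = np.frombuffer(oriented.encode(), dtype=np.uint8)
            R = len(oriented)
            for off in {0, (R - k) // 2, R - k}:
                kmer = (codes[off : off + k].astype(np.uint64) * self.powers).sum()
                for ci, p in self._lookup(kmer):
                    start = p - off
                    if start < 0 or start + R > len(self.arrays[ci]):
                        continue
                    key = (ci, start, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    mism = int((self.arrays[ci][start : start + R] != rarr).sum())
                    if mism > max_mismatch:
                        continue
                    if best is None or mism < best[0]:
                        best = (mism, key)
                        tied = False
                    elif mism == best[0] and key != best[1]:
                        tied = True
        if best is None or tied:
            return None
        ci, start, strand = best[1]
        return ci, start, strand, best[0]


def internal_map_pe(
    pairs: Iterable[Tuple[str, str, str]],
    contigs: Sequence[Contig],
    seed_len: int = 31,
    max_mismatch_frac: float = 0.05,
) -> List[MateAlignment]:
    """Map (pair_id, read1, read2) triples; emit alignments for mates that place.

    Both mates are placed independently (gapless, unique-best); whether a
    pair supports a junction is decided downstream by the detection stage.
    """
    idx = _ContigIndex(contigs, seed_len)
    out: List[MateAlignment] = []
    for pair_id, r1, r2 in pairs:
        for read in (r1, r2):
            if not read:
                raise InputError(f"pair {pair_id}: empty mate sequence")
            placed = idx.place(read.upper(), int(max_mismatch_frac * len(read)))
            if placed is None:
                continue
            ci, start, strand, _ = placed
            out.append(
                MateAlignment(
                    contig_id=idx.contigs[ci].id,
                    start=start,
                    end=start + len(read),
                    strand=strand,
                    mate_of=pair_id,
                )
            )
    return out
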