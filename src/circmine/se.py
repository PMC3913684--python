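"""Single-end (long-read, 454-style) circularity pipeline.

Instead of trimming, the single-end test concatenates the last *w* and first
*w* bases of a contig into a 2*w junction window (default 200 nt) and asks
whether any read covers that window across its midpoint with at least
``se_min_span_per_side`` nt (default 99) of gapless alignment on each side at
``se_min_identity`` (default 98%) identity.  A read that does so was sequenced
across the circle's origin, which a linear template cannot produce.

A post-hoc uniqueness screen checks that the 200 nt window is not itself a
repeated element in a reference plasmid database (a repeat appearing twice in
one replicon could mimic junction-spanning coverage); failures are flagged on
the element, never silently discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    CircularElement,
    Contig,
    InputError,
    JunctionEvidence,
    Thresholds,
    reverse_complement,
)


@dataclass
class JunctionWindow:
    """suffix(w) + prefix(w) of a contig; midpoint = w separates end from start."""

    contig_id: str
    seq: str
    midpoint: int


@dataclass
class WindowAlignment:
    """One read placement on a junction window (0-based half-open, gapless)."""

    read_id: str
    window_start: int
    window_end: int
    identity: float  # percent, matches / alignment columns * 100
    gapped: bool = False

    def __post_init__(self) -> None:
        if self.window_end <= self.window_start:
            raise InputError(
                f"window alignment for read {self.read_id}: empty interval "
                f"[{self.window_start},{self.window_end})"
            )


def build_junction_window(contig: Contig, th: Thresholds) -> JunctionWindow:
    """Concatenate the contig's last and first ``se_end_window`` bases."""
    w = th.se_end_window
    if len(contig.seq) < 2 * w:
        raise InputError(
            f"contig {contig.id}: length {len(contig.seq)} < 2 x se_end_window ({2 * w})"
        )
    return JunctionWindow(contig_id=contig.id, seq=contig.seq[-w:] + contig.seq[:w], midpoint=w)


def read_spans_junction(aln: WindowAlignment, th: Thresholds) -> bool:
    """Apply the span/identity/gap rule to one window alignment.

    True iff the alignment is gapless (unless gaps are allowed), reaches
    ``se_min_identity``, and covers at least ``se_min_span_per_side`` nt on
    each side of the window midpoint.
    """
    w = th.se_end_window
    if aln.gapped and not th.se_allow_gaps:
        return False
    if aln.identity < th.se_min_identity:
        return False
    left = w - aln.window_start
    right = aln.window_end - w
    return left >= th.se_min_span_per_side and right >= th.se_min_span_per_side


def _occurrences(needle: str, haystack: str) -> int:
    """Count (possibly overlapping) occurrences of needle in haystack."""
    n, i = 0, haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n


def junction_uniqueness_screen(window: JunctionWindow, reference_db: Iterable[str]) -> bool:
    """True (clean) iff no single reference record contains the window twice.

    Occurrences on either strand of the record count toward the same total.
    An empty database is vacuously clean.
    """
    rc = reverse_complement(window.seq)
    for record in reference_db:
        rec = record.upper()
        if _occurrences(window.seq, rec) + _occurrences(rc, rec) >= 2:
            return False
    return True


def best_gapless_alignment(read: str, window: str) -> Optional[Tuple[int, int, int, int]]:
    """Best single-diagonal (gapless) placement of *read* on *window*.

    Scans every diagonal offset and maximizes the number of matching columns
    over the overlap; ties broken toward the smallest offset.  Returns
    ``(window_start, window_end, matches, columns)`` or ``None`` for empty
    inputs.  Identity is ``matches / columns``; columns equals the overlap
    length because the alignment is gapless by construction.
    """
    if not read or not window:
        return None
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    R, W = len(r), len(w)
    best = None  # (matches, -offset) maximized
    for d in range(-(R - 1), W):
        i0 = max(0, -d)
        i1 = min(R, W - d)
        if i1 <= i0:
            continue
        matches = int((r[i0:i1] == w[i0 + d : i1 + d]).sum())
        key = (matches, -d)
        if best is None or key > best[0]:
            best = (key, (i0 + d, i1 + d, matches, i1 - i0))
    return None if best is None else best[1]


def _kmer_index(windows: Sequence[JunctionWindow], k: int) -> Dict[str, set]:
    index: Dict[str, set] = {}
    for wi, win in enumerate(windows):
        for p in range(len(win.seq) - k + 1):
            index.setdefault(win.seq[p : p + k], set()).add(wi)
    return index


def align_reads_to_windows(
    reads: Iterable[Tuple[str, str]],
    windows: Sequence[JunctionWindow],
    seed_len: int = 20,
) -> Dict[str, List[WindowAlignment]]:
    """Map single-end reads onto junction windows, both strands.

    Candidate (read, window) pairs are pre-filtered by shared exact k-mers;
    each candidate is then scored exhaustively over all gapless diagonals by
    :func:`best_gapless_alignment`.  Returns alignments grouped by contig id.
    """
    index = _kmer_index(windows, seed_len)
    hits: Dict[str, List[WindowAlignment]] = {}
    for read_id, seq in reads:
        seq = seq.upper()
        for oriented in (seq, reverse_complement(seq)):
            cand: set = set()
            for p in range(0, max(len(oriented) - seed_len + 1, 1), seed_len):
                cand |= index.get(oriented[p : p + seed_len], set())
            tail = oriented[-seed_len:]
            if len(oriented) >= seed_len:
                cand |= index.get(tail, set())
            for wi in cand:
                win = windows[wi]
                placed = best_gapless_alignment(oriented, win.seq)
                if placed is None:
                    continue
                ws, we, matches, cols = placed
                hits.setdefault(win.contig_id, []).append(
                    WindowAlignment(
                        read_id=read_id,
                        window_start=ws,
                        window_end=we,
                        identity=100.0 * matches / cols,
                        gapped=False,
                    )
                )
    return hits


def detect_circular_se(
    contigs: Sequence[Contig],
    reads: Iterable[Tuple[str, str]],
    th: Thresholds,
    reference_db: Iterable[str] = (),
    window_alignments: Optional[Dict[str, List[WindowAlignment]]] = None,
) -> Tuple[List[CircularElement], Dict[str, int]]:
    """Run the single-end pipeline over all eligible contigs.

    Pass an iterable of ``(read_id, sequence)`` pairs, or pre-computed
    *window_alignments* (contig id -> alignments) from an external search.
    Passing contigs are reported with their sequence unmodified
    (``overlap_trimmed = 0``); the uniqueness screen result is attached.

    Returns elements plus a funnel ``{input, window_pass, se_confirmed}``.
    """
    seen = set()
    for c in contigs:
        if c.id in seen:
            raise InputError(f"duplicate contig id {c.id!r}")
        seen.add(c.id)
    funnel = {"input": len(contigs)}
    windows: List[JunctionWindow] = []
    for c in contigs:
        if len(c.seq) >= 2 * th.se_end_window:
            windows.append(build_junction_window(c, th))
    funnel["window_pass"] = len(windows)

    if window_alignments is None:
        window_alignments = align_reads_to_windows(reads, windows)

    ref_list = [r for r in reference_db]
    by_id = {c.id: c for c in contigs}
    elements: List[CircularElement] = []
    for win in windows:
        spanning = [
            a for a in window_alignments.get(win.contig_id, []) if read_spans_junction(a, th)
        ]
        if not spanning:
            continue
        contig = by_id[win.contig_id]
        ev = JunctionEvidence(
            overlap_len=0,
            n_spanning_reads=len(spanning),
            supporting_ids=sorted({a.read_id for a in spanning}),
            passed=True,
        )
        elements.append(
            CircularElement(
                id=contig.id,
                seq=contig.seq,
                source_platform="single_end",
                overlap_trimmed=0,
                evidence=ev,
                uniqueness_clean=junction_uniqueness_screen(win, ref_list),
            )
        )
    funnel["se_confirmed"] = len(elements)
    return elements, funnel
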