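"""Paired-end two-step circularity pipeline.

Rolling-circle (phi29) amplification linearizes circular templates into
concatemeric fragments, so a circle assembled from such material carries an
identical copy of its start at its end (terminal redundancy, up to ~100 nt).
Step one finds and trims that duplication; step two demands read pairs whose
mates map near opposite ends of the trimmed contig in convergent orientation,
i.e. sequenced fragments that physically span the origin junction.

The terminal-overlap match is exact by design: a misassembly of even a few
nucleotides in either copy drops the contig, trading false negatives for a
zero false-positive construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import (
    CircularElement,
    Contig,
    InputError,
    JunctionEvidence,
    Thresholds,
)


@dataclass
class MateAlignment:
    """One gapless mate placement on a (trimmed) contig; 0-based half-open."""

    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mate_of: str  # pair id shared by the two mates

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise InputError(
                f"alignment for pair {self.mate_of}: bad interval [{self.start},{self.end})"
            )
        if self.strand not in "+-":
            raise InputError(f"alignment strand must be '+' or '-', got {self.strand!r}")

    @property
    def aligned_len(self) -> int:
        return self.end - self.start


def _prefix_function(s: str) -> List[int]:
    pi = [0] * len(s)
    k = 0
    for i in range(1, len(s)):
        while k and s[i] != s[k]:
            k = pi[k - 1]
        if s[i] == s[k]:
            k += 1
        pi[i] = k
    return pi


def find_terminal_overlap(contig: Contig, th: Thresholds) -> Optional[int]:
    """Largest k with ``min_terminal_overlap <= k <= frac*len`` and prefix == suffix.

    A length-k terminal overlap is exactly a length-k border of the string,
    so the candidates are enumerated from the KMP prefix-function border
    chain (longest first) rather than by scanning every k.  Returns ``None``
    when no border qualifies or when the contig is shorter than twice the
    minimum overlap.
    """
    seq = contig.seq
    n = len(seq)
    if n < 2 * th.min_terminal_overlap:
        return None
    cap = int(th.max_terminal_overlap_frac * n)
    pi = _prefix_function(seq)
    k = pi[-1]
    while k >= th.min_terminal_overlap:
        if k <= cap:
            return k
        k = pi[k - 1]
    return None


def trim_terminal_overlap(contig: Contig, k: int) -> str:
    """Remove the duplicated last *k* bases, leaving one exact copy of the circle."""
    if k < 0:
        raise InputError("overlap length must be non-negative")
    if k >= len(contig.seq):
        raise InputError(
            f"contig {contig.id}: cannot trim {k} nt from a {len(contig.seq)} nt sequence"
        )
    return contig.seq[: len(contig.seq) - k] if k else contig.seq


def pair_supports_junction(
    trimmed_len: int, a: MateAlignment, b: MateAlignment, th: Thresholds
) -> bool:
    """True iff the pair is convergent across the origin junction.

    One mate must lie entirely within the last ``pe_end_window`` nt on the
    forward strand, the other entirely within the first ``pe_end_window`` nt
    on the reverse strand, and each mate must align over at least
    ``pe_min_mate_aln`` nt.  Mates straddling a window boundary are rejected.
    """
    if a.contig_id != b.contig_id:
        raise InputError(f"mates of pair {a.mate_of} aligned to different contigs")
    w = th.pe_end_window
    m = th.pe_min_mate_aln

    def _ok(right: MateAlignment, left: MateAlignment) -> bool:
        return (
            right.strand == "+"
            and right.start >= max(trimmed_len - w, 0)
            and right.end <= trimmed_len
            and left.strand == "-"
            and left.start >= 0
            and left.end <= min(w, trimmed_len)
            and right.aligned_len >= m
            and left.aligned_len >= m
        )

    return _ok(a, b) or _ok(b, a)


def detect_circular_pe(
    contigs: Sequence[Contig],
    alignments: Iterable[MateAlignment],
    th: Thresholds,
) -> Tuple[List[CircularElement], Dict[str, int]]:
    """Run the two-step paired-end pipeline.

    *alignments* must refer to the **trimmed** candidate sequences (the
    trimming performed here is re-derived per contig; use
    :func:`trimmed_candidates` to obtain the sequences to map against).

    Returns the confirmed elements and a stage funnel
    ``{input, length_pass, overlap_pass, pe_confirmed}``.
    """
    cands, funnel = trimmed_candidates(contigs, th)
    known = {c.id for c in contigs}
    by_contig: Dict[str, Dict[str, List[MateAlignment]]] = {}
    for aln in alignments:
        if aln.contig_id not in known:
            raise InputError(f"alignment references unknown contig id {aln.contig_id!r}")
        by_contig.setdefault(aln.contig_id, {}).setdefault(aln.mate_of, []).append(aln)

    elements: List[CircularElement] = []
    for contig, k, trimmed in cands:
        supporting: List[str] = []
        for pair_id, mates in by_contig.get(contig.id, {}).items():
            if len(mates) != 2:
                continue
            if pair_supports_junction(len(trimmed), mates[0], mates[1], th):
                supporting.append(pair_id)
        if len(supporting) >= th.min_supporting_pairs:
            ev = JunctionEvidence(
                overlap_len=k,
                n_supporting_pairs=len(supporting),
                supporting_ids=sorted(supporting),
                passed=True,
            )
            elements.append(
                CircularElement(
                    id=contig.id,
                    seq=trimmed,
                    source_platform="paired_end",
                    overlap_trimmed=k,
                    evidence=ev,
                )
            )
    funnel["pe_confirmed"] = len(elements)
    return elements, funnel


def trimmed_candidates(
    contigs: Sequence[Contig], th: Thresholds
) -> Tuple[List[Tuple[Contig, int, str]], Dict[str, int]]:
    """Step-one survivors: (contig, overlap k, trimmed seq) plus funnel counts."""
    seen = set()
    for c in contigs:
        if c.id in seen:
            raise InputError(f"duplicate contig id {c.id!r}")
        seen.add(c.id)
    funnel = {"input": len(contigs)}
    long_enough = [c for c in contigs if len(c.seq) >= th.min_contig_len_pe]
    funnel["length_pass"] = len(long_enough)
    cands: List[Tuple[Contig, int, str]] = []
    for c in long_enough:
        k = find_terminal_overlap(c, th)
        if k is not None:
            cands.append((c, k, trim_terminal_overlap(c, k)))
    funnel["overlap_pass"] = len(cands)
    return cands, funnel
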