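"""In-silico inverse-PCR support.

Inverse PCR points two primers *away* from each other on the reported linear
sequence; only a circular (or concatemeric) template brings their binding
sites back into convergent orientation across the linearization origin, so a
product of the predicted size simultaneously confirms existence, circularity
and length of the element.

The mispriming screen mimics circularity for every screened contig by
doubling its sequence, then searches both strands for primer binding sites
tolerating a bounded edit composition (default: at most 1 mismatch AND 1
insertion AND 1 deletion, applied simultaneously).  A primer pair passes iff
its own element yields exactly one amplicon, of the predicted length, and no
other contig yields any.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .core import CircularElement, Contig, InputError, Thresholds, reverse_complement


@dataclass
class PrimerPair:
    """Outward-facing primer pair on an element's reported linear sequence.

    ``fwd_5prime`` is the 0-based position of the forward primer's 5' base
    (primer reads toward increasing coordinates, across the junction);
    ``rev_5prime`` is the position of the reverse primer's 5' base (primer
    reads toward decreasing coordinates).  Outward orientation requires
    ``rev_5prime < fwd_5prime``.
    """

    element_id: str
    fwd_seq: str
    rev_seq: str
    fwd_5prime: int
    rev_5prime: int

    def __post_init__(self) -> None:
        if not (0 <= self.rev_5prime < self.fwd_5prime):
            raise InputError(
                f"pair on {self.element_id}: need 0 <= rev_5prime < fwd_5prime, "
                f"got {self.rev_5prime}, {self.fwd_5prime}"
            )


@dataclass
class VirtualAmplicon:
    template_id: str
    product_len: int
    fwd_pos: int  # 5' position of the plus-strand primer on the doubled template
    rev_pos: int  # 5' position of the minus-strand primer on the doubled template
    fwd_edits: Tuple[int, int, int]  # (mismatches, insertions, deletions)
    rev_edits: Tuple[int, int, int]


@dataclass
class PrimerBinding:
    start: int
    end: int  # half-open on the searched (plus) strand
    strand: str
    mismatches: int
    insertions: int
    deletions: int

    @property
    def edits(self) -> Tuple[int, int, int]:
        return (self.mismatches, self.insertions, self.deletions)

    @property
    def total_edits(self) -> int:
        return self.mismatches + self.insertions + self.deletions


def propose_primer_regions(
    element: CircularElement, primer_len: int = 20, junction_buffer: int = 150
) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Candidate windows for outward primers, away from the junction.

    Returns ``(fwd_region, rev_region)`` as 0-based half-open intervals with
    the reverse window left of the forward window and both at distance
    >= *junction_buffer* from positions 0 and L.  Oligo selection inside the
    windows is left to external primer-design software.
    """
    L = element.length
    min_len = 2 * (junction_buffer + primer_len) + 2
    if L < min_len:
        raise InputError(
            f"element {element.id}: length {L} < minimum {min_len} for "
            f"primer_len={primer_len}, junction_buffer={junction_buffer}"
        )
    mid = L // 2
    rev_region = (junction_buffer, mid)
    fwd_region = (mid, L - junction_buffer)
    return fwd_region, rev_region


def predicted_inverse_product_len(L: int, fwd_5prime: int, rev_5prime: int) -> int:
    """Length of the inverse-PCR product across the junction.

    The product covers positions ``fwd_5prime .. L-1`` and ``0 .. rev_5prime``
    inclusive on the circle.
    """
    if not (0 <= rev_5prime < fwd_5prime < L):
        raise InputError(
            f"need 0 <= rev_5prime < fwd_5prime < L, got {rev_5prime}, {fwd_5prime}, {L}"
        )
    return (L - fwd_5prime) + rev_5prime + 1


def design_outward_primers(
    element: CircularElement, primer_len: int = 20, junction_buffer: int = 150
) -> PrimerPair:
    """Deterministic outward pair at the inner edges of the proposed regions.

    A convenience picker for simulation and screening; it applies no
    thermodynamic criteria.
    """
    fwd_region, rev_region = propose_primer_regions(element, primer_len, junction_buffer)
    fwd_5 = fwd_region[0]
    rev_5 = rev_region[1] - 1
    seq = element.seq
    return PrimerPair(
        element_id=element.id,
        fwd_seq=seq[fwd_5 : fwd_5 + primer_len],
        rev_seq=reverse_complement(seq[rev_5 - primer_len + 1 : rev_5 + 1]),
        fwd_5prime=fwd_5,
        rev_5prime=rev_5,
    )


def _part_starts(length: int, n_parts: int) -> List[Tuple[int, int]]:
    step = length // n_parts
    cuts = [i * step for i in range(n_parts)] + [length]
    return [(cuts[i], cuts[i + 1]) for i in range(n_parts)]


def _bounded_align_starts(
    primer: str, template: str, start: int, mm_cap: int, ins_cap: int, del_cap: int
) -> Optional[Tuple[int, int, int, int]]:
    """Qualifying full-primer alignment beginning at template position *start*.

    Explores alignments (match/mismatch, deletion of a primer base, insertion
    of a template base) with total edits up to ``mm_cap + ins_cap + del_cap``;
    insertions are internal only (a leading or trailing insertion is just a
    shifted start).  The site qualifies iff some *minimal-total-edit*
    alignment satisfies every per-category cap — so a site whose best
    explanation is two substitutions is rejected even though one substitution
    could formally be rewritten as an insertion plus a deletion.  Returns
    ``(end, mm, ins, dels)`` of a qualifying minimal alignment, or ``None``.
    """
    P, T = len(primer), len(template)
    budget = mm_cap + ins_cap + del_cap
    best_total: Optional[int] = None
    completions: list = []  # (total, mm, ins, dl, end)
    stack = [(0, start, 0, 0, 0)]
    seen: set = set()
    while stack:
        state = stack.pop()
        if state in seen:
            continue
        seen.add(state)
        i, j, mm, ins, dl = state
        total = mm + ins + dl
        if best_total is not None and total > best_total:
            continue
        if i == P:
            if best_total is None or total < best_total:
                best_total = total
            completions.append((total, mm, ins, dl, j))
            continue
        if j < T:
            step_mm = mm + (primer[i] != template[j])
            if step_mm + ins + dl <= budget:
                stack.append((i + 1, j + 1, step_mm, ins, dl))
            if total + 1 <= budget and 0 < i:
                stack.append((i, j + 1, mm, ins + 1, dl))
        if total + 1 <= budget:
            stack.append((i + 1, j, mm, ins, dl + 1))
    if best_total is None:
        return None
    qualifying = [
        (mm, ins, dl, end)
        for total, mm, ins, dl, end in completions
        if total == best_total and mm <= mm_cap and ins <= ins_cap and dl <= del_cap
    ]
    if not qualifying:
        return None
    mm, ins, dl, end = min(qualifying)
    return end, mm, ins, dl


def _find_bindings_one_strand(
    primer: str, template: str, mm_cap: int, ins_cap: int, del_cap: int
) -> List[Tuple[int, int, int, int, int]]:
    """All (start, end, mm, ins, del) placements of *primer* on the plus strand.

    Candidate start positions come from pigeonhole seeding: the primer is cut
    into (mm_cap + ins_cap + del_cap + 1) contiguous parts, one of which must
    occur exactly in any placement within the edit budget; each exact part
    occurrence anchors a bounded verification (with +-(ins+del) start slack).
    """
    P, T = len(primer), len(template)
    if P > T or P == 0:
        return []
    budget = mm_cap + ins_cap + del_cap
    n_parts = budget + 1
    slack = budget
    starts: set = set()
    for ps, pe in _part_starts(P, n_parts):
        part = primer[ps:pe]
        if not part:
            continue
        i = template.find(part)
        while i != -1:
            anchor = i - ps
            for s in range(anchor - slack, anchor + slack + 1):
                if 0 <= s <= T - P + del_cap:
                    starts.add(s)
            i = template.find(part, i + 1)
    out = []
    for s in sorted(starts):
        placed = _bounded_align_starts(primer, template, s, mm_cap, ins_cap, del_cap)
        if placed is not None:
            end, mm, ins, dl = placed
            out.append((s, end, mm, ins, dl))
    return out


def _dedup_bindings(raw: List[PrimerBinding]) -> List[PrimerBinding]:
    """Collapse overlapping placements of the same site to the best-scoring one."""
    raw = sorted(raw, key=lambda b: (b.total_edits, b.start))
    kept: List[PrimerBinding] = []
    for b in raw:
        if any(
            k.strand == b.strand
            and min(k.end, b.end) - max(k.start, b.start) > (b.end - b.start) // 2
            for k in kept
        ):
            continue
        kept.append(b)
    kept.sort(key=lambda b: (b.start, b.strand))
    return kept


def find_primer_bindings(primer: str, template: str, th: Thresholds) -> List[PrimerBinding]:
    """Every binding site of *primer* on either strand of *template*.

    A site qualifies when a minimal-edit alignment of the full primer has
    mismatches <= ``vpcr_max_mismatch`` AND insertions (extra template bases)
    <= ``vpcr_max_insertion`` AND deletions (skipped primer bases) <=
    ``vpcr_max_deletion``, the three caps applied simultaneously.
    Overlapping placements are deduplicated to the best-scoring position.
    Coordinates are always on the plus strand of the template; a
    minus-strand binding means the reverse complement of the primer matches
    there.
    """
    if not template:
        raise InputError("empty template")
    raw: List[PrimerBinding] = []
    for strand, oriented in (("+", primer), ("-", reverse_complement(primer))):
        for s, e, mm, ins, dl in _find_bindings_one_strand(
            oriented, template, th.vpcr_max_mismatch, th.vpcr_max_insertion, th.vpcr_max_deletion
        ):
            raw.append(PrimerBinding(s, e, strand, mm, ins, dl))
    return _dedup_bindings(raw)


def virtual_pcr_screen(
    pair: PrimerPair,
    contigs: Sequence[Contig],
    th: Thresholds,
    predicted_len: Optional[int] = None,
) -> Tuple[bool, List[VirtualAmplicon]]:
    """Mispriming screen of one primer pair against a doubled-contig database.

    Contigs shorter than ``vpcr_min_template_len`` are excluded; each
    remaining contig is doubled (seq+seq) to mimic circularity.  An amplicon
    is any convergent plus/minus binding of the two primers with product
    length at most the contig's original length; products duplicated by the
    doubling are reported once.

    Passes iff exactly one amplicon exists, it lies on the pair's own
    element, and (when *predicted_len* is given) its length matches.
    """
    amplicons: List[VirtualAmplicon] = []
    for contig in contigs:
        L = len(contig.seq)
        if L < th.vpcr_min_template_len:
            continue
        doubled = contig.seq + contig.seq
        fwd_b = find_primer_bindings(pair.fwd_seq, doubled, th)
        rev_b = find_primer_bindings(pair.rev_seq, doubled, th)
        seen: set = set()
        for plus_set, minus_set, plus_edits_first in (
            (fwd_b, rev_b, True),
            (rev_b, fwd_b, False),
        ):
            for p in plus_set:
                if p.strand != "+":
                    continue
                for m in minus_set:
                    if m.strand != "-":
                        continue
                    product = m.end - p.start
                    if product < len(pair.fwd_seq) + len(pair.rev_seq) or product > L:
                        continue
                    key = (p.start % L, product, plus_edits_first)
                    if key in seen:
                        continue
                    seen.add(key)
                    fwd_edits = p.edits if plus_edits_first else m.edits
                    rev_edits = m.edits if plus_edits_first else p.edits
                    amplicons.append(
                        VirtualAmplicon(
                            template_id=contig.id,
                            product_len=product,
                            fwd_pos=p.start,
                            rev_pos=m.end - 1,
                            fwd_edits=fwd_edits,
                            rev_edits=rev_edits,
                        )
                    )
    ok = (
        len(amplicons) == 1
        and amplicons[0].template_id == pair.element_id
        and (predicted_len is None or amplicons[0].product_len == predicted_len)
    )
    return ok, amplicons
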