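"""End-to-end orchestration: detect (PE and/or SE) -> dedup -> annotate -> vPCR.

The stage funnel (input -> length_pass -> overlap_pass -> confirmed ->
deduplicated -> replicon_positive) is assembled from per-stage counts and is
the primary run log.  Representative elements are renamed to a configurable
prefix plus a zero-padded ordinal; the member-to-cluster map retains the
original contig ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .annotate import AnnotationSummary, DomainHit, ElementAnnotation, GeneCall, classify_elements
from .core import CircularElement, Contig, InputError, Thresholds
from .dedup import ElementCluster, cluster_elements, select_representative
from .mapper import internal_map_pe
from .pe import detect_circular_pe, trimmed_candidates
from .se import detect_circular_se
from .vpcr import design_outward_primers, predicted_inverse_product_len, virtual_pcr_screen


@dataclass
class PipelineResult:
    elements: List[CircularElement]
    clusters: List[ElementCluster]
    funnel: Dict[str, int]
    pe_funnel: Optional[Dict[str, int]] = None
    se_funnel: Optional[Dict[str, int]] = None
    id_map: Dict[str, str] = field(default_factory=dict)  # member id -> element id
    rep_of: Dict[str, str] = field(default_factory=dict)  # element id -> source member id
    annotations: Optional[Dict[str, ElementAnnotation]] = None
    summary: Optional[AnnotationSummary] = None
    vpcr: Optional[pd.DataFrame] = None


def _rename(clusters: List[ElementCluster], prefix: str, policy: str) -> Tuple[
    List[CircularElement], Dict[str, str], Dict[str, str]
]:
    """Renamed representative copies, member->element id map, element->source member id."""
    import dataclasses

    chosen = []
    for cl in clusters:
        rep = select_representative(cl, policy)
        platforms = {m.source_platform for m in cl.members}
        platform = "both" if {"paired_end", "single_end"} <= platforms else rep.source_platform
        chosen.append((cl, rep, platform))
    chosen.sort(key=lambda t: t[1].id)
    width = max(5, len(str(len(chosen))))
    id_map: Dict[str, str] = {}
    rep_of: Dict[str, str] = {}
    out = []
    for i, (cl, rep, platform) in enumerate(chosen, 1):
        new_id = f"{prefix}{i:0{width}d}"
        for m in cl.members:
            id_map[m.id] = new_id
        rep_of[new_id] = rep.id
        out.append(dataclasses.replace(rep, id=new_id, source_platform=platform))
    return out, id_map, rep_of


def run_pipeline(
    pe_contigs: Optional[Sequence[Contig]] = None,
    pe_pairs: Optional[Sequence[Tuple[str, str, str]]] = None,
    pe_alignments=None,
    se_contigs: Optional[Sequence[Contig]] = None,
    se_reads: Optional[Sequence[Tuple[str, str]]] = None,
    thresholds: Optional[Thresholds] = None,
    reference_db: Iterable[str] = (),
    gene_calls: Optional[Sequence[GeneCall]] = None,
    domain_hits: Optional[Sequence[DomainHit]] = None,
    run_vpcr: bool = False,
    prefix: str = "pRC",
    representative_policy: str = "prefer_single_end",
    cluster_mode: str = "exact",
) -> PipelineResult:
    """Run every configured stage and return the combined result.

    Provide paired-end contigs with either raw pairs (mapped by the internal
    test-scale mapper against the trimmed candidates) or pre-computed mate
    alignments, and/or single-end contigs with reads.  Gene calls and domain
    hits, when given, reference the original contig ids of any cluster
    member.
    """
    th = thresholds or Thresholds()
    if pe_contigs is None and se_contigs is None:
        raise InputError("at least one of PE or SE inputs is required")

    elements: List[CircularElement] = []
    pe_funnel = se_funnel = None
    if pe_contigs is not None:
        if pe_alignments is None:
            cands, _ = trimmed_candidates(pe_contigs, th)
            trimmed_refs = [
                Contig(id=c.id, seq=trimmed, platform="paired_end")
                for c, _, trimmed in cands
            ]
            pe_alignments = (
                internal_map_pe(pe_pairs, trimmed_refs) if pe_pairs and trimmed_refs else []
            )
        pe_elements, pe_funnel = detect_circular_pe(pe_contigs, pe_alignments, th)
        elements.extend(pe_elements)
    if se_contigs is not None:
        se_elements, se_funnel = detect_circular_se(
            se_contigs, se_reads or (), th, reference_db
        )
        elements.extend(se_elements)

    clusters = cluster_elements(elements, mode=cluster_mode)
    reps, id_map, rep_of = _rename(clusters, prefix, representative_policy)

    funnel: Dict[str, int] = {}
    if pe_funnel:
        funnel.update({f"pe_{k}" if not k.startswith("pe_") else k: v for k, v in pe_funnel.items()})
    if se_funnel:
        funnel.update({f"se_{k}" if not k.startswith("se_") else k: v for k, v in se_funnel.items()})
    funnel["deduplicated"] = len(reps)

    annotations = summary = None
    if gene_calls is not None and domain_hits is not None:
        translated = []
        for g in gene_calls:
            eid = id_map.get(g.element_id)
            if eid is None:
                raise InputError(
                    f"gene {g.gene_id} references contig {g.element_id!r}, "
                    "which is not a member of any detected element"
                )
            translated.append(
                GeneCall(g.gene_id, eid, g.start, g.end, g.strand, g.partial, g.protein)
            )
        annotations, summary = classify_elements(
            [e.id for e in reps], translated, domain_hits, cutoff=th.hmm_evalue_cutoff
        )
        funnel["replicon_positive"] = summary.n_replicon_elements

    vpcr_frame = None
    if run_vpcr:
        screen_db: List[Contig] = [
            Contig(id=e.id, seq=e.seq, platform=e.source_platform) for e in reps
        ]
        rows = []
        for el in reps:
            try:
                pair = design_outward_primers(el)
            except InputError as exc:
                rows.append({"element": el.id, "designed": False, "passed": False,
                             "n_amplicons": 0, "product_len": None, "note": str(exc)})
                continue
            predicted = predicted_inverse_product_len(el.length, pair.fwd_5prime, pair.rev_5prime)
            ok, amps = virtual_pcr_screen(pair, screen_db, th, predicted_len=predicted)
            rows.append({
                "element": el.id, "designed": True, "passed": ok,
                "n_amplicons": len(amps),
                "product_len": amps[0].product_len if amps else None,
                "note": "",
            })
        vpcr_frame = pd.DataFrame(rows)

    return PipelineResult(
        elements=reps,
        clusters=clusters,
        funnel=funnel,
        pe_funnel=pe_funnel,
        se_funnel=se_funnel,
        id_map=id_map,
        rep_of=rep_of,
        annotations=annotations,
        summary=summary,
        vpcr=vpcr_frame,
    )


def cluster_map_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for cl in result.clusters:
        for m in cl.members:
            eid = result.id_map.get(m.id, m.id)
            rows.append({
                "member_id": m.id,
                "element_id": eid,
                "platform": m.source_platform,
                "is_representative": result.rep_of.get(eid) == m.id,
            })
    return pd.DataFrame(rows, columns=["member_id", "element_id", "platform", "is_representative"])


def funnel_frame(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame(
        [{"stage": k, "count": v} for k, v in result.funnel.items()],
        columns=["stage", "count"],
    )
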