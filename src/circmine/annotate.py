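"""Replicon-domain classification of circular elements.

A circular element is called a putative plasmid when any of its complete
predicted genes carries a plasmid replication-initiation (replicon) domain.
Gene calling and the profile-HMM search are external (Prodigal-style GFF3 +
protein FASTA, and HMMER domtblout, respectively); this module owns the
curated replicon family list, the E-value cutoff / best-hit-per-gene rule,
and the instances-versus-elements arithmetic: an element with n replicon
genes contributes n to the per-family instance counts but 1 to the
replicon-positive element count.

Trait tagging (mobilization, toxin/antitoxin, conjugation, phage, transposase
markers) uses an editable accession table; the shipped defaults are a
documented approximation, not a curated reference set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import InputError

#: Pfam families diagnostic of plasmid replication initiation
#: (accession, name, description). Version suffixes are ignored in matching.
REPLICON_FAMILIES: List[Tuple[str, str, str]] = [
    ("PF01446.12", "Rep_1", "Replication protein"),
    ("PF01719.12", "Rep_2", "Plasmid replication protein"),
    ("PF01051.16", "Rep_3", "Initiator Replication protein"),
    ("PF05732.6", "RepL", "Firmicute plasmid replication protein"),
    ("PF07042.6", "TrfA", "TrfA protein"),
    ("PF04796.7", "RepA_C", "Plasmid encoded RepA protein"),
    ("PF02486.14", "Rep_trans", "Replication initiation factor"),
    ("PF01402.16", "RHH_1", "Ribbon-helix-helix protein, copG family"),
    ("PF01815.11", "Rop", "Rop protein"),
    ("PF03428.8", "RP-C", "Replication protein C N-terminal domain"),
    ("PF10134.4", "RPA", "Replication initiator protein A"),
    ("PF06970.6", "RepA_N", "Replication initiator protein A (RepA) N-terminus"),
    ("PF06504.6", "RepC", "Replication protein C (RepC)"),
    ("PF03090.12", "Replicase", "Replication initiator protein"),
]

#: Default trait -> Pfam accession lists. A documented approximation: the
#: trait categories are standard plasmid/phage markers but the exact
#: accession sets are editable configuration, and one accession may belong
#: to at most one trait.
DEFAULT_TRAIT_TABLE: Dict[str, List[str]] = {
    "mob": ["PF03432", "PF03389"],  # Relaxase, MobA/MobL
    "toxin": ["PF01845", "PF05016"],  # CcdB, ParE toxin
    "antitoxin": ["PF02604", "PF04221"],  # PhdYeFM, RelB
    "t4ss": ["PF02534"],  # T4SS coupling protein (TraG/TraD/VirD4)
    "capsid": ["PF05065"],  # phage capsid
    "phage_integrase": ["PF00589"],
    "transposase": ["PF01527", "PF00665"],
}


def strip_version(accession: str) -> str:
    return accession.split(".", 1)[0]


@dataclass
class GeneCall:
    gene_id: str
    element_id: str
    start: int
    end: int
    strand: str
    partial: bool = False
    protein: str = ""


@dataclass
class DomainHit:
    """One profile-HMM domain match on a predicted gene."""

    gene_id: str
    pfam_accession: str
    family_name: str
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise InputError(f"hit on {self.gene_id}: negative E-value")


@dataclass
class ElementAnnotation:
    element_id: str
    has_replicon: bool = False
    replicon_families: Counter = field(default_factory=Counter)
    traits: Counter = field(default_factory=Counter)


@dataclass
class AnnotationSummary:
    family_instances: Counter = field(default_factory=Counter)
    n_replicon_elements: int = 0
    n_replicon_instances: int = 0
    trait_instances: Counter = field(default_factory=Counter)


def select_best_hit(hits: Sequence[DomainHit], cutoff: float = 1e-4) -> Optional[DomainHit]:
    """Best surviving domain hit for one gene.

    Hits above the E-value *cutoff* are discarded; among survivors the
    smallest E-value wins, ties broken by larger bit score, then by
    lexicographic accession.  The competition is across all families, so a
    gene whose best match is a non-replicon domain is not a replicon gene.
    """
    gene_ids = {h.gene_id for h in hits}
    if len(gene_ids) > 1:
        raise InputError(f"select_best_hit got hits for multiple genes: {sorted(gene_ids)}")
    surviving = [h for h in hits if h.e_value <= cutoff]
    if not surviving:
        return None
    return min(surviving, key=lambda h: (h.e_value, -h.bit_score, h.pfam_accession))


def classify_elements(
    element_ids: Iterable[str],
    gene_calls: Sequence[GeneCall],
    domain_hits: Sequence[DomainHit],
    replicon_table: Optional[Sequence[Tuple[str, str, str]]] = None,
    trait_table: Optional[Dict[str, List[str]]] = None,
    cutoff: float = 1e-4,
) -> Tuple[Dict[str, ElementAnnotation], AnnotationSummary]:
    """Per-element replicon/trait annotation plus a global family summary.

    Only complete genes (``partial=False``) participate.  Each gene is
    reduced to its single best hit at the cutoff; the element annotation
    aggregates those best hits.
    """
    if replicon_table is None:
        replicon_table = REPLICON_FAMILIES
    if trait_table is None:
        trait_table = DEFAULT_TRAIT_TABLE
    replicon_by_acc = {strip_version(acc): name for acc, name, _ in replicon_table}
    trait_by_acc: Dict[str, str] = {}
    for trait, accs in trait_table.items():
        for acc in accs:
            acc = strip_version(acc)
            if acc in trait_by_acc:
                raise InputError(f"accession {acc} mapped to more than one trait")
            trait_by_acc[acc] = trait

    known = set(element_ids)
    annotations = {eid: ElementAnnotation(element_id=eid) for eid in sorted(known)}
    for g in gene_calls:
        if g.element_id not in known:
            raise InputError(f"gene {g.gene_id} references unknown element {g.element_id!r}")

    hits_by_gene: Dict[str, List[DomainHit]] = {}
    for h in domain_hits:
        hits_by_gene.setdefault(h.gene_id, []).append(h)

    summary = AnnotationSummary()
    for g in sorted(gene_calls, key=lambda g: g.gene_id):
        if g.partial:
            continue
        best = select_best_hit(hits_by_gene.get(g.gene_id, []), cutoff)
        if best is None:
            continue
        acc = strip_version(best.pfam_accession)
        ann = annotations[g.element_id]
        if acc in replicon_by_acc:
            fam = replicon_by_acc[acc]
            ann.has_replicon = True
            ann.replicon_families[fam] += 1
            summary.family_instances[fam] += 1
            summary.n_replicon_instances += 1
        elif acc in trait_by_acc:
            trait = trait_by_acc[acc]
            ann.traits[trait] += 1
            summary.trait_instances[trait] += 1
    summary.n_replicon_elements = sum(1 for a in annotations.values() if a.has_replicon)
    return annotations, summary
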