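"""Cross-dataset deduplication and merging of circular elements.

The same plasmid recovered from two sequencing platforms (or twice within
one) is reported linearized at arbitrary origins and strands; clustering is
therefore performed on canonical rotations.  Exact mode groups identical
circles.  Near mode additionally merges pairs differing by at most 2 nt of
length whose rotation-aligned global identity reaches ``near_identity`` —
this tolerates the single-nucleotide homopolymer errors that can distinguish
two reads of the same plasmid (e.g. GGG read as GG).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import edlib

from .core import CircularElement, InputError, reverse_complement


@dataclass
class ElementCluster:
    canonical_seq: str
    members: List[CircularElement]
    representative: CircularElement


def rotation_aligned_identity(a: str, b: str) -> float:
    """Percent identity of the best rotation-anchored global alignment of two circles.

    The shorter sequence is aligned semi-globally against the doubled longer
    sequence, so every rotation of the longer one is a candidate anchor.
    Identity is ``100 * (1 - edit_distance / len(shorter))``.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(short, long_ + long_, mode="HW", task="distance")
    dist = res["editDistance"]
    return 100.0 * (1.0 - dist / len(short))


def cluster_elements(
    elements: Sequence[CircularElement],
    mode: str = "exact",
    near_identity: float = 99.5,
) -> List[ElementCluster]:
    """Group elements that represent the same circle.

    Clusters are disjoint and their union is the input.  Exact mode groups by
    identical canonical sequence; near mode then merges canonical groups whose
    lengths differ by <= 2 nt and whose rotation-aligned identity is at least
    *near_identity* percent.
    """
    if mode not in ("exact", "near"):
        raise InputError(f"unknown clustering mode {mode!r}")
    groups: Dict[str, List[CircularElement]] = {}
    for el in elements:
        groups.setdefault(el.canonical_seq, []).append(el)
    keys = sorted(groups)

    parent = list(range(len(keys)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if mode == "near":
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                if abs(len(keys[i]) - len(keys[j])) > 2:
                    continue
                # either strand of one against the doubled other
                ident = max(
                    rotation_aligned_identity(keys[i], keys[j]),
                    rotation_aligned_identity(reverse_complement(keys[i]), keys[j]),
                )
                if ident >= near_identity:
                    parent[find(i)] = find(j)

    merged: Dict[int, List[CircularElement]] = {}
    for i, key in enumerate(keys):
        merged.setdefault(find(i), []).extend(groups[key])

    clusters = []
    for members in merged.values():
        members = sorted(members, key=lambda e: e.id)
        rep = select_representative_members(members)
        clusters.append(
            ElementCluster(canonical_seq=rep.canonical_seq, members=members, representative=rep)
        )
    clusters.sort(key=lambda c: c.canonical_seq)
    return clusters


def select_representative_members(
    members: Sequence[CircularElement], policy: str = "prefer_single_end"
) -> CircularElement:
    """Deterministic representative of a member list (see :func:`select_representative`)."""
    if not members:
        raise InputError("cannot pick a representative from an empty cluster")
    if policy == "prefer_single_end":
        pref = [m for m in members if m.source_platform in ("single_end", "both")]
    elif policy == "prefer_paired_end":
        pref = [m for m in members if m.source_platform in ("paired_end", "both")]
    elif policy == "longest":
        mx = max(m.length for m in members)
        pref = [m for m in members if m.length == mx]
    else:
        raise InputError(f"unknown representative policy {policy!r}")
    pool = pref or list(members)
    return min(pool, key=lambda m: m.id)


def select_representative(
    cluster: ElementCluster, policy: str = "prefer_single_end"
) -> CircularElement:
    """Pick the cluster's reported copy.

    ``prefer_single_end`` mirrors discarding the short-read version of a
    circle found on both platforms; ``prefer_paired_end`` is the converse;
    ``longest`` keeps the longest member.  Ties break to the
    lexicographically smallest element id.
    """
    return select_representative_members(cluster.members, policy)
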