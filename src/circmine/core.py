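"""Shared sequence types, threshold configuration and rotation-invariant canonicalization.

Circular DNA has no natural origin or strand: the same plasmid assembled twice
may be reported linearized at different positions, on either strand.  Every
downstream comparison of circular elements therefore goes through
:func:`canonicalize`, which maps a sequence to the lexicographically smallest
string among all rotations of itself and of its reverse complement.  Two
linearizations of the same circle always share a canonical string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PLATFORMS = ("paired_end", "single_end", "both", "unknown")


class InputError(ValueError):
    """Raised when user-supplied data violates an operation's contract."""


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement over {A,C,G,T,N}.

    ``N`` complements to ``N``.  An involution: applying twice returns the
    input.
    """
    _check_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str) -> None:
    if not seq:
        raise InputError("empty DNA sequence")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise InputError(f"non-DNA characters in sequence: {sorted(bad)!r}")


def least_rotation_index(s: str) -> int:
    """Index of the lexicographically least rotation of *s* (Booth's algorithm, O(n))."""
    s2 = s + s
    n = len(s2)
    fail = [-1] * n
    k = 0
    for j in range(1, n):
        cj = s2[j]
        i = fail[j - k - 1]
        while i != -1 and cj != s2[k + i + 1]:
            if cj < s2[k + i + 1]:
                k = j - i - 1
            i = fail[i]
        if cj != s2[k + i + 1]:
            if cj < s2[k]:
                k = j
            fail[j - k] = -1
        else:
            fail[j - k] = i + 1
    return k


def least_rotation(s: str) -> str:
    i = least_rotation_index(s)
    return s[i:] + s[:i]


def rotate(s: str, k: int) -> str:
    """Rotate *s* left by *k* positions (k may exceed len(s))."""
    if not s:
        raise InputError("cannot rotate an empty sequence")
    k %= len(s)
    return s[k:] + s[:k]


def canonicalize(seq: str) -> str:
    """Rotation- and strand-invariant identifier of a circular sequence.

    Returns the lexicographically smallest string among all rotations of
    *seq* and all rotations of its reverse complement.  Identical circles
    map to the same canonical string regardless of linearization origin or
    reported strand.
    """
    _check_dna(seq)
    return min(least_rotation(seq), least_rotation(reverse_complement(seq)))


@dataclass
class Contig:
    """An assembled linear sequence.

    Parameters
    ----------
    id :
        Label, unique within one input set.
    seq :
        DNA over {A,C,G,T,N}; case-normalized to upper on construction.
    coverage :
        Optional assembler-reported coverage (non-negative).
    platform :
        Sequencing provenance: ``paired_end``, ``single_end`` or ``unknown``.
    """

    id: str
    seq: str
    coverage: Optional[float] = None
    platform: str = "unknown"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        _check_dna(self.seq)
        if self.coverage is not None and self.coverage < 0:
            raise InputError(f"contig {self.id}: negative coverage")
        if self.platform not in PLATFORMS:
            raise InputError(f"contig {self.id}: unknown platform {self.platform!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Thresholds:
    """Every numeric knob of the detection/validation pipelines.

    Lengths are nucleotides; coordinates everywhere in the package are
    0-based half-open, converted to 1-based only in written reports.

    Defaults encode the published procedure: terminal duplications of a
    rolling-circle-amplified template reach ~100 nt and are called at >40 nt
    of identical ends; paired-end junction evidence must map entirely within
    500 nt of either end with >=90 nt aligned per mate; single-end junction
    windows take 100 nt from each end (200 nt total) and require >=99 nt of
    gapless coverage on each side at >=98% identity; domain hits are kept at
    E <= 1e-4; virtual PCR tolerates 1 mismatch, 1 insertion and 1 deletion
    and screens all contigs longer than 200 nt, each doubled to mimic
    circularity.
    """

    min_terminal_overlap: int = 40
    max_terminal_overlap_frac: float = 0.5
    min_contig_len_pe: int = 1000
    pe_end_window: int = 500
    pe_min_mate_aln: int = 90
    se_end_window: int = 100
    se_min_span_per_side: int = 99
    se_min_identity: float = 98.0
    se_allow_gaps: bool = False
    min_supporting_pairs: int = 1
    hmm_evalue_cutoff: float = 1e-4
    vpcr_max_mismatch: int = 1
    vpcr_max_insertion: int = 1
    vpcr_max_deletion: int = 1
    vpcr_min_template_len: int = 201

    def __post_init__(self) -> None:
        for name in (
            "min_terminal_overlap",
            "min_contig_len_pe",
            "pe_end_window",
            "pe_min_mate_aln",
            "se_end_window",
            "se_min_span_per_side",
            "min_supporting_pairs",
            "vpcr_min_template_len",
        ):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise InputError(f"threshold {name} must be a positive integer, got {v!r}")
        for name in ("vpcr_max_mismatch", "vpcr_max_insertion", "vpcr_max_deletion"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise InputError(f"threshold {name} must be a non-negative integer, got {v!r}")
        if not 0 < self.max_terminal_overlap_frac <= 0.5:
            raise InputError("max_terminal_overlap_frac must be in (0, 0.5]")
        if not 0 < self.se_min_identity <= 100:
            raise InputError("se_min_identity must be in (0, 100]")
        if self.se_min_span_per_side > self.se_end_window:
            raise InputError("se_min_span_per_side cannot exceed se_end_window")
        if self.hmm_evalue_cutoff < 0:
            raise InputError("hmm_evalue_cutoff must be non-negative")


@dataclass
class JunctionEvidence:
    """Read support for the origin junction of a putative circle."""

    overlap_len: int = 0
    n_supporting_pairs: int = 0
    n_spanning_reads: int = 0
    supporting_ids: list = field(default_factory=list)
    passed: bool = False


@dataclass
class CircularElement:
    """A trimmed, junction-confirmed circular sequence.

    ``seq`` holds exactly one copy of the circle, linearized at an arbitrary
    origin; ``canonical_seq`` is the rotation/strand-invariant form used for
    deduplication.  ``overlap_trimmed`` records the removed terminal
    duplication (0 for single-end detections, which never trim).
    """

    id: str
    seq: str
    source_platform: str = "unknown"
    overlap_trimmed: int = 0
    evidence: JunctionEvidence = field(default_factory=JunctionEvidence)
    uniqueness_clean: Optional[bool] = None
    canonical_seq: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        _check_dna(self.seq)
        if self.source_platform not in PLATFORMS:
            raise InputError(f"element {self.id}: unknown platform {self.source_platform!r}")
        if not self.canonical_seq:
            self.canonical_seq = canonicalize(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)
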