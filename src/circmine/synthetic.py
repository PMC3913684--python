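"""Synthetic metamobilome fixtures with known ground truth.

Emulates the sequencing inputs of a small-plasmid enrichment experiment:
circular templates of 1,000-13,000 nt are rolling-circle amplified and
assembled, yielding linear contigs that carry a terminal duplication of
roughly 40-100 nt; paired-end libraries sequence 100 nt from each end of
450-550 nt fragments; a single-end long-read platform produces ~400 nt
reads.  Negative controls are plain linear contigs and "repeat-confounded"
contigs carrying an interspersed repeat longer than a read (the structure
that defeats short-read assemblers and is the classic false-positive threat
to circularity detection).

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Contig, InputError, reverse_complement, rotate

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study-condition parameters of the generator (lengths in nt)."""

    n_circles: int = 20
    n_linear: int = 20
    length_range: Tuple[int, int] = (1000, 13000)
    gc: float = 0.45
    dup_len_range: Tuple[int, int] = (40, 100)
    pe_read_len: int = 100
    insert_range: Tuple[int, int] = (450, 550)
    se_len_mean: float = 400.0
    se_len_sd: float = 80.0
    sub_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("length_range", "dup_len_range", "insert_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise InputError(f"{name} must be a non-empty positive interval")
        if not 0 <= self.gc <= 1:
            raise InputError("gc must be in [0,1]")
        if not 0 <= self.sub_rate <= 1:
            raise InputError("sub_rate must be in [0,1]")


@dataclass
class SimTruth:
    contig_id: str
    is_circular: bool
    true_circle_len: int
    dup_len: int
    rotation_offset: int
    klass: str  # circle | linear | repeat_confounded

    def __post_init__(self) -> None:
        if self.klass not in ("circle", "linear", "repeat_confounded"):
            raise InputError(f"unknown truth class {self.klass!r}")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_circle(length: int, gc: float = 0.45, seed=0) -> str:
    """Random circle sequence at the target GC fraction; seed-reproducible."""
    if length < 1:
        raise InputError("circle length must be >= 1")
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def make_mda_contig(
    circle: str, dup_len: int, rotation_offset: int, contig_id: str = "contig_1"
) -> Tuple[Contig, SimTruth]:
    """Linearize a circle the way rolling-circle amplification + assembly does.

    The contig is the circle rotated by *rotation_offset* with its first
    *dup_len* bases appended again at the end (the terminal redundancy).
    """
    L = len(circle)
    if not 0 <= dup_len <= L:
        raise InputError(f"dup_len {dup_len} out of range for a {L} nt circle")
    if not 0 <= rotation_offset < L:
        raise InputError(f"rotation_offset {rotation_offset} out of range")
    rotated = rotate(circle, rotation_offset)
    contig = Contig(id=contig_id, seq=rotated + rotated[:dup_len], platform="paired_end")
    truth = SimTruth(
        contig_id=contig_id,
        is_circular=True,
        true_circle_len=L,
        dup_len=dup_len,
        rotation_offset=rotation_offset,
        klass="circle",
    )
    return contig, truth


def _mutate(seq: str, sub_rate: float, rng: np.random.Generator) -> str:
    if sub_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < sub_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_pe_reads(
    template: str,
    coverage: float,
    pe_read_len: int = 100,
    insert_range: Tuple[int, int] = (450, 550),
    sub_rate: float = 0.0,
    seed=0,
    circular: bool = True,
    id_prefix: str = "frag",
) -> List[Tuple[str, str, str]]:
    """Paired-end fragments from a circular (origin-wrapping) or linear template.

    Fragment starts are uniform on the template; on a circle they wrap the
    origin, so the expected fraction of junction-spanning fragments is about
    mean_insert / length.  Mates read inward from opposite fragment ends.
    Returns ``(pair_id, read1, read2)`` triples; read2 is reverse-strand.
    """
    L = len(template)
    lo, hi = insert_range
    if L <= hi:
        raise InputError(f"template ({L} nt) shorter than the maximum insert ({hi} nt)")
    rng = _rng(seed)
    n_frags = int(np.ceil(coverage * L / (2 * pe_read_len)))
    doubled = template + template if circular else template
    out = []
    for i in range(n_frags):
        insert = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, L if circular else L - insert + 1))
        frag = doubled[start : start + insert]
        r1 = _mutate(frag[:pe_read_len], sub_rate, rng)
        r2 = _mutate(reverse_complement(frag[-pe_read_len:]), sub_rate, rng)
        out.append((f"{id_prefix}_{i}", r1, r2))
    return out


def simulate_se_reads(
    template: str,
    coverage: float,
    len_mean: float = 400.0,
    len_sd: float = 80.0,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed=0,
    circular: bool = True,
    id_prefix: str = "read",
) -> List[Tuple[str, str]]:
    """Single-end reads with normal length distribution, both strands.

    Substitutions at *sub_rate*; rare single-base indels at *indel_rate*
    (per read).  Returns ``(read_id, seq)`` pairs.
    """
    L = len(template)
    rng = _rng(seed)
    n_reads = int(np.ceil(coverage * L / len_mean))
    doubled = template + template if circular else template
    out = []
    for i in range(n_reads):
        rl = max(30, int(rng.normal(len_mean, len_sd)))
        rl = min(rl, L)
        start = int(rng.integers(0, L if circular else max(L - rl + 1, 1)))
        seq = doubled[start : start + rl]
        seq = _mutate(seq, sub_rate, rng)
        if indel_rate > 0 and rng.random() < indel_rate and len(seq) > 2:
            pos = int(rng.integers(1, len(seq) - 1))
            if rng.random() < 0.5:
                seq = seq[:pos] + seq[pos + 1 :]
            else:
                seq = seq[:pos] + _BASES[rng.integers(0, 4)].tobytes().decode() + seq[pos:]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        out.append((f"{id_prefix}_{i}", seq))
    return out


def make_negative_controls(
    n_linear: int,
    n_repeat_confounded: int,
    repeat_len: int = 150,
    seed=0,
    length_range: Tuple[int, int] = (1000, 13000),
    gc: float = 0.45,
    id_prefix: str = "neg",
) -> Tuple[List[Contig], List[SimTruth]]:
    """Linear and repeat-confounded negative-control contigs.

    Repeat-confounded contigs carry two interspersed copies of a repeat
    (longer than a read, never at the termini) — the repeat structure that a
    de Bruijn assembler cannot resolve and that must never be called
    circular.
    """
    rng = _rng(seed)
    contigs: List[Contig] = []
    truths: List[SimTruth] = []
    for i in range(n_linear):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        cid = f"{id_prefix}_linear_{i}"
        contigs.append(Contig(id=cid, seq=simulate_circle(L, gc, rng), platform="unknown"))
        truths.append(SimTruth(cid, False, 0, 0, 0, "linear"))
    margin = 50
    for i in range(n_repeat_confounded):
        L = int(rng.integers(max(length_range[0], 2 * repeat_len + 4 * margin), length_range[1] + 1))
        rep = simulate_circle(repeat_len, gc, rng)
        flank_total = L - 2 * repeat_len
        a = int(rng.integers(margin, flank_total - 2 * margin))
        b = int(rng.integers(margin, flank_total - a - margin))
        c = flank_total - a - b
        seq = (
            simulate_circle(a, gc, rng)
            + rep
            + simulate_circle(b, gc, rng)
            + rep
            + simulate_circle(c, gc, rng)
        )
        cid = f"{id_prefix}_repeat_{i}"
        contigs.append(Contig(id=cid, seq=seq, platform="unknown"))
        truths.append(SimTruth(cid, False, 0, 0, 0, "repeat_confounded"))
    return contigs, truths


@dataclass
class SimulatedDataset:
    circles: Dict[str, str]
    contigs: List[Contig]
    truths: List[SimTruth]
    pe_pairs: Dict[str, List[Tuple[str, str, str]]] = field(default_factory=dict)
    se_reads: Dict[str, List[Tuple[str, str]]] = field(default_factory=dict)


def simulate_dataset(
    cfg: SimConfig,
    pe_coverage: float = 20.0,
    se_coverage: float = 0.0,
    mda_skew: bool = False,
) -> SimulatedDataset:
    """Full study-shaped dataset: circles, MDA contigs, negatives and reads.

    When *mda_skew* is on, per-circle coverage is multiplied by a log-uniform
    factor in [1, 100] to mimic the amplification bias of rolling-circle MDA.
    """
    rng = _rng(cfg.seed)
    circles: Dict[str, str] = {}
    contigs: List[Contig] = []
    truths: List[SimTruth] = []
    pe_pairs: Dict[str, List[Tuple[str, str, str]]] = {}
    se_reads: Dict[str, List[Tuple[str, str]]] = {}
    for i in range(cfg.n_circles):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        circle = simulate_circle(L, cfg.gc, rng)
        cid = f"circle_{i}"
        circles[cid] = circle
        dup = int(rng.integers(cfg.dup_len_range[0], min(cfg.dup_len_range[1], L) + 1))
        offset = int(rng.integers(0, L))
        contig, truth = make_mda_contig(circle, dup, offset, contig_id=cid)
        contigs.append(contig)
        truths.append(truth)
        skew = float(np.exp(rng.uniform(0, np.log(100)))) if mda_skew else 1.0
        if pe_coverage > 0:
            pe_pairs[cid] = simulate_pe_reads(
                circle,
                pe_coverage * skew,
                cfg.pe_read_len,
                cfg.insert_range,
                cfg.sub_rate,
                rng,
                circular=True,
                id_prefix=f"{cid}_frag",
            )
        if se_coverage > 0:
            se_reads[cid] = simulate_se_reads(
                circle,
                se_coverage * skew,
                cfg.se_len_mean,
                cfg.se_len_sd,
                cfg.sub_rate,
                0.0,
                rng,
                circular=True,
                id_prefix=f"{cid}_read",
            )
    neg_contigs, neg_truths = make_negative_controls(
        cfg.n_linear, 0, seed=rng, length_range=cfg.length_range, gc=cfg.gc
    )
    contigs.extend(neg_contigs)
    truths.extend(neg_truths)
    return SimulatedDataset(circles, contigs, truths, pe_pairs, se_reads)
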