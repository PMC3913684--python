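"""Paired-end pipeline: terminal-overlap detection/trimming and junction evidence."""

import numpy as np
import pytest

from circmine.core import Contig, InputError, Thresholds, canonicalize
from circmine.mapper import internal_map_pe
from circmine.pe import (
    MateAlignment,
    detect_circular_pe,
    find_terminal_overlap,
    pair_supports_junction,
    trim_terminal_overlap,
    trimmed_candidates,
)
from circmine.synthetic import make_mda_contig, simulate_circle, simulate_pe_reads

from conftest import random_dna


def brute_overlap(seq: str, min_k: int, frac: float):
    """Oracle: check every k for prefix == suffix, return the largest in range."""
    if len(seq) < 2 * min_k:
        return None
    cap = int(frac * len(seq))
    for k in range(cap, min_k - 1, -1):
        if seq[:k] == seq[-k:]:
            return k
    return None


class TestFindTerminalOverlap:
    def test_planted_overlap(self):
        th = Thresholds(min_terminal_overlap=4)
        c = Contig(id="x", seq="ATGCCGTTAAGC" + "ATGCC")  # 17 nt, 5 nt duplication
        assert brute_overlap(c.seq, 4, 0.5) == 5
        assert find_terminal_overlap(c, th) == 5

    def test_no_overlap(self):
        th = Thresholds(min_terminal_overlap=2)
        assert find_terminal_overlap(Contig(id="x", seq="AAAATTTT"), th) is None

    def test_fractional_cap(self):
        # ATATATAT has borders 6, 4, 2; the 0.5*len cap excludes 6
        th = Thresholds(min_terminal_overlap=2, max_terminal_overlap_frac=0.5)
        assert find_terminal_overlap(Contig(id="x", seq="ATATATAT"), th) == 4

    def test_too_short_is_skipped(self):
        th = Thresholds(min_terminal_overlap=40)
        assert find_terminal_overlap(Contig(id="x", seq="ACGT" * 15), th) is None

    def test_agrees_with_bruteforce_on_planted_cases(self, rng):
        """1,000 random strings with planted terminal duplications of 0-200 nt."""
        th = Thresholds(min_terminal_overlap=40)
        for _ in range(1000):
            core_len = int(rng.integers(100, 600))
            dup = int(rng.integers(0, 201))
            core = random_dna(rng, core_len)
            seq = core + core[: min(dup, core_len)]
            expected = brute_overlap(seq, th.min_terminal_overlap, th.max_terminal_overlap_frac)
            got = find_terminal_overlap(Contig(id="x", seq=seq), th)
            assert got == expected


class TestTrim:
    def test_trim_planted(self):
        c = Contig(id="x", seq="ATGCCGTTAAGCATGCC")
        assert trim_terminal_overlap(c, 5) == "ATGCCGTTAAGC"
        assert len(trim_terminal_overlap(c, 5)) == 12

    def test_trim_zero_is_identity(self):
        c = Contig(id="x", seq="ACGTACGT")
        assert trim_terminal_overlap(c, 0) == c.seq

    def test_trim_too_much_raises(self):
        with pytest.raises(InputError):
            trim_terminal_overlap(Contig(id="x", seq="ACGT"), 4)


class TestPairSupportsJunction:
    def mk(self, start, end, strand, cid="c"):
        return MateAlignment(contig_id=cid, start=start, end=end, strand=strand, mate_of="p")

    def test_supporting_pair(self, th):
        assert pair_supports_junction(3000, self.mk(2600, 2700, "+"), self.mk(100, 190, "-"), th)

    def test_order_independent(self, th):
        assert pair_supports_junction(3000, self.mk(100, 190, "-"), self.mk(2600, 2700, "+"), th)

    def test_outside_end_window(self, th):
        assert not pair_supports_junction(
            3000, self.mk(2300, 2400, "+"), self.mk(100, 190, "-"), th
        )

    def test_short_mate_alignment(self, th):
        # 85 nt aligned violates the 90 nt minimum per mate
        assert not pair_supports_junction(
            3000, self.mk(2610, 2695, "+"), self.mk(100, 190, "-"), th
        )

    def test_wrong_orientation(self, th):
        assert not pair_supports_junction(
            3000, self.mk(2600, 2700, "-"), self.mk(100, 190, "+"), th
        )

    def test_different_contigs_raise(self, th):
        with pytest.raises(InputError):
            pair_supports_junction(
                3000, self.mk(2600, 2700, "+", "a"), self.mk(100, 190, "-", "b"), th
            )


class TestDetectCircularPE:
    def _detect(self, contigs, circle_reads, th):
        cands, _ = trimmed_candidates(contigs, th)
        refs = [Contig(id=c.id, seq=t, platform="paired_end") for c, _, t in cands]
        alns = internal_map_pe(circle_reads, refs) if refs else []
        return detect_circular_pe(contigs, alns, th)

    def test_round_trip_single_circle(self, th):
        circle = simulate_circle(3000, 0.45, seed=11)
        contig, truth = make_mda_contig(circle, 60, 777, "c1")
        reads = simulate_pe_reads(circle, 20, seed=12)
        elements, funnel = self._detect([contig], reads, th)
        assert funnel == {"input": 1, "length_pass": 1, "overlap_pass": 1, "pe_confirmed": 1}
        el = elements[0]
        assert el.overlap_trimmed == 60
        assert el.canonical_seq == canonicalize(circle)
        assert el.evidence.n_supporting_pairs >= 1

    def test_linear_contig_rejected(self, th):
        linear = Contig(id="lin", seq=simulate_circle(3000, 0.45, seed=13))
        reads = simulate_pe_reads(linear.seq, 20, seed=14, circular=False)
        elements, funnel = self._detect([linear], reads, th)
        assert elements == []
        assert funnel["overlap_pass"] == 0

    def test_min_length_filter(self):
        th = Thresholds()
        circle = simulate_circle(900, 0.45, seed=15)
        contig, _ = make_mda_contig(circle, 60, 0, "short")
        # 960 nt including duplication: still below the 1000 nt floor
        assert len(contig.seq) < 1000
        elements, funnel = detect_circular_pe([contig], [], th)
        assert funnel["length_pass"] == 0 and elements == []

    def test_indel_in_terminal_copy_drops_contig(self, th):
        """A 1 nt indel inside one terminal copy must fail step one (conservatism)."""
        circle = simulate_circle(2000, 0.45, seed=16)
        contig, _ = make_mda_contig(circle, 80, 100, "c1")
        seq = contig.seq
        pos = len(seq) - 40  # middle of the 80 nt terminal copy
        broken = Contig(id="broken", seq=seq[:pos] + seq[pos + 1 :])
        assert find_terminal_overlap(broken, th) is None

    def test_unknown_contig_in_alignment_raises(self, th):
        circle = simulate_circle(2000, 0.45, seed=17)
        contig, _ = make_mda_contig(circle, 60, 0, "c1")
        bad = MateAlignment(contig_id="ghost", start=0, end=100, strand="+", mate_of="p")
        with pytest.raises(InputError):
            detect_circular_pe([contig], [bad], th)

    def test_duplicate_contig_ids_raise(self, th):
        c = Contig(id="dup", seq="ACGT" * 300)
        with pytest.raises(InputError):
            detect_circular_pe([c, c], [], th)
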