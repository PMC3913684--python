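"""In-silico inverse PCR: region proposal, product arithmetic, binding search, screen."""

import numpy as np
import pytest

from circmine.core import CircularElement, Contig, InputError, Thresholds, reverse_complement, rotate
from circmine.synthetic import simulate_circle
from circmine.vpcr import (
    PrimerPair,
    _find_bindings_one_strand,
    design_outward_primers,
    find_primer_bindings,
    predicted_inverse_product_len,
    propose_primer_regions,
    virtual_pcr_screen,
)

from conftest import random_dna


def oracle_viable_starts(primer, template, mm_cap, ins_cap, del_cap):
    """Independent exhaustive oracle over (i, j, mm, ins, del) states.

    For each start, enumerate every full-primer alignment with total edits
    within the combined budget; the start qualifies iff some alignment of
    *minimal total edit count* satisfies all three per-category caps.
    """
    P, T = len(primer), len(template)
    budget = mm_cap + ins_cap + del_cap
    starts = set()
    for s in range(T):
        frontier = {(0, s, 0, 0, 0)}
        seen = set()
        completions = []
        while frontier:
            state = frontier.pop()
            if state in seen:
                continue
            seen.add(state)
            i, j, mm, ins, dl = state
            if i == P:
                completions.append((mm, ins, dl))
                continue
            if j < T:
                nm = mm + (primer[i] != template[j])
                if nm + ins + dl <= budget:
                    frontier.add((i + 1, j + 1, nm, ins, dl))
                if mm + ins + dl < budget and 0 < i:
                    frontier.add((i, j + 1, mm, ins + 1, dl))
            if mm + ins + dl < budget:
                frontier.add((i + 1, j, mm, ins, dl + 1))
        if not completions:
            continue
        best_total = min(sum(c) for c in completions)
        if any(
            sum(c) == best_total and c[0] <= mm_cap and c[1] <= ins_cap and c[2] <= del_cap
            for c in completions
        ):
            starts.add(s)
    return starts


class TestProposeRegions:
    def test_regions_respect_buffer(self):
        el = CircularElement(id="e", seq=simulate_circle(3000, 0.45, seed=41))
        fwd, rev = propose_primer_regions(el, primer_len=20, junction_buffer=150)
        assert rev[0] >= 150 and fwd[1] <= 3000 - 150
        assert rev[1] <= fwd[0]
        assert fwd[1] - fwd[0] >= 20 and rev[1] - rev[0] >= 20

    def test_too_short_raises_with_minimum(self):
        el = CircularElement(id="e", seq=simulate_circle(300, 0.45, seed=42))
        with pytest.raises(InputError, match="342"):
            propose_primer_regions(el, primer_len=20, junction_buffer=150)

    def test_zero_buffer_degenerate_allowed(self):
        el = CircularElement(id="e", seq=simulate_circle(100, 0.45, seed=43))
        fwd, rev = propose_primer_regions(el, primer_len=20, junction_buffer=0)
        assert rev[0] == 0 and fwd[1] == 100


class TestProductLength:
    def test_enumerated_example(self):
        # product covers positions 80..99 (20 nt) + 0..30 (31 nt) = 51
        assert predicted_inverse_product_len(100, 80, 30) == 51

    def test_back_to_back_primers(self):
        L = 500
        assert predicted_inverse_product_len(L, L - 20, 19) == 40

    def test_degenerate_single_base_arms(self):
        assert predicted_inverse_product_len(100, 99, 0) == 2

    def test_out_of_range_raises(self):
        with pytest.raises(InputError):
            predicted_inverse_product_len(100, 30, 80)

    def test_rotation_invariance(self, rng):
        """Predictions are invariant when the origin and primer positions rotate together."""
        L = 1000
        for _ in range(20):
            f = int(rng.integers(500, 999))
            r = int(rng.integers(0, 499))
            base = predicted_inverse_product_len(L, f, r)
            shift = int(rng.integers(1, L))
            # rotating the linearization by `shift` moves both 5' ends by -shift mod L;
            # when both stay in order the product is unchanged
            f2, r2 = (f - shift) % L, (r - shift) % L
            if 0 <= r2 < f2 < L:
                assert predicted_inverse_product_len(L, f2, r2) == base


class TestFindPrimerBindings:
    def test_exact_site(self, th, rng):
        primer = random_dna(rng, 20)
        template = random_dna(rng, 200) + primer + random_dna(rng, 200)
        hits = [b for b in find_primer_bindings(primer, template, th) if b.strand == "+"]
        assert any(b.start == 200 and b.edits == (0, 0, 0) for b in hits)

    def test_one_substitution_site(self, th, rng):
        primer = random_dna(rng, 20)
        site = primer[:10] + ("A" if primer[10] != "A" else "C") + primer[11:]
        template = random_dna(rng, 150) + site + random_dna(rng, 150)
        hits = [b for b in find_primer_bindings(primer, template, th) if b.strand == "+"]
        assert any(b.start == 150 and b.mismatches == 1 for b in hits)

    def test_two_substitutions_rejected(self, th):
        rng = np.random.default_rng(4242)
        primer = random_dna(rng, 20)
        site = list(primer)
        site[5] = "A" if primer[5] != "A" else "C"
        site[15] = "A" if primer[15] != "A" else "C"
        template = random_dna(rng, 100) + "".join(site) + random_dna(rng, 100)
        hits = find_primer_bindings(primer, template, th)
        assert not any(abs(b.start - 100) <= 2 for b in hits)

    def test_reverse_strand_site(self, th, rng):
        primer = random_dna(rng, 20)
        template = random_dna(rng, 60) + reverse_complement(primer) + random_dna(rng, 60)
        hits = find_primer_bindings(primer, template, th)
        assert any(b.strand == "-" and b.start == 60 for b in hits)

    def test_primer_longer_than_template(self, th):
        assert find_primer_bindings("A" * 30, "ACGT" * 5, th) == []

    def test_agrees_with_dp_oracle(self, rng):
        """Pigeonhole-seeded bounded search vs exhaustive DP on 500 random pairs."""
        caps = (1, 1, 1)
        for i in range(500):
            plen = int(rng.integers(10, 26))
            primer = random_dna(rng, plen)
            template = random_dna(rng, int(rng.integers(plen, 500)))
            if rng.random() < 0.6:
                # plant a mutated copy to exercise near-matches
                site = list(primer)
                n_edits = int(rng.integers(0, 3))
                for _ in range(n_edits):
                    p = int(rng.integers(0, len(site)))
                    site[p] = "ACGT"[int(rng.integers(0, 4))]
                pos = int(rng.integers(0, len(template) - plen + 1))
                template = template[:pos] + "".join(site) + template[pos + plen:]
            got = {s for s, *_ in _find_bindings_one_strand(primer, template, *caps)}
            expected = oracle_viable_starts(primer, template, *caps)
            assert got == expected, f"case {i}"


class TestVirtualPcrScreen:
    def test_self_consistency(self, th):
        circle = simulate_circle(2500, 0.45, seed=44)
        el = CircularElement(id="e1", seq=circle)
        pair = design_outward_primers(el)
        predicted = predicted_inverse_product_len(el.length, pair.fwd_5prime, pair.rev_5prime)
        ok, amps = virtual_pcr_screen(pair, [Contig(id="e1", seq=circle)], th,
                                      predicted_len=predicted)
        assert ok
        assert len(amps) == 1 and amps[0].product_len == predicted

    def test_decoy_with_both_sites_fails(self, th, rng):
        circle = simulate_circle(2500, 0.45, seed=45)
        el = CircularElement(id="e1", seq=circle)
        pair = design_outward_primers(el)
        predicted = predicted_inverse_product_len(el.length, pair.fwd_5prime, pair.rev_5prime)
        decoy = (random_dna(rng, 150) + pair.fwd_seq + random_dna(rng, 300)
                 + reverse_complement(pair.rev_seq) + random_dna(rng, 150))
        ok, amps = virtual_pcr_screen(
            pair, [Contig(id="e1", seq=circle), Contig(id="decoy", seq=decoy)], th,
            predicted_len=predicted,
        )
        assert not ok
        assert len(amps) >= 2
        assert {a.template_id for a in amps} == {"e1", "decoy"}

    def test_no_reverse_binding_fails(self, th, rng):
        circle = simulate_circle(2500, 0.45, seed=46)
        pair = PrimerPair(element_id="e1", fwd_seq=circle[1500:1520],
                          rev_seq=random_dna(rng, 20), fwd_5prime=1500, rev_5prime=100)
        ok, amps = virtual_pcr_screen(pair, [Contig(id="e1", seq=circle)], th)
        assert not ok and amps == []

    def test_short_templates_excluded(self, th):
        circle = simulate_circle(2500, 0.45, seed=47)
        el = CircularElement(id="e1", seq=circle)
        pair = design_outward_primers(el)
        short = Contig(id="tiny", seq=circle[:200])  # 200 nt: below the >200 nt floor
        ok, amps = virtual_pcr_screen(pair, [Contig(id="e1", seq=circle), short], th)
        assert ok or all(a.template_id == "e1" for a in amps)

    def test_doubling_equals_rotation_enumeration(self, th, rng):
        """Amplicons on seq+seq match those found on explicit rotations (circular truth)."""
        for i in range(15):
            L = int(rng.integers(600, 2000))
            circle = simulate_circle(L, 0.45, seed=1000 + i)
            el = CircularElement(id=f"e{i}", seq=circle)
            pair = design_outward_primers(el, junction_buffer=100)
            _, amps = virtual_pcr_screen(pair, [Contig(id=f"e{i}", seq=circle)], th)
            products = sorted(a.product_len for a in amps)
            # rotation enumeration oracle: any rotation that brings the sites into
            # convergent order on a linear copy yields the same product length
            predicted = predicted_inverse_product_len(L, pair.fwd_5prime, pair.rev_5prime)
            rotated = rotate(circle, pair.fwd_5prime)  # junction now inside the amplicon
            f2 = 0
            r2 = (pair.rev_5prime - pair.fwd_5prime) % L
            assert rotated[f2:f2 + 20] == pair.fwd_seq
            assert (r2 - f2) + 1 == predicted
            assert products == [predicted]
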