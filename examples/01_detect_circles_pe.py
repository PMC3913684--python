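"""Detect circular elements among paired-end assembled contigs.

Simulates five small circular plasmids the way rolling-circle amplification
and short-read assembly would present them — linear contigs with a 40-100 nt
terminal duplication — plus five plain linear contigs, then runs the
two-step detection: trim the duplicated ends, and demand read pairs mapping
convergently across the junction.
"""

from circmine import Thresholds, canonicalize
from circmine.core import Contig
from circmine.mapper import internal_map_pe
from circmine.pe import detect_circular_pe, trimmed_candidates
from circmine.synthetic import SimConfig, simulate_dataset

cfg = SimConfig(n_circles=5, n_linear=5, sub_rate=0.0, seed=42)
ds = simulate_dataset(cfg, pe_coverage=20)
th = Thresholds()

cands, _ = trimmed_candidates(ds.contigs, th)
refs = [Contig(id=c.id, seq=t, platform="paired_end") for c, _, t in cands]
pairs = [p for plist in ds.pe_pairs.values() for p in plist]
alignments = internal_map_pe(pairs, refs)

elements, funnel = detect_circular_pe(ds.contigs, alignments, th)

print("stage funnel:", funnel)
for el in elements:
    truth_ok = el.canonical_seq == canonicalize(ds.circles[el.id])
    print(
        f"{el.id}: {el.length} nt circle, trimmed {el.overlap_trimmed} nt terminal "
        f"duplication, {el.evidence.n_supporting_pairs} junction-spanning pairs, "
        f"sequence matches simulated truth: {truth_ok}"
    )
print(
    "\nThe funnel counts contigs surviving each filter; every simulated circle is\n"
    "recovered with its exact sequence (up to rotation/strand) and no linear\n"
    "contig is called circular."
)
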