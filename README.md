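# circmine

Post-assembly mining of **complete circular DNA elements** — putative small
plasmids, phage and transposon circles — among contigs assembled from
metamobilome (plasmid-enriched metagenome) sequencing.

## Who this is for

Assemblers emit only linear contigs, so a circular plasmid that was fully
assembled is indistinguishable, at first glance, from a linear fragment.
`circmine` is for microbiologists and bioinformaticians who have a
shotgun-sequenced, rolling-circle-amplified mobilome and want to pull the
*complete circles* out of the assembly with per-element read evidence,
deduplicate them across sequencing platforms, tag the plasmid-like ones by
replication-initiation domains, and design an inverse-PCR validation for
them.

## The methods at its core

**Paired-end, two-step detection.** Rolling-circle amplification (φ29 MDA)
linearizes circular templates so that an assembled circle carries a
*terminal redundancy*: its first *k* bases repeated exactly at its end
(*k* up to ~100 nt). Step one finds the largest terminal overlap with
`min_terminal_overlap ≤ k ≤ 0.5·L` (default ≥ 40 nt, exact match — a border
of the contig string, found from the KMP prefix function) and trims it,
leaving one copy of the circle. Step two demands read pairs whose mates map
gaplessly and convergently within `pe_end_window` (500 nt) of opposite ends
of the trimmed contig, each with ≥ 90 nt aligned — fragments that physically
span the origin junction. Contigs shorter than 1,000 nt are excluded so the
end windows cannot overlap.

**Single-end, one-step detection.** For long single-end reads the junction
window `suffix(100) + prefix(100)` of each contig is built, and the contig
is circular when some read covers ≥ 99 nt on *both* sides of the window
midpoint with no gaps at ≥ 98% identity. A post-hoc screen flags windows
that occur twice within any single reference plasmid — the signature of a
repeat masquerading as a junction.

**Rotation-invariant deduplication.** A circle re-linearized at another
origin or strand is the same element; sequences are compared through their
*canonical rotation* — the lexicographically least string over all rotations
of the sequence and its reverse complement (Booth's algorithm, validated
against brute force). A `near` mode additionally merges copies differing by
≤ 2 nt via rotation-anchored edit distance (edlib on the doubled sequence),
tolerating single homopolymer errors.

**Replicon-domain classification.** Complete predicted genes (Prodigal-style
GFF3) with HMMER Pfam domain hits are reduced to one best hit per gene
(E ≤ 1e-4; smallest E-value, ties by bit score). An element is a *putative
plasmid* if any best hit lands in the 14-family replication-initiation table
(Rep_1 PF01446, Rep_2 PF01719, Rep_3 PF01051, RepL PF05732, TrfA PF07042,
RepA_C PF04796, Rep_trans PF02486, RHH_1 PF01402, Rop PF01815, RP-C PF03428,
RPA PF10134, RepA_N PF06970, RepC PF06504, Replicase PF03090); an element
with *n* replicon genes contributes *n* domain instances but one element.

**In-silico inverse PCR.** Outward-facing primers away from the junction
yield a product only from a circular template; the predicted product length
is `(L − fwd₅′) + rev₅′ + 1`. The mispriming screen loads every contig
> 200 nt *twice* (seq+seq, mimicking circularity) and finds all primer sites
whose minimal-edit alignment has ≤ 1 mismatch, ≤ 1 insertion and ≤ 1
deletion; a pair passes only if exactly one amplicon exists, on its own
element, at the predicted length.

A seeded synthetic-data generator (`circmine.synthetic`) emulates the study
conditions — circles of 1,000–13,000 nt, terminal duplications of 40–100 nt,
100 nt paired-end reads from 450–550 nt inserts, ~400 nt single-end reads —
with full ground truth, so every stage is testable at desk scale.

## Worked example

```bash
python examples/01_detect_circles_pe.py
```

prints (numbers produced by the code):

```
stage funnel: {'input': 10, 'length_pass': 10, 'overlap_pass': 5, 'pe_confirmed': 5}
circle_0: 2071 nt circle, trimmed 87 nt terminal duplication, 28 junction-spanning pairs, sequence matches simulated truth: True
circle_1: 6043 nt circle, trimmed 69 nt terminal duplication, 26 junction-spanning pairs, sequence matches simulated truth: True
circle_2: 11474 nt circle, trimmed 77 nt terminal duplication, 30 junction-spanning pairs, sequence matches simulated truth: True
circle_3: 2568 nt circle, trimmed 73 nt terminal duplication, 31 junction-spanning pairs, sequence matches simulated truth: True
circle_4: 9672 nt circle, trimmed 71 nt terminal duplication, 33 junction-spanning pairs, sequence matches simulated truth: True
```

Ten contigs went in (five simulated circles with terminal duplications, five
linear); the length filter kept all ten, the terminal-overlap step kept the
five true circles, and junction-spanning read pairs confirmed each of them.
Every recovered sequence equals the simulated circle up to rotation and
strand. The other examples cover single-end detection
(`02_detect_circles_se.py`), deduplication + replicon annotation
(`03_dedup_and_annotate.py`) and the virtual PCR screen
(`04_inverse_pcr.py`).

A thin CLI wraps the same library calls:

```bash
circmine simulate --n-circles 20 --n-linear 20 --pe-coverage 20 --seed 1 --out-dir sim/
circmine detect-pe --contigs sim/contigs.fasta --reads1 sim/reads_1.fastq \
    --reads2 sim/reads_2.fastq --out-dir out/
circmine vpcr --elements out/elements.fasta --out-dir out/
```

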