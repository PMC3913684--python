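# Methods

This note documents the models and procedures implemented in `circmine`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not demonstrate.

## Why circles look like linear contigs with duplicated ends

Mobilome preparations are typically amplified with φ29 polymerase (multiple
displacement amplification, MDA). On a circular template φ29 performs
rolling-circle synthesis, producing linear concatemers; after shearing,
sequencing and assembly, a fully covered circle appears as a single linear
contig whose start is repeated, character-identically, at its end — in
practice up to roughly 100 nt. A genuinely linear template produces no such
terminal redundancy. Both detection pipelines also exploit the fact that a
circular template yields reads/fragments physically spanning the arbitrary
linearization origin ("junction"), which a linear template cannot.

## Paired-end pipeline

1. **Length filter** — contigs shorter than `min_contig_len_pe` (default
   1,000 nt) are excluded. With 500 nt end windows on both sides, a shorter
   contig would let the two windows overlap and a single interior pair could
   mimic junction evidence.
2. **Terminal overlap (step one)** — the largest `k` with
   `min_terminal_overlap ≤ k ≤ max_terminal_overlap_frac · L` such that
   `prefix(k) == suffix(k)` exactly. A terminal overlap is precisely a
   *border* of the contig string, so candidates are read off the KMP
   prefix-function border chain in O(L); the test suite checks this against
   an all-`k` brute-force scan. The match is exact by design: a single
   indel or mismatch in either copy (a misassembly signature) makes the
   contig fail, trading known false negatives for a zero-false-positive
   construction. The `0.5·L` cap keeps the trimmed core non-degenerate: a
   terminal duplication cannot meaningfully exceed one full circle copy.
   The last `k` bases are then trimmed.
3. **Junction pairs (step two)** — on the trimmed contig of length `L`, a
   pair supports the junction iff one mate lies entirely within
   `[L − 500, L)` on the forward strand, the other entirely within
   `[0, 500)` on the reverse strand, and both align gaplessly over ≥ 90 nt.
   "Entirely within" is the strict reading: a mate straddling the window
   boundary is rejected. Each mate, not the pair total, must reach 90 nt
   (mates are 100 nt reads, so the per-mate reading is the self-consistent
   one). At least `min_supporting_pairs` (default 1) such pairs confirm the
   element; the default mirrors "discard when no pair supports", and the
   knob is exposed for stricter use.

Evidence alignments may come from any external mapper as SAM (only primary,
gapless single-run-CIGAR records are counted) or from the built-in
test-scale mapper: exact 31-mer seeding at three read offsets on both
strands, full-length gapless verification by mismatch count, unique-best
placement only (ties are discarded).

## Single-end pipeline

For each contig with `L ≥ 2w` (`w = se_end_window = 100`), the junction
window `suffix(w) + prefix(w)` is built. Reads (both strands) are placed on
windows with a gapless best-diagonal aligner: every diagonal offset is
scored by matching columns and the maximum wins (ties to the smaller
offset); identity is `matches / columns`. In the pipeline, read–window
candidates are pre-filtered by shared exact 20-mers — with ≥ 98% identity
required downstream, a true junction read always shares such a seed — and
each candidate is then scored over *all* diagonals, so the pre-filter does
not change decisions on data that can pass. A contig is circular when some
read covers ≥ `se_min_span_per_side` (99) nt on **each** side of the window
midpoint, gaplessly, at ≥ `se_min_identity` (98%). One read must cover both
sides; two reads covering one side each are not accepted. Passing contigs
are reported unmodified (`overlap_trimmed = 0`).

The **uniqueness screen** searches each passing window (both strands,
overlapping occurrences counted) in every record of an optional reference
plasmid database; a record containing the window twice marks the element as
possibly repeat-driven. The flag is reported, never auto-discarded — the
screen is a post-hoc global check, not a per-element filter.

## Deduplication

Identity of circles must be invariant to linearization origin and strand,
so clustering operates on the *canonical rotation*: the lexicographic
minimum over all rotations of the sequence and of its reverse complement,
computed with Booth's linear-time least-rotation algorithm (validated
against an enumerate-all-rotations oracle). `N` participates as the literal
character with complement `N`; no IUPAC expansion, for determinism.

Exact canonical equality is the default and the auditable behaviour. The
optional `near` mode additionally merges groups whose lengths differ by
≤ 2 nt and whose rotation-anchored global identity (edlib semi-global
alignment of the shorter against the doubled longer, both strands) is
≥ 99.5% — this tolerates the single-base homopolymer discrepancies that can
distinguish two sequencings of one plasmid. Representatives are chosen by
policy (`prefer_single_end` default, mirroring the convention of keeping
the long-read copy of a cross-platform duplicate; `prefer_paired_end`;
`longest`), ties broken by smallest element id.

## Replicon-domain classification

Gene calling and the profile-HMM search are external by design; the module
contracts on their standard outputs (Prodigal-style GFF3 with the `partial`
attribute, protein FASTA, HMMER `--domtblout`). Only complete genes
participate. Per gene, hits with E-value above `hmm_evalue_cutoff` (1e-4)
are discarded and the single best survivor is kept — smallest E-value, ties
by larger bit score, then accession. The competition is across *all*
families, so a gene whose best match is, say, a transposase domain is not a
replicon gene even if a weaker replicon hit exists. From domtblout rows the
per-domain independent (i-)E-value and domain bit score are used. Pfam
accessions are compared without their version suffix.

The replicon table is the 14-family replication-initiation set (see
`circmine.annotate.REPLICON_FAMILIES`). Trait tagging (mob, toxin,
antitoxin, T4SS, capsid, phage integrase, transposase) uses an editable
accession table whose shipped defaults are a documented approximation —
the trait categories are standard, the accession sets are configuration,
and one accession may map to at most one trait. Summary arithmetic: an
element with *n* replicon genes adds *n* to per-family instance counts and
1 to the replicon-positive element count, so instances ≥ elements always.

## In-silico inverse PCR

Outward-facing primers on the reported linear sequence (reverse primer's 5′
at `r`, forward primer's 5′ at `f`, `r < f`) amplify across the junction;
the product covers positions `f..L−1` and `0..r`, hence length
`(L − f) + r + 1`. Candidate primer regions are the two halves of the
element at distance ≥ `junction_buffer` (150 nt) from both ends of the
linearization; actual oligo selection (melting temperature, hairpins) is
delegated to external primer-design software, and the minimum element
length is `2·(junction_buffer + primer_len) + 2`.

The mispriming screen doubles every contig longer than
`vpcr_min_template_len − 1 = 200` nt (seq+seq mimics circularity without
enumerating rotations; amplicons duplicated by the doubling are reported
once, capped at the original length) and searches both strands for binding
sites of both primers. A site qualifies when a **minimal-total-edit**
alignment of the full primer satisfies, simultaneously, ≤ 1 mismatch, ≤ 1
insertion (extra template base, internal only) and ≤ 1 deletion (skipped
primer base). The minimal-edit qualifier matters: without it a
two-substitution site could formally be rewritten as one mismatch plus an
insertion–deletion pair and sneak under the caps; requiring the caps on the
best explanation of the site rejects it, which matches the intended "one of
each, at most" tolerance. Whether the original tolerance allowed the three
edit types simultaneously or singly is not determinable; simultaneous caps
are the default and the search is exact under them (pigeonhole seeding —
with ≤ 3 total edits one of four primer parts must match exactly — plus a
bounded branch-and-bound verifier, cross-checked against an exhaustive
state-space oracle). No 3′-exactness is required by default. A pair passes
iff exactly one convergent amplicon exists, it lies on the pair's own
element, and its length equals the prediction.

## Synthetic data generator

`circmine.synthetic` emulates the study conditions with known ground truth:

| parameter | default | what it emulates |
| --- | --- | --- |
| circle length | uniform 1,000–13,000 nt | small-plasmid size range |
| GC fraction | 0.45 | gut-community base composition |
| terminal duplication | uniform 40–100 nt | φ29/assembly end redundancy |
| PE read / insert | 100 nt / 450–550 nt | size-selected short-read library |
| SE read length | normal(400, 80) nt | long single-end reads |
| substitution rate | 0.001 (0 in round-trip checks) | residual base errors |

Fragments are drawn uniformly on the circle and wrap the origin, so the
expected junction-spanning fraction is ≈ mean insert / circle length.
Negative controls are plain linear contigs and *repeat-confounded* contigs
carrying two interspersed copies of a repeat longer than a read, away from
the termini — the structure that breaks de Bruijn assembly of large
repeat-laden plasmids and the classic false-positive threat a circularity
caller must ignore. MDA amplification bias can be mimicked by a log-uniform
per-circle coverage multiplier (qualitative only). The error model is
substitution-only for PE reads and substitution plus rare single-base
indels for SE reads; homopolymer-biased indels, chimera formation and
quality-score structure are not modelled.

**What passing the synthetic benchmarks shows** — that the implementation
realizes its stated decision rules exactly (recovery of every well-covered,
error-free circle with the exact sequence; zero false positives on linear
and repeat-confounded negatives; failure on terminal-copy misassemblies by
construction). It does **not** show field performance on real data, where
coverage gaps, chimeric MDA products, within-sample repeats shared between
distinct elements, and assembler-specific end artifacts reduce sensitivity
in ways the generator deliberately does not simulate.

## Numerical and interface conventions

- Coordinates are 0-based half-open everywhere internally; conversion to
  1-based happens only at report boundaries (GFF ingest converts on read).
- Sequences are upper-cased on ingest; the alphabet is {A,C,G,T,N}.
- All randomness flows through seeded NumPy generators; identical seeds
  give byte-identical outputs.
- Benchmarks in `tests/test_acceptance.py` and `scripts/acceptance.py` use
  200 circles + 200 linear contigs (PE at 20×, SE at 10×), 50 circles for
  the indel-conservatism check, 100 repeat-confounded contigs, 100 circles
  × 2 linearizations for dedup, and 50 elements for the virtual-PCR screen
  — the sizes at which every property is statistically decisive while a
  full run stays within a few minutes on one core.

## Known limitations

- Step one requires *exact* terminal identity: circles whose ends carry
  even a 1 nt misassembly are missed (by design, and verified).
- Multi-contig circles, scaffold gap closing and re-assembly are out of
  scope; so are IUPAC codes beyond N and protein-level analyses.
- The internal mapper is a test-scale device (gapless, unique-best); real
  datasets should be mapped externally and ingested as SAM.
- Trait accession defaults are an approximation; counts derived from them
  are not comparable across studies without curating the table.
- Single-end detection reports contigs unmodified; if a single-end assembly
  did leave terminal redundancy on a contig, its junction window would be
  distorted and the element missed rather than mis-trimmed.
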