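"""File-format ingest and report writers.

Standard formats go through the standard libraries: FASTA/FASTQ via
Biopython, SAM via pysam, GFF3 gene calls via gffutils, tabular reports via
pandas.  HMMER per-domain table (domtblout) rows are read by a small
column parser here because no installed library exposes one as data.

Coordinates are converted to 0-based half-open on ingest and back to 1-based
only in written reports.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import DomainHit, GeneCall
from .core import CircularElement, Contig, InputError
from .pe import MateAlignment


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta_contigs(path: str, platform: str = "unknown") -> List[Contig]:
    contigs = []
    for rec in SeqIO.parse(path, "fasta"):
        contigs.append(Contig(id=rec.id, seq=str(rec.seq), platform=platform))
    if not contigs:
        raise InputError(f"{path}: no FASTA records")
    return contigs


def write_fasta(path: str, records: Iterable[Tuple[str, str]], wrap: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(recs)


def read_reads(path: str) -> List[Tuple[str, str]]:
    """Single-end reads from FASTA or FASTQ (by extension)."""
    fmt = "fastq" if path.endswith((".fq", ".fastq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, fmt)]


def read_paired_fastq(path1: str, path2: str) -> List[Tuple[str, str, str]]:
    """Mate files in order; pair ids from the /1, /2 (or .1/.2) suffix convention."""
    r1 = list(SeqIO.parse(path1, "fastq"))
    r2 = list(SeqIO.parse(path2, "fastq"))
    if len(r1) != len(r2):
        raise InputError(f"{path1} and {path2} have different read counts")
    def strip_suffix(rid: str) -> str:
        return rid[:-2] if rid[-2:] in ("/1", "/2", ".1", ".2") else rid

    pairs = []
    for a, b in zip(r1, r2):
        ida = strip_suffix(a.id)
        idb = strip_suffix(b.id)
        if ida != idb:
            raise InputError(f"unpaired read ids {a.id!r} vs {b.id!r}")
        pairs.append((ida, str(a.seq).upper(), str(b.seq).upper()))
    return pairs


def write_paired_fastq(
    path1: str, path2: str, pairs: Iterable[Tuple[str, str, str]], qual_char: str = "I"
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pid, r1, r2 in pairs:
            f1.write(f"@{pid}/1\n{r1}\n+\n{qual_char * len(r1)}\n")
            f2.write(f"@{pid}/2\n{r2}\n+\n{qual_char * len(r2)}\n")


def write_fastq(path: str, reads: Iterable[Tuple[str, str]], qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


# ----------------------------------------------------------------------- SAM

def read_sam_mate_alignments(path: str) -> List[MateAlignment]:
    """Mate alignments from a SAM file mapped against trimmed candidates.

    Only primary, mapped records whose CIGAR is a single match run (pure M,
    or = / X runs) are counted as evidence, matching the gapless contract of
    the paired-end junction test.  Pair ids are the query names; strand is
    taken from the reverse flag.
    """
    out: List[MateAlignment] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigartuples is None:
                continue
            ops = {op for op, _ in rec.cigartuples}
            if not ops <= {0, 7, 8}:  # M, =, X only: gapless, unclipped
                continue
            out.append(
                MateAlignment(
                    contig_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mate_of=rec.query_name,
                )
            )
    return out


def write_sam(
    path: str, alignments: Sequence[MateAlignment], contigs: Sequence[Contig],
    read_seqs: Optional[Dict[Tuple[str, str], str]] = None,
) -> None:
    """Minimal SAM writer for round-tripping internal alignments."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c.id, "LN": len(c.seq)} for c in contigs],
    }
    ref_ids = {c.id: i for i, c in enumerate(contigs)}
    with pysam.AlignmentFile(path, "w", header=header) as sam:
        for aln in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = aln.mate_of
            rec.reference_id = ref_ids[aln.contig_id]
            rec.reference_start = aln.start
            rec.flag = 16 if aln.strand == "-" else 0
            rec.cigartuples = [(0, aln.aligned_len)]
            seq = None
            if read_seqs is not None:
                seq = read_seqs.get((aln.mate_of, aln.strand))
            rec.query_sequence = seq if seq is not None else "N" * aln.aligned_len
            rec.mapping_quality = 60
            sam.write(rec)


# ------------------------------------------------------------- gene calls

def read_gene_calls(gff_path: str, protein_fasta: Optional[str] = None) -> List[GeneCall]:
    """CDS calls from a Prodigal-style GFF3, optionally attaching proteins.

    Completeness is read from the gene caller's ``partial`` attribute
    (``00`` = complete); records without the attribute are taken as complete.
    Gene ids follow the Prodigal protein-FASTA convention
    ``<element>_<ordinal>``.
    """
    import gffutils

    db = gffutils.create_db(
        gff_path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    proteins: Dict[str, str] = {}
    if protein_fasta:
        for rec in SeqIO.parse(protein_fasta, "fasta"):
            proteins[rec.id] = str(rec.seq).rstrip("*")
    calls: List[GeneCall] = []
    counters: Dict[str, int] = {}
    for feat in db.all_features(featuretype="CDS", order_by="start"):
        element_id = feat.seqid
        counters[element_id] = counters.get(element_id, 0) + 1
        if "ID" in feat.attributes:
            raw = feat.attributes["ID"][0]
            ordinal = raw.rsplit("_", 1)[-1]
            gene_id = f"{element_id}_{ordinal}"
        else:
            gene_id = f"{element_id}_{counters[element_id]}"
        partial = feat.attributes.get("partial", ["00"])[0] != "00"
        calls.append(
            GeneCall(
                gene_id=gene_id,
                element_id=element_id,
                start=feat.start - 1,  # GFF is 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                partial=partial,
                protein=proteins.get(gene_id, ""),
            )
        )
    return calls


# ------------------------------------------------------------- HMMER domtbl

def read_domtblout(path: str, program: str = "hmmscan") -> List[DomainHit]:
    """Per-domain rows of HMMER's --domtblout format.

    With ``program='hmmscan'`` the target columns are the profile and the
    query is the gene; ``'hmmsearch'`` swaps them.  The independent
    (i-)E-value and the domain bit score of each row are used.
    """
    if program not in ("hmmscan", "hmmsearch"):
        raise InputError(f"unknown HMMER program {program!r}")
    hits: List[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 14:
                raise InputError(f"{path}:{lineno}: truncated domtblout row")
            if program == "hmmscan":
                fam_name, fam_acc, gene_id = parts[0], parts[1], parts[3]
            else:
                gene_id, fam_name, fam_acc = parts[0], parts[3], parts[4]
            hits.append(
                DomainHit(
                    gene_id=gene_id,
                    pfam_accession=fam_acc,
                    family_name=fam_name,
                    e_value=float(parts[12]),
                    bit_score=float(parts[13]),
                )
            )
    return hits


# ------------------------------------------------------------------ reports

def elements_report_frame(elements: Sequence[CircularElement]) -> pd.DataFrame:
    rows = []
    for el in elements:
        rows.append(
            {
                "id": el.id,
                "length": el.length,
                "platform": el.source_platform,
                "overlap_trimmed": el.overlap_trimmed,
                "n_supporting_pairs": el.evidence.n_supporting_pairs,
                "n_spanning_reads": el.evidence.n_spanning_reads,
                "uniqueness_clean": el.uniqueness_clean,
                "passed": el.evidence.passed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "length", "platform", "overlap_trimmed",
            "n_supporting_pairs", "n_spanning_reads", "uniqueness_clean", "passed",
        ],
    )


def write_tsv(path: str, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_bed(path: str, intervals: Iterable[Tuple[str, int, int, str]]) -> None:
    """0-based half-open BED intervals (chrom, start, end, name)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ------------------------------------------------------------------- config

def load_config(path: str) -> Dict[str, Dict[str, object]]:
    """Threshold/simulation configuration: TOML, or flat ``section.key=value`` lines."""
    if path.endswith(".toml"):
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    out: Dict[str, Dict[str, object]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InputError(f"{path}:{lineno}: expected key=value")
            key, value = (s.strip() for s in line.split("=", 1))
            section, _, key = key.rpartition(".")
            section = section or "thresholds"
            try:
                parsed: object = int(value)
            except ValueError:
                try:
                    parsed = float(value)
                except ValueError:
                    parsed = {"true": True, "false": False}.get(value.lower(), value)
            out.setdefault(section, {})[key] = parsed
    return out
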