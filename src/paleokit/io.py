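"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython, VCF reading through pysam, trees through
dendropy.  Writers emit plain text (uncompressed VCF v4.2, TSV reports) so
every writer/reader pair round-trips losslessly for the fields the pipeline
consumes.  Coordinates are 1-based inclusive end to end.
"""

from __future__ import annotations

import io as _io
import os
from typing import Iterable, Optional

import dendropy
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError, FormatError
from .records import AlignedRead, PeptideRecord, SampleCall, SnpAlignment, TaxonRecord, VariantCallRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_variant_calls",
    "write_vcf",
    "read_taxon_report",
    "write_taxon_report",
    "read_peptide_table",
    "write_peptide_table",
    "read_reads_tsv",
    "write_reads_tsv",
    "read_reads_sam",
    "write_reads_sam",
    "write_alignment_fasta",
    "read_alignment_fasta",
    "write_phylip",
    "write_newick",
    "read_newick",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- VCF

def write_vcf(records: Iterable[VariantCallRecord], sample_ids: list, path,
              contig_lengths: Optional[dict] = None) -> None:
    """Write multi-sample VCF v4.2 with FORMAT GT:DP:AD:GQ.

    Absent per-sample fields are written as ``.``; a sample with no call at a
    site gets ``./.:.:.:.``.
    """
    records = list(records)
    if contig_lengths is None:
        contig_lengths = {}
        for r in records:
            contig_lengths[r.contig] = max(contig_lengths.get(r.contig, 0), r.pos + 1000)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    for contig, length in contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids))
    for r in records:
        alt = ",".join(r.alts) if r.alts else "."
        fields = [r.contig, str(r.pos), ".", r.ref, alt, ".", ".", ".", "GT:DP:AD:GQ"]
        for sid in sample_ids:
            c = r.calls.get(sid)
            if c is None:
                fields.append("./.:.:.:.")
                continue
            gt = "./." if c.gt is None else "/".join("." if a is None else str(a) for a in c.gt)
            dp = "." if c.dp is None else str(c.dp)
            ad = "." if c.ad is None else ",".join(str(x) for x in c.ad)
            gq = "." if c.gq is None else str(c.gq)
            fields.append(f"{gt}:{dp}:{ad}:{gq}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _norm_tuple(val):
    if val is None:
        return None
    tup = tuple(val) if isinstance(val, (tuple, list)) else (val,)
    if all(v is None for v in tup):
        return None
    return tup


def read_variant_calls(path) -> list:
    """Read a VCF into :class:`VariantCallRecord` list, file order preserved.

    Absent FORMAT fields surface as ``None``, never as zero.  Malformed input
    raises :class:`FormatError` naming the offending data line.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: malformed VCF header: {exc}") from exc
    out = []
    line_no = 0
    try:
        with vf:
            samples = list(vf.header.samples)
            for rec in vf:
                line_no += 1
                calls = {}
                for sid in samples:
                    s = rec.samples[sid]
                    gt = _norm_tuple(s.get("GT"))
                    dp = s.get("DP")
                    ad = _norm_tuple(s.get("AD"))
                    gq = s.get("GQ")
                    calls[sid] = SampleCall(
                        gt=gt,
                        dp=None if dp is None else int(dp),
                        ad=None if ad is None else tuple(int(x) for x in ad),
                        gq=None if gq is None else int(gq),
                    )
                out.append(
                    VariantCallRecord(
                        contig=rec.contig,
                        pos=rec.pos,  # pysam .pos is 1-based
                        ref=rec.ref,
                        alts=tuple(rec.alts) if rec.alts else (),
                        calls=calls,
                    )
                )
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: malformed VCF near data line {line_no + 1}: {exc}") from exc
    return out


# ---------------------------------------------------------------- taxonomic report

REPORT_COLUMNS = ["%", "reads", "taxReads", "kmers", "dup", "cov", "taxID", "rank", "taxName"]


def write_taxon_report(records: Iterable[TaxonRecord], path) -> None:
    rows = [
        {
            "%": r.pct,
            "reads": r.reads,
            "taxReads": r.tax_reads,
            "kmers": r.kmers,
            "dup": r.dup,
            "cov": r.coverage,
            "taxID": r.taxid,
            "rank": r.rank,
            "taxName": r.name,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_taxon_report(path) -> list:
    """Parse a KrakenUniq-style report TSV; rank strings preserved verbatim."""
    df = pd.read_csv(path, sep="\t", dtype={"rank": str, "taxName": str})
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory report column(s): {missing}")
    return [
        TaxonRecord(
            taxid=int(row["taxID"]),
            name=str(row["taxName"]),
            rank=str(row["rank"]),
            reads=int(row["reads"]),
            tax_reads=int(row["taxReads"]),
            kmers=int(row["kmers"]),
            coverage=float(row["cov"]),
            pct=float(row["%"]),
            dup=float(row["dup"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------- peptide tables

PEPTIDE_COLUMNS = [
    "sample_id", "sequence", "score", "psm_count", "modifications",
    "protein_accession", "protein_name", "taxon", "is_blank_hit",
]


def _mods_to_str(mods) -> str:
    return ";".join(f"{pos}:{t}" for pos, t in mods)


def _mods_from_str(s) -> list:
    if not s or (isinstance(s, float) and np.isnan(s)):
        return []
    out = []
    for part in str(s).split(";"):
        pos, t = part.split(":", 1)
        out.append((int(pos), t))
    return out


def write_peptide_table(records: Iterable[PeptideRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "sequence": r.sequence,
            "score": r.score,
            "psm_count": r.psm_count,
            "modifications": _mods_to_str(r.modifications),
            "protein_accession": r.protein_accession,
            "protein_name": r.protein_name,
            "taxon": r.taxon,
            "is_blank_hit": int(r.is_blank_hit),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PEPTIDE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peptide_table(path) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing peptide column(s): {missing}")
    return [
        PeptideRecord(
            sample_id=str(row["sample_id"]),
            sequence=str(row["sequence"]),
            score=float(row["score"]),
            psm_count=int(row["psm_count"]),
            modifications=_mods_from_str(row["modifications"]),
            protein_accession=str(row["protein_accession"]),
            protein_name=str(row["protein_name"]),
            taxon=str(row["taxon"]),
            is_blank_hit=bool(int(row["is_blank_hit"])),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------- aligned reads

READS_COLUMNS = ["read_id", "contig", "start", "mapq", "sequence"]


def write_reads_tsv(reads: Iterable[AlignedRead], path) -> None:
    rows = [
        {"read_id": r.read_id, "contig": r.contig, "start": r.start,
         "mapq": r.mapq, "sequence": r.sequence}
        for r in reads
    ]
    pd.DataFrame(rows, columns=READS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    missing = [c for c in READS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing reads column(s): {missing}")
    return [
        AlignedRead(
            read_id=str(row["read_id"]),
            contig=str(row["contig"]),
            start=int(row["start"]),
            mapq=int(row["mapq"]),
            sequence=str(row["sequence"]),
        )
        for _, row in df.iterrows()
    ]


def write_reads_sam(reads: Iterable[AlignedRead], path, reference_lengths: dict) -> None:
    """Write ungapped reads as SAM (full-match CIGAR)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.reference_id = out.header.references.index(r.contig)
            a.reference_start = r.start - 1  # SAM API is 0-based
            a.mapping_quality = r.mapq
            a.cigarstring = f"{len(r.sequence)}M"
            a.flag = 0
            out.write(a)


def read_reads_sam(path, min_mapq: int = 0):
    """Ingest ungapped alignments from SAM/BAM; reads with indels are skipped.

    Returns ``(reads, n_skipped_indel)``.
    """
    reads, skipped = [], 0
    with pysam.AlignmentFile(str(path)) as fh:
        for a in fh:
            if a.is_unmapped or a.mapping_quality < min_mapq:
                continue
            if any(op not in (0, 7, 8) for op, _ in (a.cigartuples or [])):
                skipped += 1
                continue
            reads.append(
                AlignedRead(
                    read_id=a.query_name,
                    contig=a.reference_name,
                    start=a.reference_start + 1,
                    mapq=a.mapping_quality,
                    sequence=a.query_sequence,
                )
            )
    return reads, skipped


# ---------------------------------------------------------------- alignments & trees

def write_alignment_fasta(alignment: SnpAlignment, path) -> None:
    """One FASTA record per sample, stable sample order, alphabet {A,C,G,T,N}."""
    with open(path, "w") as fh:
        for i, sid in enumerate(alignment.sample_ids):
            fh.write(f">{sid}\n{''.join(alignment.matrix[i])}\n")


def read_alignment_fasta(path):
    """Read a SNP alignment back as ``(sample_ids, matrix)`` (coords not stored)."""
    seqs = read_fasta(path)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise DataError(f"{path}: ragged alignment rows: lengths {sorted(lengths)}")
    matrix = np.array([list(s) for s in seqs.values()], dtype="<U1")
    return list(seqs), matrix


def write_phylip(alignment: SnpAlignment, path) -> None:
    with open(path, "w") as fh:
        fh.write(f" {alignment.n_samples} {alignment.n_sites}\n")
        for i, sid in enumerate(alignment.sample_ids):
            fh.write(f"{sid[:10]:<10} {''.join(alignment.matrix[i])}\n")


def write_newick(tree, path=None) -> str:
    """Serialise a dendropy Tree (or pass through a newick string); optionally to file."""
    if isinstance(tree, dendropy.Tree):
        s = tree.as_string(schema="newick", suppress_rooting=True).strip()
    else:
        s = str(tree).strip()
        dendropy.Tree.get(data=s, schema="newick")  # validate
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def read_newick(path_or_string) -> dendropy.Tree:
    s = str(path_or_string)
    if os.path.exists(s):
        with open(s) as fh:
            s = fh.read()
    try:
        return dendropy.Tree.get(data=s, schema="newick")
    except Exception as exc:
        raise FormatError(f"invalid newick: {exc}") from exc
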