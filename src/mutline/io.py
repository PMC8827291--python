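"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, VCF parsing through cyvcf2, GFF3 parsing
through gffutils; PAF (12 mandatory columns) and the simple TSV dialects
(depth, genotypes, cross-line evidence) are read with pandas or plain
splitting.  Every reader converts to the package-internal 0-based
half-open convention; every writer restores the external convention, so
reader/writer pairs are lossless round trips on valid input.
"""

from __future__ import annotations

import math
import os
from collections import defaultdict

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    DepthTrack,
    F2Plant,
    GeneModel,
    GenomeRef,
    PafAlignment,
    ParseError,
    VariantRecord,
)

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> GenomeRef:
    """Read a FASTA file into a :class:`GenomeRef`.

    Raises :class:`ParseError` for duplicate names, empty records or
    characters outside the IUPAC nucleotide alphabet (the error names
    the offending record and position).
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ParseError(f"duplicate sequence name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ParseError(f"no FASTA records found in {path}")
    return GenomeRef(sequences)  # alphabet/emptiness checked by the model


def write_fasta(genome: GenomeRef, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS features into :class:`GeneModel` objects."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="CDS", order_by="start")
        ]
        models.append(
            GeneModel(
                gene_id=gene.id,
                seq_name=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
                cds=cds,
            )
        )
    return models


def write_gff3(models: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            s, e = gm.start + 1, gm.end
            base = f"{gm.seq_name}\tmutline\t"
            tail = f"\t.\t{gm.strand}\t"
            fh.write(f"{base}gene\t{s}\t{e}{tail}.\tID={gm.gene_id}\n")
            mrna = f"{gm.gene_id}.t1"
            fh.write(
                f"{base}mRNA\t{s}\t{e}{tail}.\tID={mrna};Parent={gm.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(gm.exons, 1):
                fh.write(
                    f"{base}exon\t{xs + 1}\t{xe}{tail}.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
            for i, (cs, ce) in enumerate(gm.cds, 1):
                fh.write(
                    f"{base}CDS\t{cs + 1}\t{ce}{tail}0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# VCF


def left_normalize(
    genome: GenomeRef, seq_name: str, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Left-align and trim an allele pair against the reference.

    Standard normalization: trim shared trailing bases (extending to the
    left with the reference base when one allele would become empty),
    then trim shared leading bases.  SNVs pass through unchanged.
    """
    seq = genome[seq_name]
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif (
            len(ref) != len(alt)
            and ref
            and alt
            and ref[-1] == alt[-1]
            and pos > 0
        ):
            pos -= 1
            b = seq[pos]
            ref, alt = b + ref[:-1], b + alt[:-1]
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _fmt_int(value) -> int | None:
    if value is None:
        return None
    v = int(value)
    return None if v < 0 else v  # cyvcf2 encodes missing as negative


def read_vcf(
    path: str | os.PathLike,
    line_id: str | None = None,
    genome: GenomeRef | None = None,
) -> list[VariantRecord]:
    """Read a single-sample VCF into :class:`VariantRecord` objects.

    Multi-allelic lines are decomposed into one record per ALT, each
    flagged ``multiallelic``.  When ``genome`` is supplied, indels are
    left-normalized on ingest so that variant identity is comparable
    across per-line call sets.  Missing DP/AD become ``None`` (handled
    by the filter stages, not fatal here).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if line_id is None:
        line_id = vcf.samples[0] if vcf.samples else "sample"
    records: list[VariantRecord] = []
    for v in vcf:
        alts = list(v.ALT)
        if not alts:
            continue
        dp = None
        try:
            arr = v.format("DP")
            if arr is not None:
                dp = _fmt_int(arr[0][0])
        except KeyError:
            pass
        ad_row = None
        try:
            arr = v.format("AD")
            if arr is not None:
                ad_row = [_fmt_int(x) for x in arr[0]]
        except KeyError:
            pass
        multi = len(alts) > 1
        for i, alt in enumerate(alts):
            pos, ref = v.POS - 1, v.REF
            if genome is not None:
                pos, ref, alt = left_normalize(
                    genome, v.CHROM, pos, ref, alt
                )
            ad = None
            if ad_row is not None and ad_row[0] is not None:
                alt_count = ad_row[i + 1] if len(ad_row) > i + 1 else None
                if alt_count is not None:
                    ad = (ad_row[0], alt_count)
            records.append(
                VariantRecord(
                    line_id=line_id,
                    seq_name=v.CHROM,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    depth=dp,
                    allele_depths=ad,
                    multiallelic=multi,
                )
            )
    return records


def write_vcf(
    records: list[VariantRecord],
    path: str | os.PathLike,
    line_id: str | None = None,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write records as a minimal single-sample VCF 4.2 file.

    Consecutive records flagged ``multiallelic`` that share (seq, pos,
    ref) are re-composed into one multi-ALT line, restoring the shape
    they were decomposed from.
    """
    if line_id is None:
        line_id = records[0].line_id if records else "sample"
    groups: list[list[VariantRecord]] = []
    by_site: dict[tuple, int] = {}
    for rec in records:
        site = (rec.seq_name, rec.pos, rec.ref)
        if rec.multiallelic and site in by_site:
            groups[by_site[site]].append(rec)
        else:
            if rec.multiallelic:
                by_site[site] = len(groups)
            groups.append([rec])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
            "##FORMAT=<ID=AD,Number=R,Type=Integer,"
            'Description="Allele depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{line_id}\n"
        )
        for group in groups:
            first = group[0]
            alts = ",".join(r.alt for r in group)
            dp = "." if first.depth is None else str(first.depth)
            if all(r.allele_depths is not None for r in group):
                ad = ",".join(
                    [str(group[0].allele_depths[0])]
                    + [str(r.allele_depths[1]) for r in group]
                )
            else:
                ad = "."
            gt = "1/1" if len(group) == 1 else "1/2"
            fh.write(
                f"{first.seq_name}\t{first.pos + 1}\t.\t{first.ref}\t"
                f"{alts}\t.\tPASS\t.\tGT:DP:AD\t{gt}:{dp}:{ad}\n"
            )


# ---------------------------------------------------------------------------
# PAF


def read_paf(path: str | os.PathLike) -> list[PafAlignment]:
    """Read the 12 mandatory PAF columns (extra tags are ignored)."""
    blocks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{ln}: expected >= 12 PAF columns")
            try:
                blocks.append(
                    PafAlignment(
                        query_name=fields[0],
                        query_len=int(fields[1]),
                        qstart=int(fields[2]),
                        qend=int(fields[3]),
                        strand=fields[4],
                        target_name=fields[5],
                        target_len=int(fields[6]),
                        tstart=int(fields[7]),
                        tend=int(fields[8]),
                        matches=int(fields[9]),
                        block_len=int(fields[10]),
                        mapq=int(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
    return blocks


def write_paf(blocks: list[PafAlignment], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"{b.query_name}\t{b.query_len}\t{b.qstart}\t{b.qend}\t"
                f"{b.strand}\t{b.target_name}\t{b.target_len}\t{b.tstart}\t"
                f"{b.tend}\t{b.matches}\t{b.block_len}\t{b.mapq}\n"
            )


# ---------------------------------------------------------------------------
# depth TSV (samtools-depth dialect: seq_name, 1-based pos, depth)


def read_depth_tsv(
    path: str | os.PathLike,
    line_id: str,
    seq_lengths: dict[str, int] | None = None,
) -> list[DepthTrack]:
    """Read per-base depth.  Positions absent from the file are depth 0.

    ``seq_lengths`` fixes track lengths to the reference; without it each
    track ends at the last reported position.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["seq", "pos", "depth"]
    )
    tracks = []
    for seq, sub in df.groupby("seq", sort=False):
        length = (
            seq_lengths[str(seq)] if seq_lengths else int(sub["pos"].max())
        )
        arr = np.zeros(length, dtype=np.int64)
        pos = sub["pos"].to_numpy() - 1
        if (pos < 0).any() or (pos >= length).any():
            raise ParseError(f"{path}: position outside sequence {seq!r}")
        arr[pos] = sub["depth"].to_numpy()
        tracks.append(DepthTrack(line_id=line_id, seq_name=str(seq), depth=arr))
    return tracks


def write_depth_tsv(
    tracks: list[DepthTrack], path: str | os.PathLike
) -> None:
    """Write every base (including zeros), like ``samtools depth -a``."""
    with open(path, "w") as fh:
        for track in tracks:
            for i, d in enumerate(track.depth, 1):
                fh.write(f"{track.seq_name}\t{i}\t{d}\n")


# ---------------------------------------------------------------------------
# genotype / evidence TSV


def read_genotype_tsv(path: str | os.PathLike) -> list[F2Plant]:
    """Read a plant table: plant_id, phenotype, one column per marker."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["plant_id", "phenotype"]:
        raise ParseError(
            f"{path}: first columns must be plant_id and phenotype"
        )
    markers = list(df.columns[2:])
    return [
        F2Plant(
            plant_id=row["plant_id"],
            phenotype=row["phenotype"],
            genotypes={m: row[m] for m in markers},
        )
        for _, row in df.iterrows()
    ]


def write_genotype_tsv(
    plants: list[F2Plant], path: str | os.PathLike
) -> None:
    markers = list(plants[0].genotypes) if plants else []
    with open(path, "w") as fh:
        fh.write("\t".join(["plant_id", "phenotype"] + markers) + "\n")
        for p in plants:
            fh.write(
                "\t".join(
                    [p.plant_id, p.phenotype]
                    + [p.genotypes[m] for m in markers]
                )
                + "\n"
            )


def read_evidence_tsv(
    path: str | os.PathLike,
) -> dict[tuple[str, int, str], dict[str, int]]:
    """Read the cross-line alt-read evidence table.

    Columns: seq_name, 1-based pos, alt, line_id, alt_reads.  This is the
    automated stand-in for inspecting alignments of the *other* lines at
    a candidate site.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["seq", "pos", "alt", "line", "alt_reads"],
    )
    evidence: dict[tuple[str, int, str], dict[str, int]] = defaultdict(dict)
    for _, row in df.iterrows():
        evidence[(str(row["seq"]), int(row["pos"]) - 1, str(row["alt"]))][
            str(row["line"])
        ] = int(row["alt_reads"])
    return dict(evidence)


def write_evidence_tsv(
    evidence: dict[tuple[str, int, str], dict[str, int]],
    path: str | os.PathLike,
) -> None:
    with open(path, "w") as fh:
        for (seq, pos, alt), per_line in sorted(evidence.items()):
            for line, n in sorted(per_line.items()):
                fh.write(f"{seq}\t{pos + 1}\t{alt}\t{line}\t{n}\n")


# ---------------------------------------------------------------------------
# coverage arithmetic


def coverage_fold(total_bases: float, genome_size: float) -> int:
    """Fold coverage = total sequenced bases over genome size, rounded
    half away from zero (so 22.15 -> 22 and 28.37 -> 28, matching the
    convention used when reporting long-read yields)."""
    if total_bases <= 0 or genome_size <= 0:
        raise ValueError("total_bases and genome_size must be positive")
    return int(math.floor(total_bases / genome_size + 0.5))
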