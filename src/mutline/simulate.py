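"""Synthetic genomes, mutant lines and F2 populations with known truth.

The generator emulates the study design this package targets: a small
annotated reference, a wild-type parent, and several induced mutant
lines each carrying exactly one planted causal coding mutation (SNV,
1-bp frameshift deletion, 3-bp in-frame deletion, or a multi-kb
deletion) on a background of parent-vs-reference polymorphisms shared by
all lines plus per-line noise calls.  Variant calls are generated
directly at the VCF level (no read simulation); read-level reality
enters only through the DP/AD fields, the depth tracks, the split
long-read alignments and the cross-line alt-read evidence table.

Every causal coding mutation is verified against the consequence
classifier at generation time, and noise is constructed so that each
filter stage removes a predictable, non-empty subset — so downstream
stage counts can be checked exactly against set arithmetic on the
returned :class:`TruthSet`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .consequence import classify_variant, spliced_index
from .model import (
    DeletionTruth,
    DepthTrack,
    F2Plant,
    GeneModel,
    GenomeRef,
    MutlineError,
    PafAlignment,
    RunConfig,
    TruthSet,
    VariantRecord,
)

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

MUTATION_CLASSES = (
    "synonymous_snv",
    "missense_snv",
    "stop_gain_snv",
    "frameshift_del1",
    "inframe_del3",
    "large_deletion",
)

#: per-line noise composition of the default fixture; with the shared
#: records contributed by the partner line and ~60 background variants
#: this yields >= 200 records per line, and every filter stage removes
#: at least one record.
NOISE_COUNTS = {
    "non_cds": 70,
    "shared_cds": 8,  # initiated per line, mirrored into a partner line
    "multiallelic": 10,  # sites; each decomposes into two records
    "low_depth": 10,
    "missing_dp": 5,
    "low_af": 10,
    "missing_ad": 5,
    "cross_line": 5,
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + one stop; translates cleanly."""
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + str(rng.choice(list(_STOPS)))


def _split_lengths(
    rng: np.random.Generator, total: int, parts: int, minimum: int = 3
) -> list[int]:
    """Partition ``total`` into ``parts`` chunks, each >= minimum."""
    if total < parts * minimum:
        raise MutlineError(f"cannot split {total} into {parts} parts")
    extra = rng.multinomial(total - parts * minimum, np.ones(parts) / parts)
    return [minimum + int(x) for x in extra]


def make_reference(
    seed: int,
    n_seqs: int = 1,
    seq_length: int = 200_000,
    n_genes: int = 20,
    exons_per_gene: int = 4,
    codon_range: tuple[int, int] = (150, 450),
    intron_range: tuple[int, int] = (60, 200),
) -> tuple[GenomeRef, list[GeneModel]]:
    """Build a random annotated reference.

    Genes are placed without overlap, on both strands, with CDS equal to
    the exon intervals (no UTRs); every spliced CDS starts with ATG, ends
    with a stop and contains no internal stop.  Deterministic for a fixed
    seed.  Raises when the genes cannot be packed into ``seq_length``.
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    models: list[GeneModel] = []
    per_seq = [n_genes // n_seqs + (i < n_genes % n_seqs) for i in range(n_seqs)]
    gene_no = 0
    for si in range(n_seqs):
        name = f"chr{si + 1}"
        background = list(_random_seq(rng, seq_length))
        plans = []
        for _ in range(per_seq[si]):
            n_codons = int(rng.integers(*codon_range))
            coding = _random_coding(rng, n_codons)
            exon_lens = _split_lengths(rng, len(coding), exons_per_gene)
            introns = [
                int(rng.integers(*intron_range))
                for _ in range(exons_per_gene - 1)
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            plans.append((coding, exon_lens, introns, strand))
        total_gene = sum(len(c) + sum(i) for c, _, i, _ in plans)
        n_gaps = per_seq[si] + 1
        min_gap = 100
        free = seq_length - total_gene - n_gaps * min_gap
        if free < 0:
            raise MutlineError(
                f"{name}: need at least {total_gene + n_gaps * min_gap} bp "
                f"to place {per_seq[si]} genes, have {seq_length}"
            )
        gaps = [
            min_gap + int(g)
            for g in rng.multinomial(free, np.ones(n_gaps) / n_gaps)
        ]
        cursor = 0
        for (coding, exon_lens, introns, strand), gap in zip(plans, gaps):
            cursor += gap
            start = cursor
            genomic = (
                coding
                if strand == "+"
                else str(Seq(coding).reverse_complement())
            )
            chunk_lens = exon_lens if strand == "+" else exon_lens[::-1]
            exons, off, pos = [], 0, start
            for i, ln in enumerate(chunk_lens):
                background[pos : pos + ln] = genomic[off : off + ln]
                exons.append((pos, pos + ln))
                off += ln
                pos += ln
                if i < len(introns):
                    pos += introns[i]
            gene_no += 1
            models.append(
                GeneModel(
                    gene_id=f"gene_{gene_no:04d}",
                    seq_name=name,
                    strand=strand,
                    start=start,
                    end=pos,
                    exons=exons,
                    cds=list(exons),
                )
            )
            cursor = pos
        sequences[name] = "".join(background)
    return GenomeRef(sequences), models


def genomic_position(gene: GeneModel, spliced_pos: int) -> int:
    """Reference (0-based) position of 1-based spliced-CDS coordinate."""
    if not (1 <= spliced_pos <= gene.spliced_cds_length):
        raise ValueError("spliced position outside CDS")
    idx = spliced_pos - 1
    if gene.strand == "-":
        idx = gene.spliced_cds_length - 1 - idx
    off = 0
    for s, e in gene.cds:
        if idx < off + (e - s):
            return s + (idx - off)
        off += e - s
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# the worked fixture echoing the NIN-like candidate gene


def nin_like_gene_fixture(
    seed: int = 11,
) -> tuple[GenomeRef, GeneModel, VariantRecord, list[tuple[str, int, int]]]:
    """A four-exon gene with a 2889 nt spliced CDS and a planted 1-bp
    deletion at spliced CDS position 2189 (CAA -> CA_), sitting between
    an upstream DNA-binding domain and a downstream protein-interaction
    domain.  Returns (genome, gene, variant, domains).

    The published full-length gene is 3216 bp; with three 109 bp introns
    the CDS here is 2889 bp (963 codons) — the nearest multiple of three
    to the printed CDS length.
    """
    rng = np.random.default_rng(seed)
    n_codons = 963
    codons = list(rng.choice(_SENSE_CODONS, size=n_codons - 2))
    coding = ["ATG"] + codons + ["TAA"]
    # codon 730 covers spliced bases 2188-2190; make it CAA so deleting
    # the base at 2189 is the published CAA -> CA_ event, and keep the
    # preceding base != A so left-normalization cannot shift the record.
    coding[729] = "CAA"
    coding = "".join(coding)
    exon_lens = [500, 500, 700, 1189]
    intron_len = 109
    flank = 5000
    gene_start = flank
    pieces, exons, pos = [], [], gene_start
    off = 0
    for i, ln in enumerate(exon_lens):
        pieces.append(coding[off : off + ln])
        exons.append((pos, pos + ln))
        off += ln
        pos += ln
        if i < 3:
            pieces.append(_random_seq(rng, intron_len))
            pos += intron_len
    gene_end = pos
    seq = (
        _random_seq(rng, flank)
        + "".join(pieces)
        + _random_seq(rng, flank)
    )
    genome = GenomeRef({"chr1": seq})
    gene = GeneModel(
        gene_id="nin_like",
        seq_name="chr1",
        strand="+",
        start=gene_start,
        end=gene_end,
        exons=exons,
        cds=list(exons),
    )
    p = genomic_position(gene, 2189)
    variant = VariantRecord(
        line_id="mut_fs",
        seq_name="chr1",
        pos=p - 1,
        ref=seq[p - 1 : p + 1],
        alt=seq[p - 1],
        depth=30,
        allele_depths=(0, 30),
        notes={"planted": "causal", "class": "frameshift_del1"},
    )
    domains = [("RWP-RK", 520, 580), ("PB1", 790, 860)]
    return genome, gene, variant, domains


# ---------------------------------------------------------------------------
# mutation planting


class _PositionPool:
    """Tracks occupied reference positions so planted records never
    collide (a +/- 3 bp pad keeps normalized keys distinct)."""

    def __init__(self) -> None:
        self.used: dict[str, set[int]] = {}

    def reserve(self, seq: str, start: int, end: int, pad: int = 3) -> None:
        self.used.setdefault(seq, set()).update(range(start - pad, end + pad))

    def free(self, seq: str, start: int, end: int) -> bool:
        taken = self.used.get(seq, set())
        return not any(p in taken for p in range(start, end))


def _snv_candidates(gene: GeneModel, genome: GenomeRef, cls: str, rng):
    """Spliced positions + alt bases yielding the requested SNV class,
    decided at the codon level (the classifier re-verifies each pick)."""
    cds = "".join(genome[gene.seq_name][s:e] for s, e in gene.cds)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    n_codons = len(cds) // 3
    order = rng.permutation(n_codons - 2) + 1  # skip start and stop codons
    for ci in order:
        codon = cds[3 * ci : 3 * ci + 3]
        for k in range(3):
            for alt in "ACGT":
                if alt == codon[k]:
                    continue
                new = codon[:k] + alt + codon[k + 1 :]
                ref_aa = str(Seq(codon).translate())
                new_aa = str(Seq(new).translate())
                ok = (
                    (cls == "synonymous_snv" and new_aa == ref_aa)
                    or (
                        cls == "missense_snv"
                        and new_aa != ref_aa
                        and new_aa != "*"
                    )
                    or (cls == "stop_gain_snv" and new_aa == "*")
                )
                if ok:
                    yield 3 * ci + k + 1, alt  # 1-based spliced pos


def _complement(base: str) -> str:
    return str(Seq(base).complement())


def _make_causal(
    line: str,
    cls: str,
    gene: GeneModel,
    genome: GenomeRef,
    pool: _PositionPool,
    rng: np.random.Generator,
) -> VariantRecord:
    seq = genome[gene.seq_name]
    if cls.endswith("_snv"):
        for spos, alt_tx in _snv_candidates(gene, genome, cls, rng):
            p = genomic_position(gene, spos)
            if not pool.free(gene.seq_name, p, p + 1):
                continue
            alt = alt_tx if gene.strand == "+" else _complement(alt_tx)
            rec = VariantRecord(
                line_id=line,
                seq_name=gene.seq_name,
                pos=p,
                ref=seq[p],
                alt=alt,
                notes={"planted": "causal", "class": cls},
            )
            if classify_variant(rec, gene, genome).effect == cls[:-4]:
                pool.reserve(gene.seq_name, p, p + 1)
                return rec
        raise MutlineError(f"{gene.gene_id}: no site admits class {cls}")
    if cls == "frameshift_del1":
        length = gene.spliced_cds_length
        for spos in rng.permutation(np.arange(4, length - 3)) + 0:
            p = genomic_position(gene, int(spos))
            if p == 0 or seq[p - 1] == seq[p]:
                continue  # left-normalization would shift the record
            if not pool.free(gene.seq_name, p - 1, p + 1):
                continue
            rec = VariantRecord(
                line_id=line,
                seq_name=gene.seq_name,
                pos=p - 1,
                ref=seq[p - 1 : p + 1],
                alt=seq[p - 1],
                notes={"planted": "causal", "class": cls},
            )
            if classify_variant(rec, gene, genome).effect == "frameshift":
                pool.reserve(gene.seq_name, p - 1, p + 1)
                return rec
        raise MutlineError(f"{gene.gene_id}: no site admits class {cls}")
    if cls == "inframe_del3":
        n_codons = gene.spliced_cds_length // 3
        for ci in rng.permutation(n_codons - 2) + 1:
            positions = sorted(
                genomic_position(gene, 3 * int(ci) + k + 1) for k in range(3)
            )
            a, b = positions[0], positions[-1] + 1
            if b - a != 3:  # codon split across an intron
                continue
            if a == 0 or seq[a - 1] == seq[b - 1]:
                continue  # normalization guard
            if not pool.free(gene.seq_name, a - 1, b):
                continue
            rec = VariantRecord(
                line_id=line,
                seq_name=gene.seq_name,
                pos=a - 1,
                ref=seq[a - 1 : b],
                alt=seq[a - 1],
                notes={"planted": "causal", "class": cls},
            )
            if classify_variant(rec, gene, genome).effect == "inframe_deletion":
                pool.reserve(gene.seq_name, a - 1, b)
                return rec
        raise MutlineError(f"{gene.gene_id}: no site admits class {cls}")
    raise ValueError(f"unknown mutation class {cls!r}")


def _make_large_deletion(
    line: str,
    gene_models: list[GeneModel],
    genome: GenomeRef,
    rng: np.random.Generator,
    target_len: int,
    min_len: int,
) -> DeletionTruth:
    """Widest interval fully containing one gene and no others, capped
    at ``target_len``; errors when no gene has ``min_len`` clearance."""
    best = None
    by_seq: dict[str, list[GeneModel]] = {}
    for gm in gene_models:
        by_seq.setdefault(gm.seq_name, []).append(gm)
    for seq_name, genes in by_seq.items():
        genes = sorted(genes, key=lambda g: g.start)
        length = len(genome[seq_name])
        for i, g in enumerate(genes):
            lo = genes[i - 1].end + 1 if i > 0 else 0
            hi = genes[i + 1].start - 1 if i + 1 < len(genes) else length
            room = hi - lo
            span = max(min(target_len, room), g.end - g.start + 2)
            if span > room or span < min_len:
                continue
            s_lo = max(lo, g.end - span)
            s_hi = min(g.start, hi - span)
            if s_lo > s_hi:
                continue
            start = (s_lo + s_hi) // 2  # centred on the gene's clearance
            cand = (span, g.gene_id, seq_name, start, start + span)
            if best is None or cand[0] > best[0]:
                best = cand
    if best is None or best[0] < min_len:
        raise MutlineError(
            f"no gene has >= {min_len} bp of single-gene clearance"
        )
    _, gene_id, seq_name, start, end = best
    return DeletionTruth(
        line_id=line,
        seq_name=seq_name,
        start=int(start),
        end=int(end),
        deleted_genes=[gene_id],
    )


def _random_cds_snv(
    line, gene_models, genome, pool, rng, note
) -> VariantRecord:
    while True:
        gm = gene_models[int(rng.integers(len(gene_models)))]
        s, e = gm.cds[int(rng.integers(len(gm.cds)))]
        p = int(rng.integers(s, e))
        if not pool.free(gm.seq_name, p, p + 1):
            continue
        ref = genome[gm.seq_name][p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        pool.reserve(gm.seq_name, p, p + 1)
        return VariantRecord(
            line_id=line,
            seq_name=gm.seq_name,
            pos=p,
            ref=ref,
            alt=alt,
            notes={"planted": note},
        )


def _random_noncds_snv(
    line, gene_models, genome, pool, rng
) -> VariantRecord:
    spans = {}
    for gm in gene_models:
        spans.setdefault(gm.seq_name, []).append((gm.start, gm.end))
    names = sorted(genome.sequences)
    while True:
        seq_name = names[int(rng.integers(len(names)))]
        p = int(rng.integers(0, len(genome[seq_name])))
        if any(s <= p < e for s, e in spans.get(seq_name, [])):
            continue
        if not pool.free(seq_name, p, p + 1):
            continue
        ref = genome[seq_name][p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        pool.reserve(seq_name, p, p + 1)
        return VariantRecord(
            line_id=line,
            seq_name=seq_name,
            pos=p,
            ref=ref,
            alt=alt,
            notes={"planted": "non_cds"},
        )


def plant_mutations(
    genome: GenomeRef,
    gene_models: list[GeneModel],
    lines_spec: dict[str, str],
    seed: int,
    wt_line: str = "WT",
    deletion_len: int = 35_000,
    deletion_min_len: int = 5_000,
    n_background: int = 60,
    noise_counts: dict[str, int] | None = None,
) -> TruthSet:
    """Plant one causal mutation per mutant line plus shared background
    polymorphisms and per-line noise designed to exercise every filter
    stage.  Causal coding mutations are re-verified with the consequence
    classifier before being accepted.
    """
    rng = np.random.default_rng(seed)
    noise_counts = dict(NOISE_COUNTS, **(noise_counts or {}))
    pool = _PositionPool()
    lines = sorted(lines_spec)
    causal: dict[str, object] = {}

    # deletion first so no other variant is planted inside it
    del_lines = [l for l in lines if lines_spec[l] == "large_deletion"]
    for line in del_lines:
        truth = _make_large_deletion(
            line, gene_models, genome, rng, deletion_len, deletion_min_len
        )
        pool.reserve(truth.seq_name, truth.start, truth.end)
        causal[line] = truth

    genes_by_line: dict[str, GeneModel] = {}
    deleted = {g for l in del_lines for g in causal[l].deleted_genes}
    available = [g for g in gene_models if g.gene_id not in deleted]
    order = rng.permutation(len(available))
    gi = 0
    for line in lines:
        cls = lines_spec[line]
        if cls == "large_deletion":
            continue
        if cls not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {cls!r} for {line}")
        genes_by_line[line] = available[int(order[gi])]
        gi += 1
        causal[line] = _make_causal(
            line, cls, genes_by_line[line], genome, pool, rng
        )

    background = []
    for i in range(n_background):
        if i % 3 == 0:
            rec = _random_cds_snv(
                "*", gene_models, genome, pool, rng, "background"
            )
        else:
            rec = _random_noncds_snv("*", gene_models, genome, pool, rng)
        rec.notes["planted"] = "background"
        background.append(rec)

    all_lines = lines + [wt_line]
    noise: dict[str, list[VariantRecord]] = {l: [] for l in all_lines}
    evidence: dict[tuple[str, int, str], dict[str, int]] = {}
    for li, line in enumerate(all_lines):
        for _ in range(noise_counts["non_cds"]):
            noise[line].append(
                _random_noncds_snv(line, gene_models, genome, pool, rng)
            )
        for _ in range(noise_counts["shared_cds"]):
            # deterministic cyclic partner: every line both initiates and
            # receives the same number of shared (non-unique) records
            partner = all_lines[(li + 1) % len(all_lines)]
            rec = _random_cds_snv(
                line, gene_models, genome, pool, rng, "shared_cds"
            )
            noise[line].append(rec)
            noise[partner].append(
                dataclasses.replace(
                    rec, line_id=partner, notes=dict(rec.notes)
                )
            )
        for _ in range(noise_counts["multiallelic"]):
            rec = _random_cds_snv(
                line, gene_models, genome, pool, rng, "multiallelic"
            )
            rec.multiallelic = True
            other = str(
                rng.choice(
                    [b for b in "ACGT" if b not in (rec.ref, rec.alt)]
                )
            )
            twin = dataclasses.replace(
                rec, alt=other, notes=dict(rec.notes)
            )
            noise[line].extend([rec, twin])
        for tag in ("low_depth", "missing_dp", "low_af", "missing_ad"):
            for _ in range(noise_counts[tag]):
                noise[line].append(
                    _random_cds_snv(line, gene_models, genome, pool, rng, tag)
                )
        for _ in range(noise_counts["cross_line"]):
            rec = _random_cds_snv(
                line, gene_models, genome, pool, rng, "cross_line"
            )
            noise[line].append(rec)
            others = [l for l in all_lines if l != line]
            witness = others[int(rng.integers(len(others)))]
            evidence[(rec.seq_name, rec.pos, rec.alt)] = {witness: 1}

    return TruthSet(
        causal=causal,
        background=background,
        noise=noise,
        cross_line_evidence=evidence,
    )


# ---------------------------------------------------------------------------
# variant-call emission


def _good_dp_ad(rng, mean) -> tuple[int, tuple[int, int]]:
    dp = max(3, int(rng.poisson(mean)))
    r = int(rng.integers(0, int(dp * 0.1) + 1))
    return dp, (r, dp - r)


def simulate_variant_calls(
    truth: TruthSet,
    depth_model: dict[str, float] | float = 12.0,
    seed: int = 0,
) -> dict[str, list[VariantRecord]]:
    """Emit per-line call sets with DP/AD evidence drawn from the noise
    category each record was planted for.

    Causal, background, shared and cross-line records receive depth >= 3
    with alternate-allele fraction >= 0.9 (homozygous induced mutations);
    the remaining categories receive evidence that fails exactly one
    filter stage.  Cross-line evidence entries are *not* emitted as calls
    in the witnessing line.
    """
    rng = np.random.default_rng(seed)
    lines = sorted(truth.noise)
    calls: dict[str, list[VariantRecord]] = {}
    for line in lines:
        mean = (
            depth_model.get(line, 12.0)
            if isinstance(depth_model, dict)
            else depth_model
        )
        records: list[VariantRecord] = []
        for bg in truth.background:
            records.append(
                dataclasses.replace(bg, line_id=line, notes=dict(bg.notes))
            )
        causal = truth.causal.get(line)
        if isinstance(causal, VariantRecord):
            records.append(
                dataclasses.replace(causal, notes=dict(causal.notes))
            )
        records.extend(
            dataclasses.replace(r, notes=dict(r.notes))
            for r in truth.noise[line]
        )
        out = []
        i = 0
        while i < len(records):
            rec = records[i]
            tag = rec.notes.get("planted", "background")
            if tag == "multiallelic":
                twin = records[i + 1]
                dp = max(4, int(rng.poisson(mean)))
                a1 = dp // 2
                a2 = max(1, dp - a1)
                rec.depth = twin.depth = dp
                rec.allele_depths = (0, a1)
                twin.allele_depths = (0, a2)
                out.extend([rec, twin])
                i += 2
                continue
            if tag == "low_depth":
                dp = int(rng.integers(0, 2))
                rec.depth, rec.allele_depths = dp, (0, dp)
            elif tag == "missing_dp":
                rec.depth, rec.allele_depths = None, (0, 3)
            elif tag == "low_af":
                dp = max(6, int(rng.poisson(mean)))
                hi = int(0.85 * dp)
                a = int(rng.integers(max(1, dp // 3), max(2, hi + 1)))
                a = min(a, hi) or 1
                rec.depth, rec.allele_depths = dp, (dp - a, a)
            elif tag == "missing_ad":
                rec.depth = max(3, int(rng.poisson(mean)))
                rec.allele_depths = None
            else:  # causal / background / shared_cds / non_cds / cross_line
                rec.depth, rec.allele_depths = _good_dp_ad(rng, mean)
            out.append(rec)
            i += 1
        out.sort(key=lambda r: (r.seq_name, r.pos, r.alt))
        calls[line] = out
    return calls


# ---------------------------------------------------------------------------
# depth tracks and long-read alignments


def simulate_depth_tracks(
    genome: GenomeRef,
    deletions: dict[str, DeletionTruth | None],
    mean_depth: float = 20.0,
    noise_sd: float = 3.0,
    seed: int = 0,
    edge_bleed_bp: int = 0,
) -> dict[str, list[DepthTrack]]:
    """Gaussian-rounded per-base depth per line; a line's deleted
    interval drops to zero (with optional noisy edge bleed of at most
    ``edge_bleed_bp`` per side)."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    tracks: dict[str, list[DepthTrack]] = {}
    for line in sorted(deletions):
        per_line = []
        for seq_name in sorted(genome.sequences):
            length = len(genome[seq_name])
            depth = np.clip(
                np.rint(rng.normal(mean_depth, noise_sd, length)), 0, None
            ).astype(np.int64)
            truth = deletions[line]
            if truth is not None and truth.seq_name == seq_name:
                depth[truth.start : truth.end] = 0
                for edge in (truth.start, truth.end):
                    bleed = int(rng.integers(0, edge_bleed_bp + 1))
                    if bleed and edge == truth.start:
                        depth[edge : edge + bleed] = rng.integers(
                            0, 3, bleed
                        )
                    elif bleed:
                        depth[edge - bleed : edge] = rng.integers(
                            0, 3, bleed
                        )
            per_line.append(
                DepthTrack(line_id=line, seq_name=seq_name, depth=depth)
            )
        tracks[line] = per_line
    return tracks


def simulate_long_read_alignments(
    genome: GenomeRef,
    deletion: DeletionTruth,
    n_spanning: int = 3,
    read_len_dist: tuple[float, float] = (20_000.0, 5_000.0),
    seed: int = 0,
    allele: str = "mutant",
    n_flank_reads: int = 6,
    max_query_gap: int = 20,
) -> list[PafAlignment]:
    """PAF blocks for long reads over the deletion locus.

    For the mutant allele each deletion-spanning read yields exactly two
    blocks, adjacent on the query (gap <= ``max_query_gap``) with target
    intervals flanking the deleted interval — the split-read signature.
    For the wild-type allele spanning reads align as single contiguous
    blocks.  Non-spanning reads land entirely within one flank.
    """
    if allele not in ("mutant", "wildtype"):
        raise ValueError("allele must be 'mutant' or 'wildtype'")
    rng = np.random.default_rng(seed)
    seq_name = deletion.seq_name
    tlen = len(genome[seq_name])
    mean, sd = read_len_dist
    blocks: list[PafAlignment] = []

    def _arm(minimum=1000):
        return max(minimum, int(rng.normal(mean / 2, sd / 2)))

    for i in range(n_spanning):
        name = f"{deletion.line_id}_{allele}_span_{i + 1}"
        left = min(_arm(), deletion.start)
        right = min(_arm(), tlen - deletion.end)
        if allele == "wildtype":
            qlen = left + (deletion.end - deletion.start) + right
            blocks.append(
                PafAlignment(
                    name, qlen, 0, qlen, "+", seq_name, tlen,
                    deletion.start - left, deletion.end + right,
                    qlen, qlen, 60,
                )
            )
            continue
        gap = int(rng.integers(0, max_query_gap + 1))
        qlen = left + gap + right
        blocks.append(
            PafAlignment(
                name, qlen, 0, left, "+", seq_name, tlen,
                deletion.start - left, deletion.start, left, left, 60,
            )
        )
        blocks.append(
            PafAlignment(
                name, qlen, left + gap, qlen, "+", seq_name, tlen,
                deletion.end, deletion.end + right, right, right, 60,
            )
        )
    for i in range(n_flank_reads):
        name = f"{deletion.line_id}_{allele}_flank_{i + 1}"
        ln = max(2000, int(rng.normal(mean, sd)))
        if i % 2 == 0 and deletion.start > ln + 1:
            start = int(rng.integers(0, deletion.start - ln))
        elif tlen - deletion.end > ln + 1:
            start = int(rng.integers(deletion.end, tlen - ln))
        else:
            continue
        blocks.append(
            PafAlignment(
                name, ln, 0, ln, "+", seq_name, tlen,
                start, start + ln, ln, ln, 60,
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# F2 populations


def simulate_f2(
    n_plants: int,
    r: float,
    dominance: str = "wt_dominant",
    seed: int = 0,
    causal_marker: str = "causal",
    linked_marker: str = "linked",
) -> list[F2Plant]:
    """Selfed-F1 progeny segregating at two loci with recombination
    fraction ``r`` per gamete (no interference; double recombinants
    allowed).  The wild-type allele at the causal locus is dominant, so
    only causal homozygous-mutant plants show the mutant phenotype.
    """
    if not (0.0 <= r <= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    if dominance != "wt_dominant":
        raise ValueError("only a dominant wild-type allele is modelled")
    rng = np.random.default_rng(seed)
    classes = ("hom_wt", "het", "hom_mut")
    plants = []
    for i in range(n_plants):
        causal_mut = 0
        linked_mut = 0
        for _ in range(2):  # two independent gametes
            hap = int(rng.integers(0, 2))  # 1 = mutant haplotype
            recomb = rng.random() < r
            causal_mut += hap
            linked_mut += hap ^ recomb
        phenotype = (
            "non_nodulating" if causal_mut == 2 else "nodulating"
        )
        plants.append(
            F2Plant(
                plant_id=str(i + 1),
                phenotype=phenotype,
                genotypes={
                    causal_marker: classes[causal_mut],
                    linked_marker: classes[linked_mut],
                },
            )
        )
    return plants


# ---------------------------------------------------------------------------
# the default end-to-end fixture


@dataclass
class SimBundle:
    """Everything the default synthetic world produces."""

    genome: GenomeRef
    gene_models: list[GeneModel]
    truth: TruthSet
    calls: dict[str, list[VariantRecord]]
    config: RunConfig
    wt_line: str = "WT"

    @property
    def mutant_lines(self) -> list[str]:
        return sorted(self.truth.causal)


DEFAULT_LINES_SPEC = {
    "M1": "synonymous_snv",
    "M2": "missense_snv",
    "M3": "stop_gain_snv",
    "M4": "frameshift_del1",
    "M5": "inframe_del3",
    "M6": "large_deletion",
}


def default_fixture(seed: int = 0) -> SimBundle:
    """The stated synthetic world used by the end-to-end checks: one
    500 kb sequence carrying 50 four-exon genes, a wild-type parent and
    six mutant lines whose causal mutations span all six classes, with
    >= 200 background/noise records per line."""
    genome, genes = make_reference(
        seed, n_seqs=1, seq_length=500_000, n_genes=50, exons_per_gene=4
    )
    truth = plant_mutations(
        genome, genes, DEFAULT_LINES_SPEC, seed=seed + 1
    )
    calls = simulate_variant_calls(truth, depth_model=12.0, seed=seed + 2)
    return SimBundle(
        genome=genome,
        gene_models=genes,
        truth=truth,
        calls=calls,
        config=RunConfig(seed=seed),
    )
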