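"""Variant-consequence classification on single-transcript gene models.

Given a gene model and the reference, each candidate variant is mapped
into spliced-CDS coordinates, the mutant CDS is reconstructed, and both
alleles are translated (standard nuclear genetic code) to decide among
synonymous / missense / stop_gain / stop_loss / in-frame indel /
frameshift.  Frameshift is decided by the net coding-length change mod 3
and takes precedence over any downstream stop it introduces.  Proteins
are compared after truncation at the first stop codon, and user-supplied
protein-domain intervals are flagged as lost when the domain's amino-acid
stretch is no longer identically present in the mutant protein.
"""

from __future__ import annotations

from Bio.Seq import Seq

from .model import (
    ConsequenceCall,
    GeneModel,
    GenomeRef,
    MutlineError,
    VariantRecord,
)


class NonCodingVariant(MutlineError):
    """Raised by :func:`cds_coordinate` for variants outside the CDS."""


def splice_cds(genome: GenomeRef, gene: GeneModel) -> str:
    """Concatenate the CDS slices in transcription order.

    For a minus-strand gene this is the reverse complement of the
    left-to-right concatenation of its CDS intervals.
    """
    seq = genome[gene.seq_name]
    forward = "".join(seq[s:e] for s, e in gene.cds)
    if gene.strand == "-":
        return str(Seq(forward).reverse_complement())
    return forward


def _plus_offsets(gene: GeneModel) -> list[tuple[int, int, int]]:
    """(start, end, spliced-offset-of-start) per CDS interval, + strand."""
    out, off = [], 0
    for s, e in gene.cds:
        out.append((s, e, off))
        off += e - s
    return out


def _plus_index(gene: GeneModel, pos: int) -> int | None:
    """0-based index of reference base ``pos`` in the left-to-right CDS
    concatenation, or None when the base is not coding."""
    for s, e, off in _plus_offsets(gene):
        if s <= pos < e:
            return off + (pos - s)
    return None


def spliced_index(gene: GeneModel, pos: int) -> int | None:
    """0-based strand-oriented spliced-CDS index of reference base ``pos``."""
    idx = _plus_index(gene, pos)
    if idx is None:
        return None
    if gene.strand == "-":
        return gene.spliced_cds_length - 1 - idx
    return idx


def cds_coordinate(variant: VariantRecord, gene: GeneModel) -> int:
    """1-based spliced-CDS position of the first altered base.

    "First" is in transcription order; for a pure insertion the position
    of the first coding base 3' of the insertion point is reported.
    Raises :class:`NonCodingVariant` when no altered base is coding.
    """
    a, b = variant.altered_interval()
    coding = [
        spliced_index(gene, p)
        for p in range(a, b)
        if spliced_index(gene, p) is not None
    ]
    if coding:
        return min(coding) + 1
    if a == b:  # insertion: look at the flanking bases
        flank = [
            spliced_index(gene, p)
            for p in (a - 1, a)
            if 0 <= p and spliced_index(gene, p) is not None
        ]
        if flank:
            return min(flank) + 1
    raise NonCodingVariant(
        f"variant at {variant.seq_name}:{variant.pos + 1} does not alter "
        f"the CDS of {gene.gene_id}"
    )


def _translate(cds: str) -> str:
    """Translate and truncate at the first stop codon (stop excluded)."""
    n = len(cds) - len(cds) % 3
    aa = str(Seq(cds[:n]).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


def _canonical_edit(variant: VariantRecord) -> tuple[int, int, str]:
    """Reduce REF/ALT to the minimal replaced span.

    Shared prefix and suffix bases are trimmed, leaving a reference span
    [a, b) replaced by ``repl`` (empty for a pure deletion; a == b for a
    pure insertion).  This makes the edit arithmetic independent of
    whether the record was anchored on its left or right flank.
    """
    ref, alt = variant.ref, variant.alt
    i = 0
    while i < min(len(ref), len(alt)) and ref[i] == alt[i]:
        i += 1
    j = 0
    while j < min(len(ref), len(alt)) - i and ref[-1 - j] == alt[-1 - j]:
        j += 1
    a = variant.pos + i
    b = variant.pos + len(ref) - j
    return a, b, alt[i : len(alt) - j]


def _mutant_cds(
    variant: VariantRecord, gene: GeneModel, genome: GenomeRef
) -> tuple[str, int, list[str]]:
    """Rebuild the spliced CDS with the variant applied.

    Works on the left-to-right (plus-strand) concatenation and reverse
    complements at the end, so the edit arithmetic is strand-free.
    Returns (mutant spliced CDS, net coding-length change, notes).
    """
    seq = genome[gene.seq_name]
    if seq[variant.pos : variant.end] != variant.ref:
        raise MutlineError(
            f"REF allele mismatch at {variant.seq_name}:{variant.pos + 1}"
        )
    notes: list[str] = []
    a, b, repl = _canonical_edit(variant)
    substitution = len(repl) == b - a

    pieces, net = [], 0
    applied = False
    for s, e, _ in _plus_offsets(gene):
        overlap = max(s, a) < min(e, b)
        if not overlap:
            if a == b and s < a < e:  # pure insertion inside this interval
                pieces.append(seq[s:a] + repl + seq[a:e])
                net += len(repl)
                applied = True
            else:
                pieces.append(seq[s:e])
            continue
        lo, hi = max(s, a), min(e, b)
        if substitution:
            pieces.append(seq[s:lo] + repl[lo - a : hi - a] + seq[hi:e])
        else:
            # drop the overlapped span; the replacement bases sit at the
            # span's left edge and enter the CDS only if that edge does
            ins = ""
            if repl and not applied and s <= a < e:
                ins, applied = repl, True
            pieces.append(seq[s:lo] + ins + seq[hi:e])
            net += len(ins) - (hi - lo)
            if a < s or b > e:
                notes.append("splice_region")
    mutant = "".join(pieces)
    if gene.strand == "-":
        mutant = str(Seq(mutant).reverse_complement())
    return mutant, net, sorted(set(notes))


def _classify_substitution(full_ref: str, full_alt: str) -> str:
    """Effect of an equal-length substitution from the two translations.

    A stop arising earlier than the reference stop wins (stop_gain); a
    reference stop turned into a sense codon is stop_loss; otherwise any
    amino-acid difference is missense.
    """
    if full_alt == full_ref:
        return "synonymous"
    ref_stop = full_ref.find("*")
    alt_stop = full_alt.find("*")
    if alt_stop != -1 and (ref_stop == -1 or alt_stop < ref_stop):
        return "stop_gain"
    if ref_stop != -1 and (alt_stop == -1 or alt_stop > ref_stop):
        return "stop_loss"
    return "missense"


def classify_variant(
    variant: VariantRecord,
    gene: GeneModel,
    genome: GenomeRef,
    domains: list[tuple[str, int, int]] | None = None,
) -> ConsequenceCall:
    """Classify one variant against one gene model.

    ``domains`` is an optional list of ``(name, aa_start, aa_end)``
    intervals in 1-based reference-protein coordinates (inclusive); a
    domain is reported lost when the mutant protein no longer carries the
    identical amino-acid stretch at that location.
    """
    try:
        cds_pos = cds_coordinate(variant, gene)
    except NonCodingVariant:
        return ConsequenceCall(gene_id=None, effect="non_coding")

    ref_cds = splice_cds(genome, gene)
    alt_cds, net, notes = _mutant_cds(variant, gene, genome)
    ref_protein = _translate(ref_cds)
    alt_protein = _translate(alt_cds)

    if net % 3 != 0:
        effect = "frameshift"
    elif len(variant.ref) != len(variant.alt):
        effect = "inframe_deletion" if net <= 0 else "inframe_insertion"
        if len(alt_protein) < len(ref_protein) + net // 3:
            notes.append("premature_stop")
    else:
        # substitution: diff the full translations (stops retained)
        full_ref = str(Seq(ref_cds[: len(ref_cds) - len(ref_cds) % 3]).translate())
        full_alt = str(Seq(alt_cds[: len(alt_cds) - len(alt_cds) % 3]).translate())
        effect = _classify_substitution(full_ref, full_alt)

    lost = []
    for name, aa_start, aa_end in domains or []:
        ref_piece = ref_protein[aa_start - 1 : aa_end]
        alt_piece = alt_protein[aa_start - 1 : aa_end]
        if ref_piece and alt_piece != ref_piece:
            lost.append(name)

    return ConsequenceCall(
        gene_id=gene.gene_id,
        effect=effect,
        cds_pos=cds_pos,
        ref_protein=ref_protein,
        alt_protein=alt_protein,
        lost_domains=lost,
        notes=notes,
    )


def find_gene(
    variant: VariantRecord, gene_models: list[GeneModel]
) -> GeneModel | None:
    """The gene whose span contains the variant's altered interval
    (first match in coordinate order), or None."""
    a, b = variant.altered_interval()
    for gm in gene_models:
        if gm.seq_name != variant.seq_name:
            continue
        if gm.start < (b if b > a else a + 1) and a < gm.end:
            return gm
    return None
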