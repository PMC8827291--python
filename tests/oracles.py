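"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's own coordinate machinery: the
consequence oracle edits the whole chromosome, shifts the gene model's
intervals and re-splices from scratch; the filter oracle classifies
every record against per-base coding-position sets and plain set
arithmetic over the call sets.
"""

from __future__ import annotations

from collections import Counter

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CODON_TABLE = {}


def _codon_table():
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_full(cds: str) -> str:
    table = _codon_table()
    return "".join(
        table.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


def truncate_at_stop(protein: str) -> str:
    stop = protein.find("*")
    return protein if stop < 0 else protein[:stop]


def coding_positions(gene) -> list[int]:
    """Reference positions of CDS bases in transcription order."""
    pos = [p for s, e in gene.cds for p in range(s, e)]
    return pos[::-1] if gene.strand == "-" else pos


def altered_positions(variant) -> list[int]:
    """Reference positions changed by the variant (anchor excluded)."""
    if len(variant.ref) == len(variant.alt):
        return list(range(variant.pos, variant.end))
    if variant.ref[0] == variant.alt[0]:
        return list(range(variant.pos + 1, variant.end))
    return list(range(variant.pos, variant.end))


def oracle_cds_pos(variant, gene) -> int | None:
    """1-based spliced position of the first altered coding base, by a
    brute-force walk along the coding positions."""
    coding = coding_positions(gene)
    altered = set(altered_positions(variant))
    if not altered:  # pure insertion: first flanking coding base
        altered = {variant.pos, variant.pos + 1}
    hits = [i for i, p in enumerate(coding) if p in altered]
    return min(hits) + 1 if hits else None


def oracle_classify(variant, gene, genome) -> tuple[str, str, str]:
    """(effect, ref_protein, alt_protein) via whole-genome editing.

    The mutant chromosome is built by string replacement, the gene's CDS
    intervals are mapped through the edit, and both alleles are spliced
    and translated from scratch.
    """
    seq = genome[gene.seq_name]
    assert seq[variant.pos : variant.end] == variant.ref
    mseq = seq[: variant.pos] + variant.alt + seq[variant.end :]
    net = len(variant.alt) - len(variant.ref)
    pos, end, alt_len = variant.pos, variant.end, len(variant.alt)

    def fmap(x: int) -> int:
        if x <= pos:
            return x
        if x >= end:
            return x + net
        return pos + min(x - pos, alt_len)

    new_cds = [(fmap(s), fmap(e)) for s, e in gene.cds]
    ref_cds = "".join(seq[s:e] for s, e in gene.cds)
    alt_cds = "".join(mseq[s:e] for s, e in new_cds)
    if gene.strand == "-":
        ref_cds, alt_cds = revcomp(ref_cds), revcomp(alt_cds)

    coding = set(coding_positions(gene))
    altered = set(altered_positions(variant))
    if not altered:
        altered = {variant.pos, variant.pos + 1}
        # an insertion between two non-coding bases is non-coding
    if not (altered & coding):
        return ("non_coding", "", "")

    ref_prot = truncate_at_stop(translate_full(ref_cds))
    alt_prot = truncate_at_stop(translate_full(alt_cds))
    net_cds = len(alt_cds) - len(ref_cds)
    if net_cds % 3 != 0:
        effect = "frameshift"
    elif len(variant.ref) != len(variant.alt):
        effect = "inframe_deletion" if net_cds <= 0 else "inframe_insertion"
    else:
        full_ref = translate_full(ref_cds)
        full_alt = translate_full(alt_cds)
        if full_ref == full_alt:
            effect = "synonymous"
        else:
            rs, as_ = full_ref.find("*"), full_alt.find("*")
            if as_ != -1 and (rs == -1 or as_ < rs):
                effect = "stop_gain"
            elif rs != -1 and (as_ == -1 or as_ > rs):
                effect = "stop_loss"
            else:
                effect = "missense"
    return (effect, ref_prot, alt_prot)


# ---------------------------------------------------------------------------
# filter-stage oracle


def _coding_sets(gene_models) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {}
    for gm in gene_models:
        out.setdefault(gm.seq_name, set()).update(
            p for s, e in gm.cds for p in range(s, e)
        )
    return out


def oracle_stage_counts(
    call_sets, gene_models, evidence, config, focal_line
) -> dict[str, int]:
    """Expected per-stage survivor counts by per-record classification."""
    coding = _coding_sets(gene_models)

    def in_cds(v) -> bool:
        pts = altered_positions(v)
        if not pts:  # insertion point: either flanking base coding
            pts = [v.pos, v.pos + 1]
        return any(p in coding.get(v.seq_name, set()) for p in pts)

    other_keys = Counter(
        v.key
        for line, recs in call_sets.items()
        if line != focal_line
        for v in recs
    )

    current = list(call_sets[focal_line])
    counts = {"total": len(current)}
    current = [v for v in current if in_cds(v)]
    counts["cds"] = len(current)
    current = [v for v in current if other_keys[v.key] == 0]
    counts["unique"] = len(current)
    current = [v for v in current if not v.multiallelic]
    counts["two_alleles"] = len(current)
    current = [
        v
        for v in current
        if v.depth is not None and v.depth >= config.min_depth
    ]
    counts["read_depth"] = len(current)

    def af_ok(v) -> bool:
        if v.allele_depths is None:
            return False
        r, a = v.allele_depths
        return (r + a) > 0 and a / (r + a) >= config.min_alt_af

    current = [v for v in current if af_ok(v)]
    counts["min_allele_frequency"] = len(current)
    current = [
        v
        for v in current
        if not any(
            n > config.cross_line_max_alt_reads
            for line, n in evidence.get(
                (v.seq_name, v.pos, v.alt), {}
            ).items()
            if line != focal_line
        )
    ]
    counts["cross_line_check"] = len(current)
    return counts
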