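"""The staged candidate-mutation identification pipeline.

Per-line variant sets pass through a fixed stage order —
total -> CDS -> unique -> two-alleles -> read depth -> alternate-allele
frequency -> cross-line evidence check — and the per-stage survivor
counts are reported alongside the final candidates.  Stage semantics:

* **cds**: keep a variant iff the reference interval it alters
  intersects any CDS interval (the shared anchor base of an indel does
  not count; a pure insertion counts when its insertion point lies
  inside coding sequence).
* **unique**: keep focal-line variants whose normalized
  (seq, pos, ref, alt) key appears in no other line, the wild-type
  parent included.  A *site-level* mode (same position, any allele) is
  available but not the default.
* **two_alleles**: biallelic records only; decomposed multi-allelic
  records are removed, not re-merged.
* **read_depth**: DP >= threshold; records with missing DP are removed
  and counted in the log.
* **min_allele_frequency**: AD-derived alt fraction >= threshold;
  records lacking AD are removed (conservative reading of the manual
  inspection the threshold stands in for).
* **cross_line_check**: an automated stand-in for inspecting the other
  lines' alignments in a genome browser — drop a candidate when any
  other line shows more than the tolerated number of alt-supporting
  reads at the same site, even though no variant was called there.
"""

from __future__ import annotations

import logging

from .model import (
    FilterReport,
    GeneModel,
    MutlineError,
    RunConfig,
    STAGES,
    VariantRecord,
)

logger = logging.getLogger(__name__)

Evidence = dict[tuple[str, int, str], dict[str, int]]


def _cds_by_seq(
    gene_models: list[GeneModel],
) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for gm in gene_models:
        out.setdefault(gm.seq_name, []).extend(gm.cds)
    return {k: sorted(v) for k, v in out.items()}


def _hits_cds(variant: VariantRecord, cds: list[tuple[int, int]]) -> bool:
    a, b = variant.altered_interval()
    if a == b:  # pure insertion: judged by the bases flanking the point
        return any(s < a < e or s <= a - 1 < e for s, e in cds)
    return any(s < b and a < e for s, e in cds)


def filter_cds(
    variants: list[VariantRecord], gene_models: list[GeneModel]
) -> list[VariantRecord]:
    """Keep variants whose altered interval intersects coding sequence."""
    cds = _cds_by_seq(gene_models)
    known = {gm.seq_name for gm in gene_models}
    unknown = sorted({v.seq_name for v in variants} - known)
    if unknown:
        raise MutlineError(
            f"variants reference unknown sequence(s): {', '.join(unknown)}"
        )
    return [v for v in variants if _hits_cds(v, cds.get(v.seq_name, []))]


def filter_unique(
    variant_sets: dict[str, list[VariantRecord]],
    focal_line: str,
    per_site: bool = False,
) -> list[VariantRecord]:
    """Keep focal-line variants found in no other line's call set.

    Identity is the normalized (seq, pos, ref, alt) key, so a different
    ALT at the same position elsewhere does not disqualify; pass
    ``per_site=True`` for the stricter position-only comparison.
    """
    keyfn = (
        (lambda v: (v.seq_name, v.pos))
        if per_site
        else (lambda v: v.key)
    )
    others = {
        keyfn(v)
        for line, recs in variant_sets.items()
        if line != focal_line
        for v in recs
    }
    return [v for v in variant_sets[focal_line] if keyfn(v) not in others]


def filter_two_alleles(
    variants: list[VariantRecord],
) -> list[VariantRecord]:
    """Keep biallelic records (one REF, one ALT)."""
    return [
        v
        for v in variants
        if not v.multiallelic and v.alt not in (".", "", "*")
    ]


def filter_depth(
    variants: list[VariantRecord], min_depth: int = 2
) -> list[VariantRecord]:
    """Keep records with DP >= ``min_depth``; missing DP is removed."""
    missing = sum(1 for v in variants if v.depth is None)
    if missing:
        logger.info("read_depth: removed %d records with missing DP", missing)
    return [v for v in variants if v.depth is not None and v.depth >= min_depth]


def filter_alt_af(
    variants: list[VariantRecord], min_af: float = 0.9
) -> list[VariantRecord]:
    """Keep records whose AD-derived alt fraction is >= ``min_af``."""
    missing = sum(1 for v in variants if v.alt_af is None)
    if missing:
        logger.info(
            "min_allele_frequency: removed %d records lacking AD", missing
        )
    return [
        v for v in variants if v.alt_af is not None and v.alt_af >= min_af
    ]


def cross_line_check(
    variants: list[VariantRecord],
    evidence: Evidence,
    max_alt_reads: int = 0,
    focal_line: str | None = None,
) -> list[VariantRecord]:
    """Drop candidates with cross-line alt-read support above tolerance."""
    kept = []
    for v in variants:
        focal = focal_line or v.line_id
        per_line = evidence.get((v.seq_name, v.pos, v.alt), {})
        if any(
            n > max_alt_reads
            for line, n in per_line.items()
            if line != focal
        ):
            continue
        kept.append(v)
    return kept


def run_pipeline(
    variant_sets: dict[str, list[VariantRecord]],
    gene_models: list[GeneModel],
    evidence: Evidence | None = None,
    config: RunConfig | None = None,
    focal_lines: list[str] | None = None,
    wt_line: str | None = "WT",
) -> dict[str, FilterReport]:
    """Run all stages for each focal line and report per-stage counts.

    ``focal_lines`` defaults to every line except the wild-type parent
    (which still participates in the uniqueness comparison).  Each
    surviving record's ``passed_stages`` is filled in.
    """
    config = config or RunConfig()
    evidence = evidence or {}
    if focal_lines is None:
        focal_lines = sorted(l for l in variant_sets if l != wt_line)
    reports = {}
    for line in focal_lines:
        counts: dict[str, int] = {}
        current = list(variant_sets[line])
        counts["total"] = len(current)
        current = filter_cds(current, gene_models)
        counts["cds"] = len(current)
        sets = dict(variant_sets)
        sets[line] = current
        current = filter_unique(sets, line)
        counts["unique"] = len(current)
        current = filter_two_alleles(current)
        counts["two_alleles"] = len(current)
        current = filter_depth(current, config.min_depth)
        counts["read_depth"] = len(current)
        current = filter_alt_af(current, config.min_alt_af)
        counts["min_allele_frequency"] = len(current)
        current = cross_line_check(
            current, evidence, config.cross_line_max_alt_reads, line
        )
        counts["cross_line_check"] = len(current)
        for v in current:
            v.passed_stages = set(STAGES)
        logger.info(
            "line %s: %s (min_depth=%d, min_af=%.2f, max_alt=%d)",
            line,
            " -> ".join(f"{s}={counts[s]}" for s in STAGES),
            config.min_depth,
            config.min_alt_af,
            config.cross_line_max_alt_reads,
        )
        reports[line] = FilterReport(
            line_id=line, counts=counts, candidates=current
        )
    return reports
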