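"""Large-deletion detection from depth contrast plus split-read support.

A deletion unique to one mutant shows up as a run of windows where the
mutant's coverage collapses while the wild type's does not; windows
where the wild type itself is depleted (assembly gaps, N stretches) are
excluded from consideration so shared artefacts are not called.  Depth
breakpoints are then refined to base precision from split long-read
alignments: a deletion-spanning read aligns in two blocks that are
adjacent on the read but flank the deleted interval on the reference,
and the modal inner edges across supporting reads give the breakpoints.
A collinearity check over a contig's alignment blocks flags candidate
reference misassembly, and annotated genes inside the final interval
are reported as fully deleted or truncated.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict

import numpy as np

from .model import (
    DeletionCall,
    DepthTrack,
    GeneModel,
    MutlineError,
    PafAlignment,
    RunConfig,
)


def window_means(track: DepthTrack, window_bp: int) -> np.ndarray:
    """Mean depth over tiling windows (the last one may be short)."""
    if window_bp < 1:
        raise ValueError("window_bp must be positive")
    n = len(track.depth)
    edges = np.arange(0, n, window_bp)
    sums = np.add.reduceat(track.depth.astype(float), edges)
    sizes = np.diff(np.append(edges, n))
    return sums / sizes


def _candidate_runs(
    mut_win: np.ndarray,
    wt_win: np.ndarray,
    mut_median: float,
    wt_median: float,
    config: RunConfig,
) -> list[tuple[int, int]]:
    """Maximal candidate window runs, bridged across single-window gaps."""
    eligible = wt_win >= config.deletion_wt_floor * wt_median
    depleted = mut_win <= config.deletion_mutant_ceiling * mut_median
    flags = eligible & depleted
    runs: list[tuple[int, int]] = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(flags)))
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= 1:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return merged


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def detect_deletions(
    mutant_track: DepthTrack,
    wt_track: DepthTrack,
    other_mutant_tracks: list[DepthTrack] | None = None,
    config: RunConfig | None = None,
) -> list[DeletionCall]:
    """Depth-contrast scan for deletions unique to the focal mutant.

    A call is a maximal run of windows where the mutant mean is at or
    below ``ceiling x mutant-median`` while the wild-type mean stays at
    or above ``floor x WT-median``; runs are merged across single-window
    gaps and kept when at least ``deletion_min_len`` long.  The same
    scan over the other mutants decides ``unique_to_line`` (reciprocal
    overlap >= 0.5 disqualifies).
    """
    config = config or RunConfig()
    if len(mutant_track.depth) != len(wt_track.depth):
        raise MutlineError("mutant and wild-type tracks differ in length")
    window = config.depth_window_bp
    n = len(mutant_track.depth)
    mut_win = window_means(mutant_track, window)
    wt_win = window_means(wt_track, window)
    mut_med = float(np.median(mutant_track.depth))
    wt_med = float(np.median(wt_track.depth))
    runs = _candidate_runs(mut_win, wt_win, mut_med, wt_med, config)

    other_runs = []
    for other in other_mutant_tracks or []:
        if len(other.depth) != n:
            raise MutlineError(
                f"track for {other.line_id} differs in length"
            )
        o_win = window_means(other, window)
        o_med = float(np.median(other.depth))
        for w0, w1 in _candidate_runs(
            o_win, wt_win, o_med, wt_med, config
        ):
            other_runs.append((w0 * window, min(w1 * window, n)))

    calls = []
    for w0, w1 in runs:
        start, end = w0 * window, min(w1 * window, n)
        if end - start < config.deletion_min_len:
            continue
        unique = not any(
            _reciprocal_overlap((start, end), o) >= 0.5 for o in other_runs
        )
        calls.append(
            DeletionCall(
                line_id=mutant_track.line_id,
                seq_name=mutant_track.seq_name,
                start=start,
                end=end,
                source="depth_only",
                mutant_mean_depth=float(
                    mutant_track.depth[start:end].mean()
                ),
                wt_mean_depth=float(wt_track.depth[start:end].mean()),
                unique_to_line=unique,
            )
        )
    return calls


def _split_pairs(
    paf: list[PafAlignment], tolerance: int
) -> dict[str, list[tuple[int, int]]]:
    """Per query, the implied deleted intervals of its query-adjacent,
    same-strand block pairs (target-left block's end, target-right
    block's start)."""
    by_query: dict[str, list[PafAlignment]] = defaultdict(list)
    for b in paf:
        by_query[b.query_name].append(b)
    out: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for name, blocks in by_query.items():
        blocks = sorted(blocks, key=lambda b: b.qstart)
        for b1, b2 in zip(blocks, blocks[1:]):
            if b1.strand != b2.strand or b1.target_name != b2.target_name:
                continue
            if not (-tolerance <= b2.qstart - b1.qend <= tolerance):
                continue
            left, right = sorted((b1, b2), key=lambda b: b.tstart)
            if left.tend < right.tstart:
                out[name].append((left.tend, right.tstart))
    return dict(out)


def refine_breakpoints(
    call: DeletionCall,
    paf_mutant: list[PafAlignment],
    tolerance: int = 100,
    min_support: int = 2,
) -> DeletionCall:
    """Replace depth-scan breakpoints with the modal split-read edges.

    Requires at least ``min_support`` distinct spanning reads whose
    implied deleted interval overlaps the depth candidate; otherwise the
    call is returned unchanged with a note.  Ties in the modal edge pair
    are broken toward the widest interval.
    """
    votes: Counter[tuple[int, int]] = Counter()
    supporters = set()
    for name, pairs in _split_pairs(paf_mutant, tolerance).items():
        for lo, hi in pairs:
            if lo < call.end and call.start < hi:
                votes[(lo, hi)] += 1
                supporters.add(name)
    if len(supporters) < min_support:
        return dataclasses.replace(
            call,
            notes=call.notes
            + [
                f"split-read support {len(supporters)} < {min_support}; "
                "breakpoints not refined"
            ],
        )
    best = max(
        votes.items(),
        key=lambda kv: (kv[1], kv[0][1] - kv[0][0], -kv[0][0]),
    )[0]
    return dataclasses.replace(
        call,
        start=best[0],
        end=best[1],
        source="split_refined",
        n_split_mutant=len(supporters),
    )


def spanning_support(
    interval: tuple[int, int],
    paf: list[PafAlignment],
    flank: int = 100,
    tolerance: int = 100,
) -> tuple[int, int]:
    """(contiguous, split) spanning-read counts over ``interval``.

    Contiguous: a single block covering the interval plus ``flank`` on
    both sides (the intact-allele signature).  Split: a query-adjacent
    block pair whose implied deleted interval overlaps it.
    """
    lo, hi = interval
    contiguous = {
        b.query_name
        for b in paf
        if b.tstart <= lo - flank and b.tend >= hi + flank
    }
    split = {
        name
        for name, pairs in _split_pairs(paf, tolerance).items()
        if any(plo < hi and lo < phi for plo, phi in pairs)
    }
    return len(contiguous), len(split)


def collinearity_check(
    contig_blocks: list[PafAlignment], max_gap: int = 100_000
) -> tuple[str, list[tuple[PafAlignment, PafAlignment]]]:
    """Classify one query's alignment blocks as collinear or rearranged.

    Blocks are walked in query order; each adjacent pair must stay on
    one target, in one orientation, with target coordinates monotone in
    that orientation and the implied target gap at most ``max_gap``.
    Returns the verdict plus every discordant adjacent pair.
    """
    blocks = sorted(contig_blocks, key=lambda b: b.qstart)
    discordant = []
    for b1, b2 in zip(blocks, blocks[1:]):
        ok = b1.target_name == b2.target_name and b1.strand == b2.strand
        if ok and b1.strand == "+":
            ok = b2.tstart >= b1.tstart and abs(b2.tstart - b1.tend) <= max_gap
        elif ok:
            ok = b2.tend <= b1.tend and abs(b1.tstart - b2.tend) <= max_gap
        if not ok:
            discordant.append((b1, b2))
    status = "collinear" if not discordant else "rearranged"
    return status, discordant


def genes_in_interval(
    call: DeletionCall | tuple[str, int, int],
    gene_models: list[GeneModel],
) -> tuple[list[str], list[str]]:
    """Gene ids fully inside the interval, and those only truncated."""
    if isinstance(call, DeletionCall):
        seq, lo, hi = call.seq_name, call.start, call.end
    else:
        seq, lo, hi = call
    deleted, truncated = [], []
    for gm in gene_models:
        if gm.seq_name != seq:
            continue
        if lo <= gm.start and gm.end <= hi:
            deleted.append(gm.gene_id)
        elif gm.start < hi and lo < gm.end:
            truncated.append(gm.gene_id)
    return deleted, truncated


def annotate_call(
    call: DeletionCall, gene_models: list[GeneModel]
) -> DeletionCall:
    """Fill in the deleted/truncated gene lists of a call."""
    deleted, truncated = genes_in_interval(call, gene_models)
    return dataclasses.replace(
        call, deleted_genes=deleted, truncated_genes=truncated
    )
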