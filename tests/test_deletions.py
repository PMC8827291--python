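"""Depth-scan deletion calling, split-read refinement, spanning support,
collinearity and gene-content reporting."""

import numpy as np
import pytest

import mutline as m


def _paf(qname, qlen, qs, qe, strand, ts, te, tname="chr1", tlen=10**6):
    return m.PafAlignment(
        qname, qlen, qs, qe, strand, tname, tlen, ts, te, qe - qs, qe - qs, 60
    )


class TestWindowMeans:
    def test_constant_depth(self):
        track = m.DepthTrack("L", "c", np.full(5000, 20))
        assert (m.window_means(track, 1000) == 20).all()

    def test_all_zero(self):
        track = m.DepthTrack("L", "c", np.zeros(3000, dtype=int))
        assert (m.window_means(track, 1000) == 0).all()

    def test_hand_computed_toy_with_short_last_window(self):
        depth = np.array([2, 4, 6, 8, 10])
        track = m.DepthTrack("L", "c", depth)
        got = m.window_means(track, 2)
        assert got.tolist() == [3.0, 7.0, 10.0]


def _world(seed=5):
    genome, genes = m.make_reference(seed, 1, 200_000, 6, 4)
    truth = m.plant_mutations(
        genome, genes, {"D1": "large_deletion"}, seed=seed + 1,
        deletion_len=35_000,
    )
    return genome, genes, truth.causal["D1"]


class TestDetectDeletions:
    def test_planted_deletion_recovered_within_one_window(self):
        genome, genes, d = _world()
        assert d.length == 35_000
        tracks = m.simulate_depth_tracks(
            genome, {"D1": d, "WT": None}, 20.0, 3.0, seed=7
        )
        (call,) = m.detect_deletions(
            tracks["D1"][0], tracks["WT"][0], config=m.RunConfig()
        )
        assert abs(call.start - d.start) <= 1000
        assert abs(call.end - d.end) <= 1000
        assert call.source == "depth_only" and call.unique_to_line

    def test_identical_tracks_give_no_calls(self):
        genome = m.GenomeRef({"chr1": "A" * 60_000})
        tracks = m.simulate_depth_tracks(genome, {"A": None}, 20, 3, seed=1)
        t = tracks["A"][0]
        assert m.detect_deletions(t, t, config=m.RunConfig()) == []

    def test_shared_deletion_not_unique(self):
        genome, genes, d = _world()
        d2 = m.DeletionTruth("D2", d.seq_name, d.start, d.end)
        tracks = m.simulate_depth_tracks(
            genome, {"D1": d, "D2": d2, "WT": None}, 20.0, 3.0, seed=9
        )
        (call,) = m.detect_deletions(
            tracks["D1"][0],
            tracks["WT"][0],
            other_mutant_tracks=[tracks["D2"][0]],
            config=m.RunConfig(),
        )
        assert call.unique_to_line is False

    def test_invariant_to_uniform_depth_scaling(self):
        genome, genes, d = _world()
        tracks = m.simulate_depth_tracks(
            genome, {"D1": d, "WT": None}, 20.0, 3.0, seed=11
        )
        mt, wt = tracks["D1"][0], tracks["WT"][0]
        calls = m.detect_deletions(mt, wt, config=m.RunConfig())
        scaled = m.detect_deletions(
            m.DepthTrack("D1", mt.seq_name, mt.depth * 3),
            m.DepthTrack("WT", wt.seq_name, wt.depth * 3),
            config=m.RunConfig(),
        )
        assert [(c.start, c.end) for c in calls] == [
            (c.start, c.end) for c in scaled
        ]

    def test_wt_depleted_windows_excluded(self):
        """A region where both lines lose coverage (shared assembly gap)
        is not called."""
        rng = np.random.default_rng(3)
        n = 60_000
        base = rng.normal(20, 2, n).round().clip(0)
        mut = base.copy()
        wt = rng.normal(20, 2, n).round().clip(0)
        mut[20_000:30_000] = 0
        wt[20_000:30_000] = 0  # the wild type is depleted there too
        calls = m.detect_deletions(
            m.DepthTrack("M", "c", mut.astype(int)),
            m.DepthTrack("WT", "c", wt.astype(int)),
            config=m.RunConfig(),
        )
        assert calls == []

    def test_length_mismatch_errors(self):
        a = m.DepthTrack("A", "c", np.full(100, 5))
        b = m.DepthTrack("B", "c", np.full(99, 5))
        with pytest.raises(m.MutlineError):
            m.detect_deletions(a, b)


class TestRefineBreakpoints:
    def _call(self, start=11_000, end=45_000):
        return m.DeletionCall(
            line_id="D1",
            seq_name="chr1",
            start=start,
            end=end,
            source="depth_only",
            mutant_mean_depth=0.0,
            wt_mean_depth=20.0,
        )

    def test_three_clean_spanning_reads_recover_exact_interval(self):
        blocks = []
        for i in range(3):
            q = f"read{i}"
            blocks.append(_paf(q, 30_000, 0, 15_000, "+", 85_000, 100_000))
            blocks.append(
                _paf(q, 30_000, 15_000, 30_000, "+", 135_000, 150_000)
            )
        refined = m.refine_breakpoints(
            self._call(99_000, 136_000), blocks
        )
        assert (refined.start, refined.end) == (100_000, 135_000)
        assert refined.source == "split_refined"
        assert refined.n_split_mutant == 3

    def test_no_split_reads_returns_depth_only_with_note(self):
        refined = m.refine_breakpoints(self._call(), [])
        assert refined.source == "depth_only"
        assert any("not refined" in n for n in refined.notes)

    def test_single_read_below_min_support_unchanged(self):
        q = "lonely"
        blocks = [
            _paf(q, 20_000, 0, 10_000, "+", 90_000, 100_000),
            _paf(q, 20_000, 10_000, 20_000, "+", 135_000, 145_000),
        ]
        refined = m.refine_breakpoints(
            self._call(99_000, 136_000), blocks, min_support=2
        )
        assert refined.source == "depth_only"
        assert any("1 < 2" in n for n in refined.notes)

    def test_end_to_end_on_generator_output(self):
        genome, genes, d = _world(seed=13)
        tracks = m.simulate_depth_tracks(
            genome, {"D1": d, "WT": None}, 20.0, 3.0, seed=14
        )
        (call,) = m.detect_deletions(
            tracks["D1"][0], tracks["WT"][0], config=m.RunConfig()
        )
        paf = m.simulate_long_read_alignments(
            genome, d, n_spanning=3, seed=15, allele="mutant"
        )
        refined = m.refine_breakpoints(call, paf)
        assert (refined.start, refined.end) == (d.start, d.end)


class TestSpanningSupport:
    def test_wildtype_contiguous_mutant_split(self):
        genome, genes, d = _world(seed=17)
        paf_mut = m.simulate_long_read_alignments(
            genome, d, n_spanning=3, seed=18, allele="mutant"
        )
        paf_wt = m.simulate_long_read_alignments(
            genome, d, n_spanning=4, seed=19, allele="wildtype"
        )
        assert m.spanning_support((d.start, d.end), paf_mut) == (0, 3)
        assert m.spanning_support((d.start, d.end), paf_wt) == (4, 0)

    def test_empty_paf(self):
        assert m.spanning_support((100, 200), []) == (0, 0)


class TestCollinearity:
    def test_ordered_blocks_with_small_gaps_collinear(self):
        blocks = [
            _paf("c1", 60_000, 0, 20_000, "+", 100_000, 120_000),
            _paf("c1", 60_000, 20_000, 40_000, "+", 121_000, 141_000),
            _paf("c1", 60_000, 40_000, 60_000, "+", 142_000, 162_000),
        ]
        status, bad = m.collinearity_check(blocks)
        assert status == "collinear" and bad == []

    def test_relocated_middle_block_rearranged(self):
        blocks = [
            _paf("c1", 60_000, 0, 20_000, "+", 100_000, 120_000),
            _paf("c1", 60_000, 20_000, 40_000, "+", 900_000, 920_000),
            _paf("c1", 60_000, 40_000, 60_000, "+", 121_000, 141_000),
        ]
        status, bad = m.collinearity_check(blocks, max_gap=100_000)
        assert status == "rearranged"
        assert len(bad) == 2  # both adjacencies around the stray block

    def test_single_block_vacuously_collinear(self):
        blocks = [_paf("c1", 10_000, 0, 10_000, "+", 5_000, 15_000)]
        assert m.collinearity_check(blocks)[0] == "collinear"

    def test_slices_of_one_true_alignment_collinear(self):
        """Cutting one genuine alignment into consecutive pieces can
        never create discordance."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            n_cuts = int(rng.integers(2, 6))
            edges = np.sort(rng.choice(np.arange(1, 50), n_cuts, False))
            edges = [0, *(int(e) * 1000 for e in edges), 50_000]
            offset = int(rng.integers(0, 500_000))
            strand = "+" if rng.random() < 0.5 else "-"
            blocks = []
            for a, b in zip(edges, edges[1:]):
                if strand == "+":
                    ts, te = offset + a, offset + b
                else:
                    ts, te = offset + 50_000 - b, offset + 50_000 - a
                blocks.append(_paf("c", 50_000, a, b, strand, ts, te))
            assert m.collinearity_check(blocks)[0] == "collinear"

    def test_strand_flip_rearranged(self):
        blocks = [
            _paf("c1", 40_000, 0, 20_000, "+", 100_000, 120_000),
            _paf("c1", 40_000, 20_000, 40_000, "-", 121_000, 141_000),
        ]
        assert m.collinearity_check(blocks)[0] == "rearranged"


class TestGenesInInterval:
    def test_contained_vs_straddling(self, bundle):
        g = bundle.gene_models[10]
        inside = (g.seq_name, g.start - 5, g.end + 5)
        deleted, truncated = m.genes_in_interval(inside, bundle.gene_models)
        assert g.gene_id in deleted
        straddle = (g.seq_name, g.start + 10, g.end + 5)
        deleted, truncated = m.genes_in_interval(
            straddle, bundle.gene_models
        )
        assert g.gene_id in truncated and g.gene_id not in deleted

    def test_matches_brute_force_over_fixture(self, bundle):
        rng = np.random.default_rng(29)
        genes = bundle.gene_models
        L = len(bundle.genome["chr1"])
        for _ in range(50):
            a = int(rng.integers(0, L - 40_000))
            b = a + int(rng.integers(5_000, 40_000))
            deleted, truncated = m.genes_in_interval(("chr1", a, b), genes)
            exp_del = [
                g.gene_id for g in genes if a <= g.start and g.end <= b
            ]
            exp_trunc = [
                g.gene_id
                for g in genes
                if g.start < b and a < g.end
                and not (a <= g.start and g.end <= b)
            ]
            assert deleted == exp_del and truncated == exp_trunc
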