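"""Clustering: EM behaviour, filtering/merging, orientation, ordering,
misassembly detection and correction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from strandweave import simdata as sd
from strandweave import strandstate as ss
from strandweave import saarclust as sc


@pytest.fixture(scope="module")
def fitted(small_genome, small_contigs, small_strandseq):
    grid = ss.BinGrid.fixed(small_contigs.contig_lengths, 200_000)
    counts = ss.count_reads(small_strandseq.reads, grid)
    model = sc.em_cluster(counts, K=10, seed=1)
    scaffolds = sc.filter_and_merge(model, small_contigs.contig_lengths)
    return counts, model, scaffolds


class TestEMCluster:
    def test_loglik_monotone_nondecreasing(self, fitted):
        _, model, _ = fitted
        ll = np.array(model.loglik)
        assert np.all(np.diff(ll) >= -1e-6 * np.maximum(1.0, np.abs(ll[:-1])))

    def test_single_chromosome_one_effective_cluster(self):
        g = sd.simulate_genome(sd.GenomeSpec((2_000_000,), 1e-3, seed=4))
        ct = sd.fragment_contigs(g, 300_000, seed=4)
        data = sd.simulate_strandseq(g, ct, n_cells=30, reads_per_cell=2000,
                                     sce_rate=0.0, background=0.0, seed=4)
        grid = ss.BinGrid.fixed(ct.contig_lengths, 200_000)
        counts = ss.count_reads(data.reads, grid)
        model = sc.em_cluster(counts, K=5, seed=4)
        scaffolds = sc.filter_and_merge(model, ct.contig_lengths)
        assert scaffolds.n_clusters == 1

    def test_three_chromosomes_recovered(self, small_genome, small_contigs, fitted):
        _, _, scaffolds = fitted
        assert scaffolds.n_clusters == 3
        table = scaffolds.contig_table
        retained = table[table["cluster"] >= 0]
        # partition identical to truth: one cluster <-> one chromosome
        truth = {c: small_contigs.true_chromosome(c) for c in retained["contig"]}
        for cl, sub in retained.groupby("cluster"):
            assert len({truth[c] for c in sub["contig"]}) == 1

    def test_wc_flip_of_one_contig_keeps_cluster_flips_orientation(
            self, small_contigs, small_strandseq):
        # swapping W and C of one contig's reads must not move it to another
        # cluster; its orientation posterior flips instead
        reads = small_strandseq.reads.copy()
        target = small_contigs.contig_names[0]
        mask = reads["contig"] == target
        flip = {"+": "-", "-": "+"}
        reads.loc[mask, "strand"] = reads.loc[mask, "strand"].map(flip)
        grid = ss.BinGrid.fixed(small_contigs.contig_lengths, 200_000)
        counts0 = ss.count_reads(small_strandseq.reads, grid)
        counts1 = ss.count_reads(reads, grid)
        m0 = sc.em_cluster(counts0, K=10, seed=1)
        m1 = sc.em_cluster(counts1, K=10, seed=1)
        s0 = sc.filter_and_merge(m0, small_contigs.contig_lengths)
        s1 = sc.filter_and_merge(m1, small_contigs.contig_lengths)
        t0 = s0.contig_table.set_index("contig")
        t1 = s1.contig_table.set_index("contig")
        # same co-clustering of the flipped contig with its chromosome mates
        mates0 = set(s0.cluster_members[t0.loc[target, "cluster"]])
        mates1 = set(s1.cluster_members[t1.loc[target, "cluster"]])
        assert mates0 == mates1
        # relative orientation vs a cluster mate flips (the absolute frame of
        # a merged cluster is arbitrary between fits)
        bins = grid.bins
        mate = next(c for c in sorted(mates0) if c != target)
        ii = bins.index[bins["contig"] == target].to_numpy()
        jj = bins.index[bins["contig"] == mate].to_numpy()
        rel0 = abs(s0.bin_orient[ii].mean() - s0.bin_orient[jj].mean())
        rel1 = abs(s1.bin_orient[ii].mean() - s1.bin_orient[jj].mean())
        assert abs(rel0 - rel1) > 0.9  # one of them is the flipped relation

    def test_degenerate_all_zero_rejected(self):
        grid = ss.BinGrid.fixed({"c": 400_000}, 200_000)
        counts = ss.CountMatrix(W=np.zeros((2, 3), dtype=int),
                                C=np.zeros((2, 3), dtype=int),
                                grid=grid, cells=["a", "b", "c"])
        with pytest.raises(ValueError):
            sc.em_cluster(counts, K=2, seed=0)


class TestFilterAndMerge:
    def test_ambiguous_contig_discarded(self, small_contigs, small_strandseq):
        # a contig with no reads has a flat posterior over clusters: its
        # runner-up reaches prob_th and it must be discarded as ambiguous
        target = small_contigs.contig_names[0]
        reads = small_strandseq.reads[small_strandseq.reads["contig"] != target]
        grid = ss.BinGrid.fixed(small_contigs.contig_lengths, 200_000)
        counts = ss.count_reads(reads, grid)
        model = sc.em_cluster(counts, K=10, seed=1)
        scaffolds = sc.filter_and_merge(model, small_contigs.contig_lengths)
        table = scaffolds.contig_table.set_index("contig")
        assert table.loc[target, "discard_reason"] == "ambiguous"

    def test_always_wc_contig_discarded(self, small_genome):
        # one contig simulated hemizygous: only one homolog present -> its
        # reads are WC-like in every cell.  Build it by forcing templates so
        # that chromosome 3 looks WC everywhere: mix reads of two cells.
        g = small_genome
        ct = sd.fragment_contigs(g, 600_000, seed=6)
        data = sd.simulate_strandseq(g, ct, n_cells=40, reads_per_cell=3000,
                                     sce_rate=0.0, background=0.0, seed=6)
        reads = data.reads.copy()
        # make every read of chr3 contigs a coin flip: always-WC signature
        chr3 = set(ct.segments.loc[ct.segments["chrom"] == "chr3", "contig"])
        mask = reads["contig"].isin(chr3).to_numpy()
        rng = np.random.default_rng(0)
        reads.loc[mask, "strand"] = rng.choice(["+", "-"], size=int(mask.sum()))
        grid = ss.BinGrid.fixed(ct.contig_lengths, 200_000)
        counts = ss.count_reads(reads, grid)
        model = sc.em_cluster(counts, K=8, seed=6)
        scaffolds = sc.filter_and_merge(model, ct.contig_lengths)
        table = scaffolds.contig_table.set_index("contig")
        for c in chr3:
            assert table.loc[c, "discard_reason"] == "always_wc"

    def test_short_contigs_dropped(self, fitted):
        counts, model, _ = fitted
        big = sc.filter_and_merge(model, min_contig_size=450_000)
        table = big.contig_table
        assert ((table["length"] < 450_000)
                == (table["discard_reason"] == "too_short")).all()

    def test_desired_clusters_warning_when_too_many(self, fitted):
        counts, model, _ = fitted
        with pytest.warns(UserWarning):
            sc.filter_and_merge(model, desired_clusters=50)


class TestSyncOrientation:
    @staticmethod
    def _states(pattern, flipped):
        """contigs x cells states: 'pattern' WW/CC per cell; flipped rows swap."""
        base = np.array([ss.WW if p == "W" else ss.CC for p in pattern])
        rows = []
        for f in flipped:
            rows.append(sc._FLIP[base] if f else base.copy())
        return np.array(rows)

    def test_all_concordant_no_flips(self):
        st = self._states("WWCCWCWC", [False] * 4)
        out = sc.sync_orientation(st, np.array([4, 3, 2, 1]), list("abcd"))
        assert set(out.values()) == {"+"}

    def test_single_opposing_contig_flipped(self):
        st = self._states("WWCCWCWCWC", [False, False, True, False])
        out = sc.sync_orientation(st, np.array([4.0, 3, 2, 1]), list("abcd"))
        assert out == {"a": "+", "b": "+", "c": "-", "d": "+"}

    def test_global_swap_two_fold_symmetry(self):
        st = self._states("WWCCWCWCWC", [False, False, True, False])
        st_sw = self._states("WWCCWCWCWC", [True, True, False, True])
        out = sc.sync_orientation(st, np.array([4.0, 3, 2, 1]), list("abcd"))
        out_sw = sc.sync_orientation(st_sw, np.array([4.0, 3, 2, 1]), list("abcd"))
        # same relative orientations: length-majority group is canonical +
        assert out == out_sw


class TestOrderContigs:
    @staticmethod
    def _random_instance(rng, n_contigs, n_cells):
        """Simulated SCE coinheritance: states along an ordered chromosome."""
        states = np.zeros((n_contigs, n_cells), dtype=np.int8)
        for j in range(n_cells):
            s = rng.integers(0, 3)
            for i in range(n_contigs):
                if rng.random() < 0.2:  # SCE between consecutive contigs
                    s = rng.integers(0, 3)
                states[i, j] = s
        return states

    def test_two_contigs_trivial(self):
        states = np.array([[ss.WW, ss.CC], [ss.WW, ss.WW]], dtype=np.int8)
        order, D, flag = sc.order_contigs(states, ["a", "b"])
        assert order == ["a", "b"]

    def test_tsp_matches_exhaustive_minimum(self):
        # brute force over all 6!/2 orders on SCE-rich random instances
        rng = np.random.default_rng(5)
        for trial in range(5):
            states = self._random_instance(rng, 6, 40)
            ids = [f"c{i}" for i in range(6)]
            order, D, flag = sc.order_contigs(states, ids, method="tsp")
            got = sc.path_cost(D, [ids.index(c) for c in order])
            best = min(sc.path_cost(D, list(p))
                       for p in itertools.permutations(range(6)))
            assert got == pytest.approx(best, abs=1e-12)

    def test_no_sce_low_confidence_flag(self):
        states = np.full((4, 30), ss.WW, dtype=np.int8)
        order, D, flag = sc.order_contigs(states, list("abcd"))
        assert flag and order == list("abcd")


@pytest.fixture(scope="module")
def error_run():
    g = sd.simulate_genome(sd.GenomeSpec((10_000_000,) * 3, 1e-3, seed=9))
    ct = sd.fragment_contigs(g, 1_200_000, n_chimeras=2, n_misorientations=2,
                             seed=9)
    data = sd.simulate_strandseq(g, ct, n_cells=80, reads_per_cell=6000,
                                 sce_rate=0.2, background=0.1, seed=9)
    grid = ss.BinGrid.fixed(ct.contig_lengths, 200_000)
    counts = ss.count_reads(data.reads, grid)
    model = sc.em_cluster(counts, K=15, seed=9)
    scaffolds = sc.filter_and_merge(model, ct.contig_lengths, desired_clusters=3)
    report = sc.detect_assembly_errors(model, scaffolds, reads=data.reads)
    return g, ct, data, model, scaffolds, report


class TestErrorDetectionAndCorrection:
    def test_injected_chimeras_found_within_one_bin(self, error_run):
        _, ct, _, _, _, report = error_run
        for _, e in ct.errors[ct.errors["type"] == "chimera"].iterrows():
            m = report.chimeras[report.chimeras["contig"] == e["contig"]]
            assert ((m["breakpoint"] - e["start"]).abs() <= 200_000).any()

    def test_injected_misorientations_found_within_one_bin(self, error_run):
        _, ct, _, _, _, report = error_run
        for _, e in ct.errors[ct.errors["type"] == "misorientation"].iterrows():
            m = report.misorientations[report.misorientations["contig"] == e["contig"]]
            assert len(m) > 0
            assert ((m["start"] - e["start"]).abs() <= 200_000).any()
            assert ((m["end"] - e["end"]).abs() <= 200_000).any()

    def test_clean_contigs_not_flagged(self, error_run):
        _, ct, _, _, _, report = error_run
        bad = set(ct.errors["contig"])
        flagged = set(report.chimeras["contig"]) | set(report.misorientations["contig"])
        assert flagged <= bad

    def test_corrections_reach_fixed_point(self, error_run):
        g, ct, data, model, scaffolds, report = error_run
        corrected, _, log = sc.apply_corrections(ct, report)
        replay = sd.simulate_strandseq(g, corrected, 80, 6000, sce_rate=0.2,
                                       background=0.1, seed=9,
                                       templates=data.templates, sces=data.sces)
        grid2 = ss.BinGrid.fixed(corrected.contig_lengths, 200_000)
        counts2 = ss.count_reads(replay.reads, grid2)
        model2 = sc.em_cluster(counts2, K=15, seed=9)
        scaffolds2 = sc.filter_and_merge(model2, corrected.contig_lengths,
                                         desired_clusters=3)
        report2 = sc.detect_assembly_errors(model2, scaffolds2, reads=replay.reads)
        assert report2.empty

    def test_chimera_split_conserves_length(self, error_run):
        g, ct, _, _, _, report = error_run
        corrected, _, _ = sc.apply_corrections(ct, report)
        assert (sum(corrected.contig_lengths.values())
                == sum(ct.contig_lengths.values()))

    def test_empty_report_is_identity(self, small_genome, small_contigs):
        empty = sc.AssemblyErrorReport(
            chimeras=pd.DataFrame(columns=["contig", "breakpoint", "bin_left",
                                           "bin_right", "cluster_left", "cluster_right"]),
            misorientations=pd.DataFrame(columns=["contig", "start", "end"]))
        seqs = {c: small_contigs.contig_sequence(small_genome, c)
                for c in small_contigs.contig_names[:2]}
        corrected, out_seqs, log = sc.apply_corrections(small_contigs, empty, seqs)
        pd.testing.assert_frame_equal(corrected.segments, small_contigs.segments)
        assert out_seqs == seqs and len(log) == 0

    def test_flip_correction_reverse_complements_sequence(self, small_genome):
        ct = sd.fragment_contigs(small_genome, 1_500_000, seed=3)
        contig = max(ct.contig_lengths, key=ct.contig_lengths.get)
        seq = ct.contig_sequence(small_genome, contig)
        report = sc.AssemblyErrorReport(
            chimeras=pd.DataFrame(columns=["contig", "breakpoint", "bin_left",
                                           "bin_right", "cluster_left", "cluster_right"]),
            misorientations=pd.DataFrame([{"contig": contig, "start": 1000,
                                           "end": 2000}]))
        corrected, seqs, _ = sc.apply_corrections(ct, report, {contig: seq})
        got = seqs[contig]
        assert got[1000:2000] == sd.revcomp(seq[1000:2000])
        assert got[:1000] == seq[:1000] and got[2000:] == seq[2000:]
        # the corrected truth segments describe the same sequence
        assert corrected.contig_sequence(small_genome, contig) == got

    def test_overlapping_corrections_rejected(self, small_contigs):
        contig = small_contigs.contig_names[0]
        report = sc.AssemblyErrorReport(
            chimeras=pd.DataFrame(columns=["contig", "breakpoint", "bin_left",
                                           "bin_right", "cluster_left", "cluster_right"]),
            misorientations=pd.DataFrame([
                {"contig": contig, "start": 1000, "end": 5000},
                {"contig": contig, "start": 4000, "end": 8000}]))
        with pytest.raises(ValueError):
            sc.apply_corrections(small_contigs, report)
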