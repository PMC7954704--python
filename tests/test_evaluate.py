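"""Evaluation statistics: phasing metrics, QV, N50, LOH segmentation,
collapse detection, common breaks, SD resolution."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandweave import evaluate as ev


def brute_switch_hamming(t1, t2, u1, u2):
    """Independent brute-force recount: both pairings, recode-and-compare."""
    t1, t2, u1, u2 = map(np.asarray, (t1, t2, u1, u2))
    best = None
    for u1p, u2p in ((u1, u2), (u2, u1)):
        ham = int((t1 != u1p).sum() + (t2 != u2p).sum())
        if best is None or ham < best[0]:
            s1 = [int(a != b) for a, b in zip(t1[:-1], t1[1:])]
            s2 = [int(a != b) for a, b in zip(t2[:-1], t2[1:])]
            r1 = [int(a != b) for a, b in zip(u1p[:-1], u1p[1:])]
            r2 = [int(a != b) for a, b in zip(u2p[:-1], u2p[1:])]
            sw = sum(a != b for a, b in zip(s1, r1)) + sum(a != b for a, b in zip(s2, r2))
            n = len(t1)
            best = (ham, (ham / n) / 2, (sw / n) / 2)
    return best[1], best[2]


class TestPhasingMetrics:
    def test_identical_phasing_zero(self):
        h1 = np.array([0, 1, 1, 0, 1])
        assert ev.hamming_rate(h1, 1 - h1, h1, 1 - h1) == 0.0
        assert ev.switch_error_rate(h1, 1 - h1, h1, 1 - h1) == 0.0

    def test_global_swap_absorbed(self):
        h1 = np.array([0, 1, 1, 0, 1])
        assert ev.hamming_rate(h1, 1 - h1, 1 - h1, h1) == 0.0
        assert ev.switch_error_rate(h1, 1 - h1, 1 - h1, h1) == 0.0

    def test_single_interior_flip_two_pair_differences(self):
        # flipping one interior site among n=10 changes 2 adjacent pairs
        truth = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        test = truth.copy()
        test[4] = 1 - test[4]
        rate = ev.switch_error_rate(test, 1 - test, truth, 1 - truth)
        assert rate == pytest.approx(2 / 10)

    def test_mhc_worked_example(self):
        # 4 mismatching sites among 1,433 -> 0.28% Hamming
        n = 1433
        truth = np.tile([0, 1], (n + 1) // 2)[:n]
        test = truth.copy()
        test[[10, 200, 700, 1200]] = 1 - test[[10, 200, 700, 1200]]
        rate = ev.hamming_rate(test, 1 - test, truth, 1 - truth)
        assert round(100 * rate, 2) == 0.28

    def test_complement_identity_forced_pairings(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 2, size=101)
        test = truth.copy()
        test[rng.choice(101, 7, replace=False)] ^= 1
        right = ev.hamming_rate(test, 1 - test, truth, 1 - truth, pairing=False)
        wrong = ev.hamming_rate(test, 1 - test, truth, 1 - truth, pairing=True)
        assert right + wrong == pytest.approx(1.0)

    def test_random_instances_match_brute_force(self):
        # oracle equivalence on random 20-site instances
        rng = np.random.default_rng(77)
        for _ in range(200):
            u1 = rng.integers(0, 2, size=20)
            t1 = u1.copy()
            flips = rng.random(20) < 0.2
            t1 = np.where(flips, 1 - t1, t1)
            bh, bs = brute_switch_hamming(t1, 1 - t1, u1, 1 - u1)
            assert ev.hamming_rate(t1, 1 - t1, u1, 1 - u1) == pytest.approx(bh)
            assert ev.switch_error_rate(t1, 1 - t1, u1, 1 - u1) == pytest.approx(bs)

    def test_unphased_sites_excluded(self):
        t1 = np.array([0, -1, 1, 0])
        u1 = np.array([0, 1, 1, 0])
        rate = ev.hamming_rate(t1, np.where(t1 >= 0, 1 - t1, -1), u1, 1 - u1)
        assert rate == 0.0

    def test_too_few_shared_sites_raises(self):
        with pytest.raises(ValueError):
            ev.switch_error_rate([0], [1], [0], [1])

    def test_per_chromosome_table(self):
        h = np.array([0, 1, 0, 1])
        test = {"chr1": (h, 1 - h), "chr2": (1 - h, h)}
        truth = {"chr1": (h, 1 - h), "chr2": (h, 1 - h)}
        table = ev.phasing_metrics_by_chromosome(test, truth)
        assert (table["hamming"] == 0).all() and (table["switch"] == 0).all()


class TestQV:
    def test_identity_99_gives_qv20(self):
        rep = ev.qv_from_alignment(99, 1, 0, 0)
        assert rep.qv == pytest.approx(20.0)

    def test_identity_9999_gives_qv40(self):
        rep = ev.qv_from_alignment(9999, 1, 0, 0)
        assert rep.qv == pytest.approx(40.0)

    def test_qv_4047_implies_over_10000_bases_per_error(self):
        # direct evaluation of 10^(40.47/10)
        bpe = 10 ** (40.47 / 10)
        assert bpe >= 10_000
        assert bpe == pytest.approx(1.11e4, rel=0.01)

    def test_indel_bases_count_as_errors(self):
        a = ev.qv_from_alignment(1000, 0, 3, 2)
        b = ev.qv_from_alignment(1000, 5, 0, 0)
        assert a.qv == pytest.approx(b.qv)

    def test_perfect_identity_capped(self):
        rep = ev.qv_from_alignment(100, 0, 0, 0)
        assert math.isinf(rep.qv)

    def test_scale_invariance_and_monotonicity(self):
        a = ev.qv_from_alignment(990, 10, 0, 0)
        b = ev.qv_from_alignment(1980, 20, 0, 0)
        assert a.qv == pytest.approx(b.qv)
        better = ev.qv_from_alignment(995, 5, 0, 0)
        assert better.qv > a.qv

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.qv_from_alignment(10, -1, 0, 0)


def brute_n50(lengths):
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    acc = 0
    for L in lengths:
        acc += L
        if acc * 2 >= total:
            return L


class TestN50:
    @pytest.mark.parametrize("lengths,expect", [
        ([100], 100), ([50, 50, 100], 100), ([1, 1, 1, 7], 7),
    ])
    def test_examples(self, lengths, expect):
        assert ev.contig_n50(lengths) == expect

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(300):
            lengths = rng.integers(1, 10_000, size=rng.integers(1, 40)).tolist()
            assert ev.contig_n50(lengths) == brute_n50(lengths)

    @given(st.lists(st.integers(1, 10**7), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_property_matches_oracle(self, lengths):
        assert ev.contig_n50(lengths) == brute_n50(lengths)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.contig_n50([])


class TestLOH:
    def _chromosome(self, length, loh_start=None, loh_end=None, seed=0):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(length, size=length // 1000, replace=False))
        het = np.ones(len(pos))
        if loh_start is not None:
            het[(pos >= loh_start) & (pos < loh_end)] = 0.0
        return pos, het

    def test_uniform_heterozygosity_single_norm_segment(self):
        pos, het = self._chromosome(30_000_000)
        with pytest.warns(UserWarning):
            seg = ev.detect_loh(pos, het, 30_000_000)
        assert len(seg) == 1 and seg.iloc[0]["genotype"] == "NORM"

    def test_injected_het_free_stretch_recovered(self):
        L = 50_000_000
        a, b = 20_000_000, 25_000_000
        pos, het = self._chromosome(L, a, b, seed=3)
        seg = ev.detect_loh(pos, het, L)
        loh = seg[seg["genotype"] == "LOH"]
        assert len(loh) >= 1
        s, e = int(loh.iloc[0]["start"]), int(loh.iloc[0]["end"])
        overlap = max(0, min(e, b) - max(s, a))
        assert overlap / (b - a) >= 0.95
        assert (e - s) <= (b - a) * 1.2

    def test_segments_tile_chromosome(self):
        L = 50_000_000
        pos, het = self._chromosome(L, 10_000_000, 18_000_000, seed=5)
        seg = ev.detect_loh(pos, het, L)
        assert seg.iloc[0]["start_bin"] == 0
        assert (seg["start_bin"].iloc[1:].to_numpy()
                == seg["end_bin"].iloc[:-1].to_numpy()).all()

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            ev.detect_loh([100], [1.0], 500_000)


class TestCollapses:
    def _track(self, spikes=(), mean=30.0, sd=5.0, n=2000, step=1000, seed=0):
        rng = np.random.default_rng(seed)
        cov = rng.normal(mean, sd, size=n)
        rows = pd.DataFrame({
            "chrom": "ctg1",
            "start": np.arange(n) * step,
            "end": (np.arange(n) + 1) * step,
            "coverage": cov,
        })
        for s, e, mult in spikes:
            m = (rows["start"] >= s) & (rows["start"] < e)
            rows.loc[m, "coverage"] = mean * mult
        return rows

    def test_uniform_coverage_no_collapses(self):
        out = ev.detect_collapses(self._track())
        assert len(out) == 0

    def test_injected_doubled_region_found(self):
        out = ev.detect_collapses(self._track(spikes=[(1_000_000, 1_020_000, 2.0)]))
        assert len(out) == 1
        assert abs(out.iloc[0]["start"] - 1_000_000) <= 1000
        assert abs(out.iloc[0]["end"] - 1_020_000) <= 1000

    def test_repeat_annotated_region_excluded(self):
        track = self._track(spikes=[(1_000_000, 1_020_000, 2.0)])
        repeats = pd.DataFrame([{"chrom": "ctg1", "start": 1_000_000,
                                 "end": 1_016_000}])  # 80% of the collapse
        out = ev.detect_collapses(track, repeat_annotation=repeats)
        assert len(out) == 0

    def test_short_spike_below_min_len_ignored(self):
        out = ev.detect_collapses(self._track(spikes=[(1_000_000, 1_010_000, 2.0)]))
        assert len(out) == 0

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            ev.detect_collapses(pd.DataFrame(columns=["chrom", "start", "end",
                                                      "coverage"]))


def _tiling(breaks, chrom="chr1", length=20_000_000, name="ctg"):
    """Contig intervals on a reference with gaps at the given midpoints."""
    edges = [0] + sorted(breaks) + [length]
    rows = []
    for i in range(len(edges) - 1):
        s, e = edges[i], edges[i + 1]
        rows.append({"chrom": chrom, "start": s + (2000 if i else 0),
                     "end": e - 2000 if i < len(edges) - 2 else e,
                     "contig": f"{name}{i}"})
    return pd.DataFrame(rows)


class TestCommonBreaks:
    def test_identical_tilings_one_common_break(self):
        t = {"A": _tiling([7_000_000]), "B": _tiling([7_000_000], name="x")}
        out = ev.common_breaks(t)
        assert len(out) == 1

    def test_breaks_in_different_bins_not_common(self):
        t = {"A": _tiling([7_000_000]), "B": _tiling([9_000_000], name="x")}
        assert len(ev.common_breaks(t)) == 0

    def test_shared_and_private_breaks_enumeration(self):
        shared = [3_000_000, 8_000_000, 15_000_000]
        t = {"A": _tiling(shared + [5_000_000]),
             "B": _tiling(shared + [11_000_000], name="x")}
        out = ev.common_breaks(t)
        assert len(out) == 3

    def test_adding_assembly_monotone(self):
        shared = [3_000_000, 8_000_000]
        t2 = {"A": _tiling(shared + [5_000_000]), "B": _tiling(shared, name="x")}
        t3 = dict(t2, C=_tiling([3_000_000], name="y"))
        assert len(ev.common_breaks(t3)) <= len(ev.common_breaks(t2))

    def test_small_contigs_filtered(self):
        # a 50-kbp sliver between two gaps is dropped, merging its gaps
        t = {"A": _tiling([7_000_000, 7_050_000]), "B": _tiling([7_000_000], name="x")}
        out = ev.common_breaks(t)
        assert len(out) == 1

    def test_annotation_within_slop(self):
        t = {"A": _tiling([7_000_000]), "B": _tiling([7_000_000], name="x")}
        ann = {"sd": pd.DataFrame([{"chrom": "chr1", "start": 7_005_000,
                                    "end": 7_020_000}])}
        out = ev.common_breaks(t, annotations=ann)
        assert bool(out.iloc[0]["sd"])

    def test_single_assembly_rejected(self):
        with pytest.raises(ValueError):
            ev.common_breaks({"A": _tiling([7_000_000])})


class TestSDResolution:
    def _sds(self):
        return pd.DataFrame([{"chrom": "chr1", "start": 1_000_000, "end": 1_100_000}])

    def test_wide_alignment_resolves_all_extensions(self):
        aln = pd.DataFrame([{"chrom": "chr1", "start": 940_000, "end": 1_160_000}])
        avg, per_x = ev.sd_resolution(aln, self._sds())
        assert avg == 100.0 and all(v == 100.0 for v in per_x.values())

    def test_one_short_flank_unresolved_everywhere(self):
        aln = pd.DataFrame([{"chrom": "chr1", "start": 900_000, "end": 1_105_000}])
        avg, per_x = ev.sd_resolution(aln, self._sds())
        assert avg == 0.0

    def test_split_alignments_unresolved(self):
        aln = pd.DataFrame([
            {"chrom": "chr1", "start": 900_000, "end": 1_050_000},
            {"chrom": "chr1", "start": 1_050_000, "end": 1_200_000}])
        avg, _ = ev.sd_resolution(aln, self._sds())
        assert avg == 0.0

    def test_partial_grid_resolution_averaged(self):
        # 25 kbp flanks: resolved at 10/20 kbp, unresolved at 30/40/50 kbp
        aln = pd.DataFrame([{"chrom": "chr1", "start": 975_000, "end": 1_125_000}])
        avg, per_x = ev.sd_resolution(aln, self._sds())
        assert per_x[10_000] == 100.0 and per_x[30_000] == 0.0
        assert avg == pytest.approx(40.0)

    def test_empty_sd_set_rejected(self):
        with pytest.raises(ValueError):
            ev.sd_resolution(pd.DataFrame(columns=["chrom", "start", "end"]),
                             pd.DataFrame(columns=["chrom", "start", "end"]))
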