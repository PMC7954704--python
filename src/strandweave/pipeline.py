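"""End-to-end orchestration: simulate -> count -> cluster -> phase ->
haplotag -> evaluate, plus the library-downsampling experiment.

The pipeline operates in memory on the simulator's outputs (or caller-
provided equivalents) and produces a JSON-serializable report with one
section per enabled stage.  All randomness flows from ``RunConfig.seed``;
the same configuration and seed reproduce the report exactly (wall-clock
aside).
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import evaluate as ev
from . import haplotag as ht
from . import saarclust as sc
from . import simdata as sd
from . import strandphase as sp
from . import strandstate as ss


class StageError(RuntimeError):
    """A pipeline stage failed or its dependencies are disabled."""


@dataclass
class RunConfig:
    """All stage parameters in one place.

    Defaults are the standard Strand-seq analysis settings: 200-kbp bins,
    ambiguity threshold 0.25, 100-kbp minimum contig size, 500-kbp
    genotyping windows with background 0.1 and 50-read minimum, 5-Mbp WC
    region collapse/minimum, phasing quality filters mapq 10 / baseq 20
    with 2 iterations.  Simulation sizes default to the synthetic study
    scale (5 chromosomes x 10 Mbp, 120 libraries); ``num_clusters`` is
    scaled accordingly (human-scale runs would use 100-150)."""

    # genome
    chrom_lengths: tuple = (10_000_000,) * 5
    snv_density: float = 1.0e-3
    # contig tiling
    target_n50: int = 800_000
    n_chimeras: int = 0
    n_misorientations: int = 0
    # Strand-seq libraries
    n_cells: int = 120
    reads_per_cell: int = 10_000
    sce_rate: float = 0.2
    background: float = 0.1
    read_length: int = 100
    strand_allele_error: float = 0.0
    # long reads
    lr_coverage: float = 10.0
    lr_mean_length: int = 15_000
    lr_allele_error: float = 0.0
    # clustering
    bin_size: int = 200_000
    num_clusters: int = 30
    prob_th: float = 0.25
    agreement_th: float = 0.7
    desired_clusters: int | None = None
    min_contig_size: int = 100_000
    order_method: str = "tsp"
    # strand-state genotyping
    windowsize: int = 500_000
    min_reads: int = 50
    state_background: float = 0.1
    wc_min_region: int = 5_000_000
    wc_collapse: int = 5_000_000
    # phasing
    min_baseq: int = 20
    min_mapq: int = 10
    num_iterations: int = 2
    min_support: int = 2
    margin: float = 0.8
    # stage switches
    run_errors: bool = False
    run_phase: bool = True
    run_haplotag: bool = True
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        import yaml

        d = asdict(self)
        d["chrom_lengths"] = list(d["chrom_lengths"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["chrom_lengths"] = tuple(d["chrom_lengths"])
        return cls(**d)


@dataclass
class SimBundle:
    genome: sd.Genome
    contigs: sd.ContigSet
    ssdata: sd.StrandSeqData
    lreads: sd.LongReadSet | None


def simulate_inputs(config: RunConfig) -> SimBundle:
    genome = sd.simulate_genome(sd.GenomeSpec(
        chrom_lengths=tuple(config.chrom_lengths),
        snv_density=config.snv_density, seed=config.seed))
    contigs = sd.fragment_contigs(
        genome, target_n50=config.target_n50, n_chimeras=config.n_chimeras,
        n_misorientations=config.n_misorientations, seed=config.seed)
    ssdata = sd.simulate_strandseq(
        genome, contigs, n_cells=config.n_cells,
        reads_per_cell=config.reads_per_cell, sce_rate=config.sce_rate,
        background=config.background, read_length=config.read_length,
        allele_error=config.strand_allele_error, seed=config.seed)
    lreads = None
    if config.run_phase and config.run_haplotag:
        lreads = sd.simulate_long_reads(
            genome, mean_length=config.lr_mean_length,
            coverage=config.lr_coverage, allele_error=config.lr_allele_error,
            seed=config.seed)
    return SimBundle(genome=genome, contigs=contigs, ssdata=ssdata, lreads=lreads)


# ---------------------------------------------------------------------------
# scaffolding helpers
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldLayout:
    """Per-cluster contig order/orientation and scaffold offsets."""

    order: dict[int, list[str]]
    orientation: dict[str, str]
    offsets: dict[str, int]
    cluster_of: dict[str, int]
    cluster_length: dict[int, int]
    low_confidence: dict[int, bool]


def build_layout(scaffolds: sc.ScaffoldSet, counts: ss.CountMatrix,
                 config: RunConfig) -> ScaffoldLayout:
    """Orient and order each merged cluster and lay contigs end to end."""
    Wc, Cc, contig_list = counts.contig_totals()
    states = ss.call_strand_state(Wc, Cc, background=config.state_background,
                                  min_reads=config.min_reads)
    cidx = {c: i for i, c in enumerate(contig_list)}
    lengths = {c: int((counts.grid.bins.loc[counts.grid.bins["contig"] == c, "end"]
                       - counts.grid.bins.loc[counts.grid.bins["contig"] == c, "start"]).sum())
               for c in contig_list}
    order: dict[int, list[str]] = {}
    orientation: dict[str, str] = {}
    low_conf: dict[int, bool] = {}
    for cluster, members in scaffolds.cluster_members.items():
        st = states[[cidx[c] for c in members]]
        lens = np.array([lengths[c] for c in members], dtype=float)
        orient = sc.sync_orientation(st, lens, list(members))
        orientation.update(orient)
        # orientation-corrected states for coinheritance ordering
        st2 = st.copy()
        for i, c in enumerate(members):
            if orient[c] == "-":
                known = st2[i] != ss.UNKNOWN
                st2[i, known] = sc._FLIP[st2[i, known]]
        ordered, _, flag = sc.order_contigs(st2, list(members), method=config.order_method)
        order[cluster] = ordered
        low_conf[cluster] = flag
    offsets, cluster_of, cluster_length = {}, {}, {}
    for cluster, members in order.items():
        off = 0
        for c in members:
            offsets[c] = off
            cluster_of[c] = cluster
            off += lengths[c]
        cluster_length[cluster] = off
    return ScaffoldLayout(order=order, orientation=orientation, offsets=offsets,
                          cluster_of=cluster_of, cluster_length=cluster_length,
                          low_confidence=low_conf)


def lift_reads_to_scaffolds(reads: pd.DataFrame, layout: ScaffoldLayout,
                            contig_lengths: dict[str, int]) -> pd.DataFrame:
    """Express contig read placements in cluster-scaffold coordinates."""
    sub = reads[reads["contig"].isin(layout.cluster_of)].copy()
    contig = sub["contig"].to_numpy()
    pos = sub["pos"].to_numpy()
    off = np.array([layout.offsets[c] for c in contig])
    clen = np.array([contig_lengths[c] for c in contig])
    minus = np.array([layout.orientation[c] == "-" for c in contig])
    newpos = np.where(minus, clen - 1 - pos, pos) + off
    strand = sub["strand"].to_numpy().copy()
    flip = minus
    strand = np.where(flip, np.where(strand == "+", "-", "+"), strand)
    sub["pos"] = newpos
    sub["strand"] = strand
    sub["contig"] = [f"scaffold{layout.cluster_of[c]}" for c in contig]
    return sub


def snv_scaffold_positions(genome: sd.Genome, contigs: sd.ContigSet,
                           layout: ScaffoldLayout) -> pd.DataFrame:
    """Locate each het SNV on its contig and cluster scaffold.

    Mirrors variant calling on the clustered assembly: positions are known
    in contig coordinates; the truth segment map provides them here.
    """
    seg = contigs.segments
    rows = []
    clens = contigs.contig_lengths
    for _, s in seg.iterrows():
        sub = genome.snvs[(genome.snvs["chrom"] == s["chrom"])
                          & (genome.snvs["pos"] >= s["start"])
                          & (genome.snvs["pos"] < s["end"])]
        if len(sub) == 0:
            continue
        gpos = sub["pos"].to_numpy()
        if s["strand"] == "+":
            cpos = s["c_start"] + (gpos - s["start"])
        else:
            cpos = s["c_start"] + (s["end"] - 1 - gpos)
        contig = s["contig"]
        if contig not in layout.cluster_of:
            continue
        if layout.orientation[contig] == "-":
            spos = clens[contig] - 1 - cpos
        else:
            spos = cpos
        rows.append(pd.DataFrame({
            "snv_id": sub.index.to_numpy(), "contig": contig,
            "cluster": layout.cluster_of[contig],
            "scaffold_pos": spos + layout.offsets[contig],
        }))
    if not rows:
        return pd.DataFrame(columns=["snv_id", "contig", "cluster", "scaffold_pos"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# truth-based metrics
# ---------------------------------------------------------------------------


def clustering_accuracy(scaffolds: sc.ScaffoldSet, contigs: sd.ContigSet) -> dict:
    """Fraction of retained contig length assigned to the true chromosome.

    Each merged cluster is labelled with its majority chromosome by length;
    a contig counts as correct when its (majority) true chromosome matches.
    """
    table = scaffolds.contig_table
    retained = table[table["cluster"] >= 0]
    truth = {c: contigs.true_chromosome(c) for c in retained["contig"]}
    lengths = contigs.contig_lengths
    label: dict[int, str] = {}
    for cl, sub in retained.groupby("cluster"):
        by: dict[str, float] = {}
        for c in sub["contig"]:
            by[truth[c]] = by.get(truth[c], 0) + lengths[c]
        label[cl] = max(sorted(by), key=lambda k: by[k])
    good = sum(lengths[c] for _, r in retained.iterrows()
               for c in [r["contig"]] if truth[c] == label[r["cluster"]])
    total = sum(lengths[c] for c in retained["contig"])
    return {"length_accuracy": good / total if total else 0.0,
            "n_clusters": len(label),
            "retained_length": int(total),
            "cluster_chromosome": label}


def orientation_accuracy(layout: ScaffoldLayout, contigs: sd.ContigSet) -> float:
    """Length fraction of correctly oriented contigs, best global flip per
    cluster (the plus/minus frame of a scaffold is arbitrary)."""
    lengths = contigs.contig_lengths
    good = bad = 0.0
    for cluster, members in layout.order.items():
        match = flip = 0.0
        for c in members:
            L = lengths[c]
            if layout.orientation[c] == contigs.true_orientation(c):
                match += L
            else:
                flip += L
        good += max(match, flip)
        bad += min(match, flip)
    return good / (good + bad) if good + bad else 0.0


def order_correlation(layout: ScaffoldLayout, contigs: sd.ContigSet) -> float:
    """Mean |Spearman| between inferred and true contig order per cluster."""
    truth = contigs.true_order().set_index("contig")
    rhos, weights = [], []
    for cluster, members in layout.order.items():
        ranks_true = [int(truth.loc[c, "order_index"]) for c in members if c in truth.index]
        if len(ranks_true) < 3:
            continue
        ranks_inf = [i for i, c in enumerate(members) if c in truth.index]
        rho = spearmanr(ranks_inf, ranks_true).statistic
        if np.isnan(rho):
            continue
        rhos.append(abs(float(rho)))
        weights.append(len(ranks_true))
    if not rhos:
        return float("nan")
    return float(np.average(rhos, weights=weights))


def phasing_truth_arrays(blocks: dict, genome: sd.Genome, snv_map: pd.DataFrame
                         ) -> tuple[dict, dict]:
    """Aligned (test, truth) haplotype arrays per cluster for the metrics."""
    test, truth = {}, {}
    for cluster, block in blocks.items():
        ids = block.snv_ids.astype(int)
        test[cluster] = (block.h1, block.h2)
        truth[cluster] = (genome.snvs.loc[ids, "h1"].to_numpy(),
                          genome.snvs.loc[ids, "h2"].to_numpy())
    return test, truth


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, bundle: SimBundle | None = None) -> dict:
    """Run all enabled stages and return the report dictionary."""
    t0 = time.time()
    if config.run_haplotag and not config.run_phase:
        raise StageError("haplotag stage requires the phase stage")
    if bundle is None:
        bundle = simulate_inputs(config)
    genome, contigs, ssdata = bundle.genome, bundle.contigs, bundle.ssdata
    report: dict = {"config": {**asdict(config),
                               "chrom_lengths": list(config.chrom_lengths)},
                    "stages": {}}

    # counting
    grid = ss.BinGrid.fixed(contigs.contig_lengths, bin_size=config.bin_size)
    counts = ss.count_reads(ssdata.reads, grid, min_mapq=config.min_mapq,
                            cells=ssdata.cells)
    report["stages"]["count"] = {
        "n_bins": len(grid.bins), "n_cells": len(counts.cells),
        "retained_reads": int(counts.n.sum()), "skipped_reads": counts.n_skipped,
    }

    # clustering
    model = sc.em_cluster(counts, K=config.num_clusters, seed=config.seed)
    scaffolds = sc.filter_and_merge(
        model, contigs.contig_lengths, prob_th=config.prob_th,
        agreement_th=config.agreement_th, desired_clusters=config.desired_clusters,
        min_contig_size=config.min_contig_size, min_reads=config.min_reads,
        background=config.state_background)
    layout = build_layout(scaffolds, counts, config)
    acc = clustering_accuracy(scaffolds, contigs)
    report["stages"]["cluster"] = {
        "n_merged_clusters": scaffolds.n_clusters,
        "em_iterations": len(model.loglik),
        "length_accuracy": acc["length_accuracy"],
        "retained_length": acc["retained_length"],
        "orientation_accuracy": orientation_accuracy(layout, contigs),
        "order_spearman": order_correlation(layout, contigs),
    }

    if config.run_errors:
        errors = sc.detect_assembly_errors(model, scaffolds, reads=ssdata.reads,
                                           background=config.state_background)
        report["stages"]["errors"] = {
            "n_chimeras": len(errors.chimeras),
            "n_misorientations": len(errors.misorientations),
        }
        report["_errors"] = errors

    blocks: dict = {}
    if config.run_phase:
        lifted = lift_reads_to_scaffolds(ssdata.reads, layout, contigs.contig_lengths)
        scaffold_lengths = {f"scaffold{k}": v for k, v in layout.cluster_length.items()}
        win = ss.window_states(lifted, scaffold_lengths, windowsize=config.windowsize,
                               min_reads=config.min_reads,
                               background=config.state_background,
                               min_mapq=config.min_mapq)
        wc = ss.export_wc_regions(win, min_region=config.wc_min_region,
                                  collapse=config.wc_collapse)
        snv_map = snv_scaffold_positions(genome, contigs, layout)
        phased_sites = total_sites = 0
        backbone_sites = 0
        for cluster in layout.order:
            sub = snv_map[snv_map["cluster"] == cluster].sort_values("scaffold_pos")
            if len(sub) == 0:
                continue
            name = f"scaffold{cluster}"
            creads = lifted[lifted["contig"] == name]
            cregions = ss.WCRegionSet(wc.regions[wc.regions["contig"] == name])
            pm = sp.build_phase_matrix(creads, ssdata.alleles, cregions,
                                       sub["snv_id"].to_numpy(),
                                       min_baseq=config.min_baseq,
                                       min_mapq=config.min_mapq, cluster=cluster)
            block = sp.phase_strands(pm, num_iterations=config.num_iterations)
            block.block_id = cluster
            backbone_sites += int(block.phased.sum())
            if bundle.lreads is not None:
                block = sp.extend_with_long_reads(
                    block, bundle.lreads.alleles, min_support=config.min_support,
                    margin=config.margin)
            blocks[cluster] = block
            phased_sites += int(block.phased.sum())
            total_sites += len(block.h1)
        test, truth = phasing_truth_arrays(blocks, genome, snv_map)
        metrics = ev.phasing_metrics_by_chromosome(test, truth)
        report["stages"]["phase"] = {
            "total_het_snvs": int(len(genome.snvs)),
            "clustered_het_snvs": total_sites,
            "backbone_phased_fraction": backbone_sites / total_sites if total_sites else 0.0,
            "phased_fraction": phased_sites / total_sites if total_sites else 0.0,
            "largest_block_fraction": phased_sites / total_sites if total_sites else 0.0,
            "switch_error": float(np.average(metrics["switch"], weights=metrics["n_shared"]))
            if len(metrics) else float("nan"),
            "hamming": float(np.average(metrics["hamming"], weights=metrics["n_shared"]))
            if len(metrics) else float("nan"),
        }
        report["_blocks"] = blocks

    if config.run_haplotag:
        lreads = bundle.lreads
        tags = ht.haplotag_reads(lreads.alleles, blocks,
                                 read_ids=lreads.reads["read_id"].to_numpy())
        split = ht.split_reads(tags)
        n = len(lreads.reads)
        tagged = int((tags["tag"] > 0).sum())
        # correctness vs truth, per cluster up to H1/H2 swap
        merged = tags.merge(lreads.reads[["read_id", "hap"]], on="read_id")
        correct = 0
        for cluster, sub in merged[merged["tag"] > 0].groupby("cluster"):
            agree = int((sub["tag"] == sub["hap"]).sum())
            correct += max(agree, len(sub) - agree)
        report["stages"]["haplotag"] = {
            "n_reads": n, "tagged_fraction": tagged / n if n else 0.0,
            "tag_accuracy": correct / tagged if tagged else float("nan"),
            "partition_sizes": {k: len(v) for k, v in split.items()},
            "partition_conserved": sum(len(v) for v in split.values()) == n,
        }

    report["stages"]["evaluate"] = {
        "contig_n50": ev.contig_n50(list(contigs.contig_lengths.values())),
    }
    report["wall_clock_s"] = round(time.time() - t0, 3)
    return report


def report_to_json(report: dict, path: str) -> None:
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    with open(path, "w") as fh:
        json.dump(clean, fh, indent=2, default=str)


def downsample_experiment(config: RunConfig, fractions: Sequence[float],
                          replicates: int = 1, seed: int | None = None,
                          bundle: SimBundle | None = None) -> pd.DataFrame:
    """Re-run the pipeline on random library subsets.

    Returns one row per (fraction, replicate) with clustering accuracy and
    the tagged-read fraction; fractions yielding zero cells are skipped with
    a warning.
    """
    if seed is None:
        seed = config.seed
    if bundle is None:
        bundle = simulate_inputs(config)
    rows = []
    for frac in fractions:
        for rep in range(replicates):
            k = int(np.floor(frac * len(bundle.ssdata.cells)))
            if k == 0:
                warnings.warn(f"fraction {frac} yields zero cells; skipped")
                continue
            cells = sd.subsample_libraries(bundle.ssdata.cells, frac,
                                           seed=seed + 1000 * rep)
            sub = replace(config, n_cells=len(cells))
            subbundle = SimBundle(genome=bundle.genome, contigs=bundle.contigs,
                                  ssdata=bundle.ssdata.subset(cells),
                                  lreads=bundle.lreads)
            rep_report = run_pipeline(sub, bundle=subbundle)
            rows.append({
                "fraction": frac, "replicate": rep, "n_cells": len(cells),
                "length_accuracy": rep_report["stages"]["cluster"]["length_accuracy"],
                "n_merged_clusters": rep_report["stages"]["cluster"]["n_merged_clusters"],
                "tagged_fraction": rep_report["stages"].get("haplotag", {}).get(
                    "tagged_fraction", float("nan")),
            })
    return pd.DataFrame(rows)
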