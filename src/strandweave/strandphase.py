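"""Chromosome-length haplotype phasing from Watson-Crick strand signal.

Within a WC cell-chromosome, all Watson reads originate from one homolog
and all Crick reads from the other, so every heterozygous SNV observed in a
haplotype-informative (WC) region contributes a phased allele regardless of
physical distance.  The phase matrix collects these observations as one
Watson row and one Crick row per cell; an iterative strand-assignment
procedure (the concrete rule is pinned below so results are exactly
reproducible) builds consensus haplotypes, which are then densified with
long-read allele observations.

Entries are 0 (ref), 1 (alt) or -1 (missing).  Haplotype labels are
canonicalized so H1 carries the ref allele at the first phased site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .strandstate import WCRegionSet

MISSING = np.int8(-1)


@dataclass
class PhaseMatrix:
    """Per-(cell, template strand) allele observations at cluster het SNVs."""

    data: np.ndarray            # rows x sites, int8 in {-1, 0, 1}
    rows: list[tuple[str, str]]  # (cell, 'W'|'C')
    snv_ids: np.ndarray
    cluster: int | str | None = None

    @property
    def n_sites(self) -> int:
        return len(self.snv_ids)


@dataclass
class HaplotypeBlock:
    """Phased alleles H1/H2 per SNV; -1 marks unphased sites."""

    snv_ids: np.ndarray
    h1: np.ndarray
    h2: np.ndarray
    support: np.ndarray  # votes per site
    cluster: int | str | None = None
    block_id: int = 0

    @property
    def phased(self) -> np.ndarray:
        return self.h1 >= 0

    @property
    def phased_fraction(self) -> float:
        return float(self.phased.mean()) if len(self.h1) else 0.0

    def copy(self) -> "HaplotypeBlock":
        return HaplotypeBlock(self.snv_ids.copy(), self.h1.copy(), self.h2.copy(),
                              self.support.copy(), self.cluster, self.block_id)


def build_phase_matrix(reads: pd.DataFrame, alleles: pd.DataFrame,
                       wc_regions: WCRegionSet, snv_ids: np.ndarray,
                       min_baseq: int = 20, min_mapq: int = 10,
                       cluster=None) -> PhaseMatrix:
    """Collect strand-resolved allele observations inside WC regions.

    ``reads`` must be on the same coordinate system as ``wc_regions``
    (cluster scaffolds): columns read_id, cell, contig, pos, strand, mapq,
    dup.  ``alleles`` carries (read_id, snv_id, allele, baseq).  Watson
    reads populate the cell's W row, Crick reads the C row; conflicting
    duplicate observations at one (row, SNV) are resolved by majority, ties
    become missing.
    """
    snv_ids = np.asarray(snv_ids)
    col_of = {int(s): i for i, s in enumerate(snv_ids)}
    keep = (reads["mapq"] >= min_mapq) & (~reads["dup"].astype(bool))
    sub = reads[keep]

    # membership test: read inside one of its cell's WC regions.  Rows are
    # built per (cell, region): after an SCE pair the Watson template can
    # belong to different homologs in two WC regions of the same cell, so
    # regions must be assigned to haplotypes independently.
    reg = wc_regions.regions
    in_region = np.zeros(len(sub), dtype=bool)
    region_key = np.empty(len(sub), dtype=object)
    pos = sub["pos"].to_numpy()
    for (cell, contig), g in reg.groupby(["cell", "contig"], sort=False):
        mask = ((sub["cell"] == cell) & (sub["contig"] == contig)).to_numpy()
        if not mask.any():
            continue
        g = g.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        p = pos[mask]
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
        in_region[mask] = ok
        keys = np.array([f"{cell}:{contig}:{i}" for i in idx], dtype=object)
        region_key[mask] = keys
    sub = sub.assign(row_cell=region_key)[in_region]

    obs = alleles[alleles["baseq"] >= min_baseq] if "baseq" in alleles else alleles
    obs = obs[obs["snv_id"].isin(col_of)]
    obs = obs.merge(sub[["read_id", "row_cell", "strand"]], on="read_id", how="inner")
    obs = obs.rename(columns={"row_cell": "cell"})
    if len(obs) == 0:
        return PhaseMatrix(data=np.empty((0, len(snv_ids)), dtype=np.int8),
                           rows=[], snv_ids=snv_ids, cluster=cluster)

    obs["template"] = np.where(obs["strand"] == "-", "W", "C")
    votes = (obs.groupby(["cell", "template", "snv_id"])["allele"]
             .agg(n1="sum", n="count").reset_index())
    votes["n0"] = votes["n"] - votes["n1"]
    votes = votes[votes["n0"] != votes["n1"]]
    if len(votes) == 0:
        return PhaseMatrix(data=np.empty((0, len(snv_ids)), dtype=np.int8),
                           rows=[], snv_ids=snv_ids, cluster=cluster)
    votes["allele"] = (votes["n1"] > votes["n0"]).astype(np.int8)

    row_keys = sorted(set(zip(votes["cell"], votes["template"])))
    row_of = {rk: i for i, rk in enumerate(row_keys)}
    data = np.full((len(row_keys), len(snv_ids)), MISSING, dtype=np.int8)
    ri = np.array([row_of[(c, t)] for c, t in zip(votes["cell"], votes["template"])])
    ci = np.array([col_of[int(s)] for s in votes["snv_id"]])
    data[ri, ci] = votes["allele"].to_numpy()
    return PhaseMatrix(data=data, rows=row_keys, snv_ids=snv_ids, cluster=cluster)


def _canonicalize(h1: np.ndarray, h2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """H1 carries the ref allele at the first phased site."""
    phased = np.flatnonzero(h1 >= 0)
    if phased.size and h1[phased[0]] == 1:
        return h2, h1
    return h1, h2


def phase_strands(matrix: PhaseMatrix, num_iterations: int = 2) -> HaplotypeBlock:
    """Iterative strand-to-haplotype assignment with majority consensus.

    Initialization takes the row with the most observations as H1 and its
    partner row (the other template strand of the same cell) as H2,
    complemented where missing.  Each iteration assigns every cell's (W, C)
    row pair to (H1, H2) or (H2, H1), whichever minimizes mismatches against
    the current consensus, then rebuilds the consensus per site by majority
    vote (ties stay unphased).  Deterministic given the input row order.
    """
    nsites = matrix.n_sites
    if len(matrix.rows) == 0 or nsites == 0:
        return HaplotypeBlock(snv_ids=np.asarray(matrix.snv_ids),
                              h1=np.full(nsites, MISSING), h2=np.full(nsites, MISSING),
                              support=np.zeros(nsites, dtype=np.int32),
                              cluster=matrix.cluster)
    data = matrix.data
    cells = list(dict.fromkeys(c for c, _ in matrix.rows))
    w_row = {c: None for c in cells}
    c_row = {c: None for c in cells}
    for i, (cell, t) in enumerate(matrix.rows):
        (w_row if t == "W" else c_row)[cell] = i

    counts = (data >= 0).sum(axis=1)
    seed_row = int(np.argmax(counts))
    seed_cell, seed_t = matrix.rows[seed_row]
    partner = (c_row if seed_t == "W" else w_row)[seed_cell]
    h1 = data[seed_row].copy()
    h2 = data[partner].copy() if partner is not None else np.full(nsites, MISSING, dtype=np.int8)
    fill = (h2 < 0) & (h1 >= 0)
    h2[fill] = 1 - h1[fill]
    fill = (h1 < 0) & (h2 >= 0)
    h1[fill] = 1 - h2[fill]

    swap = {c: False for c in cells}
    for _ in range(max(1, num_iterations)):
        # assign each cell's row pair to the consensus
        for cell in cells:
            iw, ic = w_row[cell], c_row[cell]
            rw = data[iw] if iw is not None else None
            rc = data[ic] if ic is not None else None
            m_id = _mismatches(rw, h1) + _mismatches(rc, h2)
            m_sw = _mismatches(rw, h2) + _mismatches(rc, h1)
            if m_sw < m_id:
                swap[cell] = True
            elif m_id < m_sw:
                swap[cell] = False
            # ties keep the previous assignment
        # consensus: votes for the H1 allele
        votes1 = np.zeros(nsites, dtype=np.int32)
        votes0 = np.zeros(nsites, dtype=np.int32)
        for cell in cells:
            iw, ic = w_row[cell], c_row[cell]
            to_h1 = data[ic] if swap[cell] else (data[iw] if iw is not None else None)
            to_h2 = data[iw] if swap[cell] else (data[ic] if ic is not None else None)
            if swap[cell] and ic is None:
                to_h1 = None
            if swap[cell] and iw is None:
                to_h2 = None
            if to_h1 is not None:
                votes1 += to_h1 == 1
                votes0 += to_h1 == 0
            if to_h2 is not None:  # partner strand votes the complement
                votes1 += to_h2 == 0
                votes0 += to_h2 == 1
        h1 = np.where(votes1 > votes0, 1, np.where(votes0 > votes1, 0, MISSING)).astype(np.int8)
        h2 = np.where(h1 >= 0, 1 - h1, MISSING).astype(np.int8)
    h1, h2 = _canonicalize(h1, h2)
    return HaplotypeBlock(snv_ids=np.asarray(matrix.snv_ids), h1=h1, h2=h2,
                          support=(votes1 + votes0).astype(np.int32),
                          cluster=matrix.cluster)


def _mismatches(row: np.ndarray | None, hap: np.ndarray) -> int:
    if row is None:
        return 0
    both = (row >= 0) & (hap >= 0)
    return int((row[both] != hap[both]).sum())


def assign_reads_to_haplotypes(block: HaplotypeBlock, lr_alleles: pd.DataFrame
                               ) -> pd.DataFrame:
    """Majority-vote read assignment against backbone-phased sites.

    Returns one row per read with agreement counts n_h1/n_h2 and ``hap`` in
    {1, 2, 0} (0 = unassigned on strict ties or zero informative sites).
    """
    col_of = {int(s): i for i, s in enumerate(block.snv_ids)}
    obs = lr_alleles[lr_alleles["snv_id"].isin(col_of)].copy()
    if len(obs) == 0:
        return pd.DataFrame(columns=["read_id", "n_h1", "n_h2", "hap"])
    ci = np.array([col_of[int(s)] for s in obs["snv_id"]])
    phased = block.h1[ci] >= 0
    obs = obs[phased]
    ci = ci[phased]
    a = obs["allele"].to_numpy()
    agree1 = (a == block.h1[ci]).astype(int)
    agree2 = (a == block.h2[ci]).astype(int)
    g = pd.DataFrame({"read_id": obs["read_id"].to_numpy(),
                      "n_h1": agree1, "n_h2": agree2}).groupby("read_id").sum().reset_index()
    g["hap"] = np.where(g["n_h1"] > g["n_h2"], 1, np.where(g["n_h2"] > g["n_h1"], 2, 0))
    return g


def extend_with_long_reads(block: HaplotypeBlock, lr_alleles: pd.DataFrame,
                           min_support: int = 2, margin: float = 0.8) -> HaplotypeBlock:
    """Densify the strand-phased backbone with long-read alleles.

    Reads are assigned to haplotypes by majority agreement with the backbone
    (strict ties unassigned).  A backbone-unphased SNV becomes phased when at
    least ``min_support`` assigned reads cover it, the majority-allele
    fraction reaches ``margin`` within each non-empty haplotype read set, and
    the two sets (when both present) vote for different alleles.  Phased
    backbone sites are never changed, so the phased fraction cannot decrease.
    """
    out = block.copy()
    tags = assign_reads_to_haplotypes(block, lr_alleles)
    tagged = tags[tags["hap"] > 0][["read_id", "hap"]]
    if len(tagged) == 0:
        return out
    col_of = {int(s): i for i, s in enumerate(block.snv_ids)}
    obs = lr_alleles.merge(tagged, on="read_id", how="inner")
    obs = obs[obs["snv_id"].isin(col_of)]
    ci = np.array([col_of[int(s)] for s in obs["snv_id"]])
    unphased = block.h1[ci] < 0
    obs = obs[unphased]
    ci = ci[unphased]
    if len(obs) == 0:
        return out
    df = pd.DataFrame({"col": ci, "hap": obs["hap"].to_numpy(),
                       "allele": obs["allele"].to_numpy()})
    stats = df.groupby(["col", "hap"])["allele"].agg(n="count", n1="sum").reset_index()
    for col, sub in stats.groupby("col"):
        total = int(sub["n"].sum())
        if total < min_support:
            continue
        call = {}
        ok = True
        for _, r in sub.iterrows():
            frac1 = r["n1"] / r["n"]
            if max(frac1, 1 - frac1) < margin:
                ok = False
                break
            call[int(r["hap"])] = 1 if frac1 >= 0.5 else 0
        if not ok:
            continue
        if 1 in call and 2 in call:
            if call[1] == call[2]:
                continue
            a1 = call[1]
        elif 1 in call:
            a1 = call[1]
        else:
            a1 = 1 - call[2]
        out.h1[col] = a1
        out.h2[col] = 1 - a1
        out.support[col] += total
    return out


# ---------------------------------------------------------------------------
# VCF serialization
# ---------------------------------------------------------------------------


def write_phased_vcf(blocks, snv_table: pd.DataFrame, path: str,
                     sample: str = "sample") -> None:
    """Write phased haplotypes as a VCF with GT (| phased, / unphased) + PS.

    ``snv_table`` is indexed by snv_id with columns chrom, pos, ref, alt.
    ``blocks`` is a single HaplotypeBlock or an iterable of them.
    """
    import pysam

    if isinstance(blocks, HaplotypeBlock):
        blocks = [blocks]
    header = pysam.VariantHeader()
    chroms = list(dict.fromkeys(snv_table["chrom"]))
    for c in chroms:
        maxpos = int(snv_table.loc[snv_table["chrom"] == c, "pos"].max()) + 2
        header.contigs.add(c, length=maxpos)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set")
    header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for block in blocks:
            order = np.argsort([int(snv_table.loc[int(s), "pos"]) for s in block.snv_ids],
                               kind="stable")
            for i in order:
                sid = int(block.snv_ids[i])
                row = snv_table.loc[sid]
                rec = vf.new_record(
                    contig=str(row["chrom"]), start=int(row["pos"]),
                    stop=int(row["pos"]) + 1,
                    alleles=(str(row["ref"]), str(row["alt"])), id=str(sid),
                )
                if block.h1[i] >= 0:
                    rec.samples[sample]["GT"] = (int(block.h1[i]), int(block.h2[i]))
                    rec.samples[sample].phased = True
                    rec.samples[sample]["PS"] = int(block.block_id)
                else:
                    rec.samples[sample]["GT"] = (0, 1)
                    rec.samples[sample].phased = False
                vf.write(rec)


def read_phased_vcf(path: str) -> pd.DataFrame:
    """Read a phased VCF back into (snv_id, chrom, pos, h1, h2, phased, ps)."""
    import pysam

    rows = []
    with pysam.VariantFile(path) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            call = rec.samples[sample]
            gt = call["GT"]
            rows.append({
                "snv_id": int(rec.id) if rec.id is not None else -1,
                "chrom": rec.contig, "pos": rec.start,
                "h1": gt[0], "h2": gt[1],
                "phased": bool(call.phased),
                "ps": call.get("PS") if call.phased else None,
            })
    return pd.DataFrame(rows)
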