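"""Binned Watson/Crick counts, strand-state genotyping, SCE breakpoints and
Watson-Crick (haplotype-informative) region export.

Coordinates are 0-based half-open throughout (BED compatible).  A "Watson"
read maps to the minus strand, a "Crick" read to the plus strand; the strand
state of a (region, cell) pair is called from the Watson fraction
f = W / (W + C):

* ``WW``  if f >= 1 - 2*background
* ``CC``  if f <= 2*background
* ``WC``  if |f - 0.5| <= 0.15
* ``unknown`` otherwise, or when fewer than ``min_reads`` reads are present.

The hard-call bands concretize the symmetric background-noise tolerance
(default background = 0.1) used for Strand-seq genotyping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

# state codes
WW, WC, CC, UNKNOWN = 0, 1, 2, 3
STATE_NAMES = np.array(["WW", "WC", "CC", "unknown"])


@dataclass
class BinGrid:
    """Non-overlapping, ordered, half-open bins over contigs.

    ``bins`` columns: ``contig``, ``start``, ``end``; index is the bin id.
    """

    bins: pd.DataFrame

    @classmethod
    def fixed(cls, contig_lengths: dict[str, int], bin_size: int = 200_000,
              step_size: int | None = None) -> "BinGrid":
        """Fixed-size bins (default 200 kbp).

        A terminal runt bin shorter than a quarter of ``bin_size`` is merged
        into its predecessor: a few-hundred-bp bin holds too few reads to
        genotype and would only add noise.
        """
        step = step_size or bin_size
        rows = []
        for contig, length in contig_lengths.items():
            starts = np.arange(0, max(length, 1), step)
            if (step == bin_size and len(starts) > 1
                    and length - starts[-1] < bin_size // 4):
                starts = starts[:-1]
            for s in starts:
                end = int(min(s + bin_size, length))
                if s == starts[-1] and step == bin_size:
                    end = int(length)
                rows.append({"contig": contig, "start": int(s), "end": end})
        return cls(bins=pd.DataFrame(rows))

    @classmethod
    def dynamic(cls, contig_lengths: dict[str, int], reads: pd.DataFrame,
                positions_per_bin: int = 200_000) -> "BinGrid":
        """Bins holding a fixed number of mappable positions.

        Mappable positions are approximated as distinct read start positions
        observed across all cells.
        """
        rows = []
        for contig, length in contig_lengths.items():
            pos = np.unique(reads.loc[reads["contig"] == contig, "pos"].to_numpy())
            if pos.size == 0:
                rows.append({"contig": contig, "start": 0, "end": int(length)})
                continue
            edges = [0]
            for k in range(positions_per_bin, pos.size, positions_per_bin):
                edges.append(int(pos[k]))
            edges.append(int(length))
            for a, b in zip(edges[:-1], edges[1:]):
                if b > a:
                    rows.append({"contig": contig, "start": a, "end": b})
        return cls(bins=pd.DataFrame(rows))

    @property
    def contigs(self) -> list[str]:
        return list(dict.fromkeys(self.bins["contig"]))

    def bin_lengths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()


@dataclass
class CountMatrix:
    """Watson/Crick read counts per (bin, cell)."""

    W: np.ndarray
    C: np.ndarray
    grid: BinGrid
    cells: list[str]
    n_skipped: int = 0

    @property
    def n(self) -> np.ndarray:
        return self.W + self.C

    def contig_totals(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Aggregate bin counts to contig x cell totals."""
        contigs = self.grid.contigs
        idx = {c: i for i, c in enumerate(contigs)}
        rows = np.array([idx[c] for c in self.grid.bins["contig"]])
        W = np.zeros((len(contigs), len(self.cells)))
        C = np.zeros_like(W)
        np.add.at(W, rows, self.W)
        np.add.at(C, rows, self.C)
        return W, C, contigs


def count_reads(reads: pd.DataFrame, grid: BinGrid, min_mapq: int = 10,
                cells: list[str] | None = None) -> CountMatrix:
    """Bin directional reads into a Watson/Crick count matrix.

    Duplicate-flagged reads and reads with mapping quality below
    ``min_mapq`` are excluded; reads on contigs absent from the grid are
    skipped with a warning and counted in ``n_skipped``.
    """
    if cells is None:
        cells = sorted(reads["cell"].unique())
    cell_idx = {c: j for j, c in enumerate(cells)}
    keep = (reads["mapq"] >= min_mapq) & (~reads["dup"].astype(bool))
    sub = reads[keep]
    known = sub["contig"].isin(set(grid.contigs))
    n_skipped = int((~known).sum())
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} reads on contigs absent from the bin grid")
    sub = sub[known]

    nbins = len(grid.bins)
    W = np.zeros((nbins, len(cells)), dtype=np.int64)
    C = np.zeros_like(W)
    gb = grid.bins
    for contig, rsub in sub.groupby("contig", sort=False):
        bsub = gb[gb["contig"] == contig]
        starts = bsub["start"].to_numpy()
        ends = bsub["end"].to_numpy()
        bids = bsub.index.to_numpy()
        pos = rsub["pos"].to_numpy()
        which = np.searchsorted(starts, pos, side="right") - 1
        inside = (which >= 0) & (pos < ends[np.clip(which, 0, len(ends) - 1)])
        which = which[inside]
        cj = np.array([cell_idx[c] for c in rsub["cell"].to_numpy()[inside]])
        wmask = rsub["strand"].to_numpy()[inside] == "-"
        np.add.at(W, (bids[which[wmask]], cj[wmask]), 1)
        np.add.at(C, (bids[which[~wmask]], cj[~wmask]), 1)
    return CountMatrix(W=W, C=C, grid=grid, cells=list(cells), n_skipped=n_skipped)


def call_strand_state(W, C, background: float = 0.1, min_reads: int = 50):
    """Hard strand-state call(s) from Watson/Crick counts (vectorized).

    Returns an integer state array (codes WW/WC/CC/UNKNOWN) of the broadcast
    shape of ``W`` and ``C``; scalars in, scalar out.
    """
    W = np.asarray(W, dtype=float)
    C = np.asarray(C, dtype=float)
    n = W + C
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, W / np.maximum(n, 1), np.nan)
    state = np.full(np.broadcast(W, C).shape, UNKNOWN, dtype=np.int8)
    ok = n >= min_reads
    state[ok & (f >= 1 - 2 * background)] = WW
    state[ok & (f <= 2 * background)] = CC
    band = ok & (np.abs(f - 0.5) <= 0.15)
    state[band & (state == UNKNOWN)] = WC
    if state.ndim == 0:
        return int(state)
    return state


def watson_fraction(W, C) -> np.ndarray:
    n = np.asarray(W, float) + np.asarray(C, float)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, np.asarray(W, float) / np.maximum(n, 1), np.nan)


def window_states(reads: pd.DataFrame, contig_lengths: dict[str, int],
                  windowsize: int = 500_000, min_reads: int = 50,
                  background: float = 0.1, min_mapq: int = 10) -> pd.DataFrame:
    """Per (cell, contig) fixed-size window strand states.

    Returns a tidy frame with columns ``cell``, ``contig``, ``start``,
    ``end``, ``W``, ``C``, ``state`` (string).
    """
    keep = (reads["mapq"] >= min_mapq) & (~reads["dup"].astype(bool))
    sub = reads[keep]
    rows = []
    for (cell, contig), g in sub.groupby(["cell", "contig"], sort=True):
        length = contig_lengths[contig]
        edges = np.arange(0, length + windowsize, windowsize)
        edges[-1] = max(edges[-1], length)
        pos = g["pos"].to_numpy()
        wmask = g["strand"].to_numpy() == "-"
        wcount, _ = np.histogram(pos[wmask], bins=edges)
        ccount, _ = np.histogram(pos[~wmask], bins=edges)
        states = call_strand_state(wcount, ccount, background, min_reads)
        for i in range(len(edges) - 1):
            rows.append({"cell": cell, "contig": contig, "start": int(edges[i]),
                         "end": int(min(edges[i + 1], length)),
                         "W": int(wcount[i]), "C": int(ccount[i]),
                         "state": STATE_NAMES[states[i]]})
    return pd.DataFrame(rows, columns=["cell", "contig", "start", "end", "W", "C", "state"])


_EXPECTED_WF = {  # expected Watson fraction per state under symmetric background
    "WW": lambda b: 1 - b / 2,
    "CC": lambda b: b / 2,
    "WC": lambda b: 0.5,
}


def detect_sce_breakpoints(reads: pd.DataFrame, contig_lengths: dict[str, int],
                           windowsize: int = 500_000, min_reads: int = 50,
                           background: float = 0.1, min_mapq: int = 10) -> pd.DataFrame:
    """Detect strand-state switches (SCEs / misassembly signal) per cell.

    Hard states are called in fixed-size windows; a breakpoint is emitted
    between consecutive called windows whose states differ.  The position is
    refined inside the two flanking windows by maximizing the binomial
    split likelihood of the left/right states over all read-gap split points.
    Windows with fewer than ``min_reads`` reads are never called.
    """
    out = []
    ws = window_states(reads, contig_lengths, windowsize, min_reads, background, min_mapq)
    keep = (reads["mapq"] >= min_mapq) & (~reads["dup"].astype(bool))
    sub = reads[keep]
    groups = dict(tuple(sub.groupby(["cell", "contig"], sort=False)))
    for (cell, contig), g in ws.groupby(["cell", "contig"], sort=True):
        called = g[g["state"] != "unknown"].reset_index(drop=True)
        if len(called) < 2:
            continue
        rsub = groups.get((cell, contig))
        if rsub is None:
            continue
        rpos = rsub["pos"].to_numpy()
        rw = (rsub["strand"].to_numpy() == "-").astype(float)
        order = np.argsort(rpos, kind="stable")
        rpos, rw = rpos[order], rw[order]
        for i in range(len(called) - 1):
            a, b = called.iloc[i], called.iloc[i + 1]
            if a["state"] == b["state"]:
                continue
            lo, hi = int(a["start"]), int(b["end"])
            pos = _refine_breakpoint(rpos, rw, lo, hi, a["state"], b["state"], background)
            out.append({"cell": cell, "contig": contig, "pos": pos,
                        "left_state": a["state"], "right_state": b["state"]})
    return pd.DataFrame(out, columns=["cell", "contig", "pos", "left_state", "right_state"])


def _refine_breakpoint(rpos, rw, lo, hi, left_state, right_state, background) -> int:
    """Best split position in [lo, hi) under a two-segment binomial model."""
    sel = (rpos >= lo) & (rpos < hi)
    p = rpos[sel]
    w = rw[sel]
    if p.size == 0:
        return (lo + hi) // 2
    pl = np.clip(_EXPECTED_WF[left_state](background), 1e-6, 1 - 1e-6)
    pr = np.clip(_EXPECTED_WF[right_state](background), 1e-6, 1 - 1e-6)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cn = np.arange(p.size + 1, dtype=float)
    ll = (cw * np.log(pl) + (cn - cw) * np.log(1 - pl)
          + (cw[-1] - cw) * np.log(pr) + ((cn[-1] - cn) - (cw[-1] - cw)) * np.log(1 - pr))
    k = int(np.argmax(ll))  # first maximizer -> lowest position on ties
    if k == 0:
        return int(max(lo, p[0]))
    if k == p.size:
        return int(min(hi, p[-1] + 1))
    return int((p[k - 1] + p[k]) // 2 + 1)


@dataclass
class WCRegionSet:
    """Per-cell haplotype-informative (WC) intervals on one coordinate system."""

    regions: pd.DataFrame  # cell, contig, start, end

    def for_cell(self, cell: str) -> pd.DataFrame:
        return self.regions[self.regions["cell"] == cell]


def export_wc_regions(states: pd.DataFrame, min_region: int = 5_000_000,
                      collapse: int = 5_000_000) -> WCRegionSet:
    """Merge WC-called windows into haplotype-informative regions.

    Maximal runs of WC windows are merged; runs separated by less than
    ``collapse`` bp of *uncalled* windows are joined (low-coverage gaps are
    treated as noise), while an intervening window with a definite WW or CC
    call breaks the region — a confident opposite state is a real strand
    switch, and joining across it would mix homologs.  Merged regions
    shorter than ``min_region`` are dropped.
    """
    rows = []
    for (cell, contig), g in states.groupby(["cell", "contig"], sort=True):
        g = g.sort_values("start")
        cur_s, cur_e = None, None
        merged = []
        for _, r in g.iterrows():
            st = r["state"]
            if st == "WC":
                if cur_s is None:
                    cur_s, cur_e = int(r["start"]), int(r["end"])
                elif int(r["start"]) - cur_e < collapse:
                    cur_e = max(cur_e, int(r["end"]))
                else:
                    merged.append((cur_s, cur_e))
                    cur_s, cur_e = int(r["start"]), int(r["end"])
            elif st in ("WW", "CC") and cur_s is not None:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = None, None
        if cur_s is not None:
            merged.append((cur_s, cur_e))
        for s, e in merged:
            if e - s >= min_region:
                rows.append({"cell": cell, "contig": contig, "start": s, "end": e})
    return WCRegionSet(regions=pd.DataFrame(rows, columns=["cell", "contig", "start", "end"]))
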