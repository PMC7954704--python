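"""Synthetic diploid genomes, contig tilings and single-cell strand-sequencing libraries.

The simulator emulates the inputs of a Strand-seq-driven assembly workflow:

* a diploid genome with biallelic heterozygous SNVs (two haplotypes H1/H2),
* a "squashed" contig tiling of that genome with optional injected assembly
  errors (chimeric joins between chromosomes, internally misoriented
  intervals),
* per-cell Strand-seq read placements.  Each cell inherits one template
  strand (Watson or Crick) per homolog per chromosome, uniformly at random;
  sister chromatid exchanges (SCEs) flip the template strand downstream of a
  uniformly placed position; a configurable fraction of background reads get
  a random direction,
* long reads represented as allele observations at heterozygous SNV sites.

Every stochastic choice is recorded in truth tables so that downstream
clustering, phasing and tagging can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

WATSON = "-"  # Watson template = minus-strand reads
CRICK = "+"  # Crick template = plus-strand reads

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic diploid genome.

    chrom_lengths
        Length in bp of each chromosome.
    snv_density
        Per-bp probability of a heterozygous SNV, in (0, 0.01].  A density of
        0 is allowed and yields identical haplotypes.
    seed
        Seed; the same seed always yields byte-identical output.
    """

    chrom_lengths: tuple[int, ...]
    snv_density: float = 1.0e-3
    seed: int = 0

    def __post_init__(self):
        if len(self.chrom_lengths) == 0:
            raise ValueError("at least one chromosome required")
        if any(int(l) <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")
        if not (0 <= self.snv_density <= 0.01):
            raise ValueError("snv_density must lie in [0, 0.01]")


@dataclass
class Genome:
    """A simulated diploid genome.

    ``snvs`` has one row per heterozygous SNV (index = global SNV id) with
    columns ``chrom``, ``pos`` (0-based), ``ref``, ``alt``, ``h1``, ``h2``
    where ``h1``/``h2`` are 0 (ref) / 1 (alt) and differ at every site.
    Chromosome base sequences are generated lazily and deterministically.
    """

    spec: GenomeSpec
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    snvs: pd.DataFrame

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def _ref_array(self, chrom: str) -> np.ndarray:
        ci = self.chrom_names.index(chrom)
        rng = np.random.default_rng([self.spec.seed, 7919, ci])
        return rng.integers(0, 4, size=self.chrom_lengths[chrom], dtype=np.uint8)

    def reference_sequence(self, chrom: str) -> str:
        return _BASES[self._ref_array(chrom)].tobytes().decode()

    def haplotype_sequence(self, chrom: str, hap: int) -> str:
        """Base sequence of haplotype ``hap`` (1 or 2) for one chromosome."""
        if hap not in (1, 2):
            raise ValueError("hap must be 1 or 2")
        arr = self._ref_array(chrom)
        sub = self.snvs[self.snvs["chrom"] == chrom]
        alt_mask = (sub["h1"] if hap == 1 else sub["h2"]).to_numpy() == 1
        pos = sub["pos"].to_numpy()[alt_mask]
        alt = sub["alt_code"].to_numpy()[alt_mask]
        arr = arr.copy()
        arr[pos] = alt
        return _BASES[arr].tobytes().decode()

    def snv_positions(self, chrom: str) -> np.ndarray:
        return self.snvs.loc[self.snvs["chrom"] == chrom, "pos"].to_numpy()


def simulate_genome(spec: GenomeSpec) -> Genome:
    """Draw SNV positions (Bernoulli per bp) and het genotypes for a genome."""
    chrom_names = [f"chr{i + 1}" for i in range(len(spec.chrom_lengths))]
    rows = []
    for ci, (name, length) in enumerate(zip(chrom_names, spec.chrom_lengths)):
        rng = np.random.default_rng([spec.seed, 104729, ci])
        if spec.snv_density > 0:
            pos = np.flatnonzero(rng.random(int(length)) < spec.snv_density)
        else:
            pos = np.empty(0, dtype=np.int64)
        ref_rng = np.random.default_rng([spec.seed, 7919, ci])
        ref = ref_rng.integers(0, 4, size=int(length), dtype=np.uint8)[pos]
        alt = (ref + rng.integers(1, 4, size=pos.size, dtype=np.uint8)) % 4
        h1 = rng.integers(0, 2, size=pos.size, dtype=np.int8)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": pos,
                    "ref_code": ref,
                    "alt_code": alt,
                    "h1": h1,
                    "h2": (1 - h1).astype(np.int8),
                }
            )
        )
    snvs = pd.concat(rows, ignore_index=True)
    snvs["ref"] = [chr(b) for b in _BASES[snvs["ref_code"].to_numpy()]]
    snvs["alt"] = [chr(b) for b in _BASES[snvs["alt_code"].to_numpy()]]
    return Genome(
        spec=spec,
        chrom_names=chrom_names,
        chrom_lengths=dict(zip(chrom_names, map(int, spec.chrom_lengths))),
        snvs=snvs,
    )


# ---------------------------------------------------------------------------
# contigs
# ---------------------------------------------------------------------------


@dataclass
class ContigSet:
    """A contig tiling of the genome plus ground truth.

    ``segments`` has one row per (contig, segment) in contig order with
    columns ``contig``, ``seg``, ``chrom``, ``start``, ``end``, ``strand``.
    A clean contig has one segment; an injected chimera joins segments from
    two chromosomes; an injected misorientation yields three segments of the
    same chromosome with the middle one on the opposite strand.  ``errors``
    records every injected error (type, contig, join point / interval).
    """

    segments: pd.DataFrame
    errors: pd.DataFrame

    def __post_init__(self):
        self._rebuild_index()

    def _rebuild_index(self):
        seg = self.segments
        lens = (seg["end"] - seg["start"]).to_numpy()
        offs = []
        for contig, sub in seg.groupby("contig", sort=False):
            l = (sub["end"] - sub["start"]).to_numpy()
            offs.append(np.concatenate([[0], np.cumsum(l)[:-1]]))
        seg = seg.copy()
        seg["c_start"] = np.concatenate(offs) if offs else np.empty(0, int)
        seg["c_end"] = seg["c_start"] + lens
        self.segments = seg

    @property
    def contig_names(self) -> list[str]:
        return list(dict.fromkeys(self.segments["contig"]))

    @property
    def contig_lengths(self) -> dict[str, int]:
        g = self.segments.groupby("contig", sort=False)
        return {c: int((s["end"] - s["start"]).sum()) for c, s in g}

    def true_chromosome(self, contig: str) -> str:
        """Majority (by length) chromosome of origin of a contig."""
        sub = self.segments[self.segments["contig"] == contig]
        by = sub.groupby("chrom").apply(
            lambda s: int((s["end"] - s["start"]).sum()), include_groups=False
        )
        return str(by.idxmax())

    def true_orientation(self, contig: str) -> str:
        """Majority (by length) strand of a contig's segments."""
        sub = self.segments[self.segments["contig"] == contig]
        plus = int(sub.loc[sub["strand"] == "+", "end"].sub(
            sub.loc[sub["strand"] == "+", "start"]).sum())
        minus = int((sub["end"] - sub["start"]).sum()) - plus
        return "+" if plus >= minus else "-"

    def true_order(self) -> pd.DataFrame:
        """Per-chromosome contig order by genomic start of the first segment."""
        first = self.segments.groupby("contig", sort=False).first().reset_index()
        first["true_chrom"] = [self.true_chromosome(c) for c in first["contig"]]
        first = first.sort_values(["true_chrom", "start"], kind="stable")
        first["order_index"] = first.groupby("true_chrom").cumcount()
        return first[["contig", "true_chrom", "start", "order_index"]]

    def contig_sequence(self, genome: Genome, contig: str, hap: int | None = None) -> str:
        """Contig base sequence (reference, or haplotype ``hap``)."""
        parts = []
        for _, s in self.segments[self.segments["contig"] == contig].iterrows():
            seq = (
                genome.reference_sequence(s["chrom"])
                if hap is None
                else genome.haplotype_sequence(s["chrom"], hap)
            )[int(s["start"]): int(s["end"])]
            if s["strand"] == "-":
                seq = revcomp(seq)
            parts.append(seq)
        return "".join(parts)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def fragment_contigs(
    genome: Genome,
    target_n50: int,
    n_chimeras: int = 0,
    n_misorientations: int = 0,
    seed: int = 0,
    min_contig: int = 100_000,
    error_margin: int = 300_000,
    min_error_size: int = 600_000,
) -> ContigSet:
    """Tile each chromosome with contigs and inject assembly errors.

    Contig piece lengths are drawn ~ Uniform(0.6, 1.4) * ``target_n50`` so the
    realized N50 lands near the target.  Each clean contig gets a uniform
    random orientation.  Chimeras concatenate two contigs from different
    chromosomes; misorientations reverse-complement an internal interval of
    at least ``min_error_size`` bp with at least ``error_margin`` bp flanking
    margin (intervals much shorter than the downstream bin size would be
    invisible by construction).  Everything is recorded in the truth tables.
    """
    if target_n50 > max(genome.chrom_lengths.values()):
        raise ValueError("target_n50 exceeds the longest chromosome")
    rng = np.random.default_rng([seed, 15485863])
    pieces = []  # (chrom, start, end)
    for chrom in genome.chrom_names:
        length = genome.chrom_lengths[chrom]
        cuts = [0]
        while cuts[-1] < length:
            cuts.append(cuts[-1] + int(target_n50 * rng.uniform(0.6, 1.4)))
        cuts[-1] = length
        if len(cuts) > 2 and cuts[-1] - cuts[-2] < min_contig:
            del cuts[-2]
        pieces.extend((chrom, cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1))
    n = len(pieces)
    if n_chimeras * 2 + n_misorientations > n:
        raise ValueError("more injected errors than contigs")
    order = rng.permutation(n)  # shuffle so contig names do not encode order
    names = [f"ctg{i:04d}" for i in range(n)]
    strands = rng.choice(["+", "-"], size=n)

    seg_rows = []
    for i, pi in enumerate(order):
        chrom, start, end = pieces[pi]
        seg_rows.append(
            {"contig": names[i], "seg": 0, "chrom": chrom, "start": start,
             "end": end, "strand": strands[i]}
        )
    segments = pd.DataFrame(seg_rows)
    errors: list[dict] = []

    # misorientations first: need long single-segment contigs.  The flipped
    # interval is kept under half the contig (a flipped majority would make
    # the minority frame look canonical) and above ``min_error_size``.
    lengths = (segments["end"] - segments["start"]).to_numpy()
    need = max(2 * error_margin + min_error_size,
               int(np.ceil(min_error_size / 0.45)))
    eligible = np.flatnonzero(lengths >= need)
    if len(eligible) < n_misorientations:
        raise ValueError("not enough long contigs for requested misorientations")
    mis_idx = rng.choice(eligible, size=n_misorientations, replace=False)
    new_rows = []
    mis_contigs: set = set()
    for idx in sorted(mis_idx):
        row = segments.iloc[idx]
        mis_contigs.add(row["contig"])
        L = int(row["end"] - row["start"])
        size = int(rng.integers(min_error_size, int(0.45 * L) + 1))
        a = int(rng.integers(error_margin, L - error_margin - size + 1))
        b = a + size
        parts = _flip_interval_single(row, a, b)
        new_rows.append((idx, parts))
        errors.append(
            {"type": "misorientation", "contig": row["contig"],
             "start": a, "end": b}
        )
    # rebuild with flipped intervals
    if new_rows:
        frames = []
        replaced = {idx: parts for idx, parts in new_rows}
        for idx in range(len(segments)):
            if idx in replaced:
                frames.append(pd.DataFrame(replaced[idx]))
            else:
                frames.append(segments.iloc[[idx]])
        segments = pd.concat(frames, ignore_index=True)

    # chimeras: join the tail contig of one chromosome to the head of another
    clean = [c for c in segments["contig"].unique() if c not in mis_contigs]
    chroms_of = {c: segments.loc[segments["contig"] == c, "chrom"].iloc[0] for c in clean}
    pairs = []
    pool = list(clean)
    for _ in range(n_chimeras):
        a = pool[int(rng.integers(len(pool)))]
        others = [c for c in pool if chroms_of[c] != chroms_of[a] and c != a]
        if not others:
            raise ValueError("cannot place chimera: need two chromosomes")
        b = others[int(rng.integers(len(others)))]
        pool.remove(a)
        pool.remove(b)
        pairs.append((a, b))
    for a, b in pairs:
        sa = segments[segments["contig"] == a]
        sb = segments[segments["contig"] == b]
        join = int((sa["end"] - sa["start"]).sum())
        sb = sb.copy()
        sb["contig"] = a
        sb["seg"] = np.arange(len(sa), len(sa) + len(sb))
        segments = pd.concat(
            [segments[~segments["contig"].isin([a, b])], sa, sb], ignore_index=True
        )
        errors.append({"type": "chimera", "contig": a, "start": join, "end": join})

    # stable order: by contig name then segment index
    segments = segments.sort_values(["contig", "seg"], kind="stable").reset_index(drop=True)
    err_df = pd.DataFrame(errors, columns=["type", "contig", "start", "end"])
    return ContigSet(segments=segments, errors=err_df)


def _flip_interval_single(row: pd.Series, a: int, b: int) -> list[dict]:
    """Reverse-complement contig interval [a, b) of a one-segment contig."""
    chrom, s, e, strand, contig = row["chrom"], int(row["start"]), int(row["end"]), row["strand"], row["contig"]

    def to_genome(lo, hi):
        if strand == "+":
            return s + lo, s + hi
        return e - hi, e - lo

    out = []
    for k, (lo, hi, flip) in enumerate(
        [(0, a, False), (a, b, True), (b, e - s, False)]
    ):
        g0, g1 = to_genome(lo, hi)
        st = strand
        if flip:
            st = "-" if strand == "+" else "+"
        out.append(
            {"contig": contig, "seg": k, "chrom": chrom, "start": g0, "end": g1,
             "strand": st}
        )
    return out


# ---------------------------------------------------------------------------
# Strand-seq libraries
# ---------------------------------------------------------------------------


@dataclass
class StrandSeqData:
    """Simulated Strand-seq libraries plus truth.

    ``reads`` columns: ``read_id``, ``cell``, ``contig``, ``pos`` (0-based,
    contig coordinates), ``strand`` (``+`` Crick / ``-`` Watson), ``mapq``,
    ``dup``.  ``alleles``: one row per (read, covered het SNV) with the
    observed allele and base quality.  Truth: ``templates[cell, chrom, hom]``
    (0 = Watson, 1 = Crick), ``sces`` (cell, chrom, hom, pos) and per-read
    ``hap`` / ``background`` columns in ``truth``.
    """

    reads: pd.DataFrame
    alleles: pd.DataFrame
    truth: pd.DataFrame
    templates: np.ndarray
    sces: pd.DataFrame
    cells: list[str]
    chrom_names: list[str]

    def subset(self, cells: Sequence[str]) -> "StrandSeqData":
        keep = set(cells)
        mask = self.reads["cell"].isin(keep).to_numpy()
        rid = self.reads.loc[mask, "read_id"]
        idx = [self.cells.index(c) for c in cells]
        return StrandSeqData(
            reads=self.reads[mask].reset_index(drop=True),
            alleles=self.alleles[self.alleles["read_id"].isin(set(rid))].reset_index(drop=True),
            truth=self.truth[mask].reset_index(drop=True),
            templates=self.templates[idx],
            sces=self.sces[self.sces["cell"].isin(keep)].reset_index(drop=True),
            cells=list(cells),
            chrom_names=self.chrom_names,
        )


def simulate_strandseq(
    genome: Genome,
    contigs: ContigSet,
    n_cells: int,
    reads_per_cell: int,
    sce_rate: float = 0.2,
    background: float = 0.05,
    read_length: int = 100,
    allele_error: float = 0.0,
    baseq: int = 30,
    mapq: int = 60,
    seed: int = 0,
    templates: np.ndarray | None = None,
    sces: pd.DataFrame | None = None,
) -> StrandSeqData:
    """Simulate per-cell directional Strand-seq read placements.

    Each cell inherits, per chromosome and homolog, a template strand drawn
    uniformly from {W, C} (so strand states over cells follow WW:WC:CC =
    1:2:1).  The direction of a read equals the template strand of the
    homolog it came from, flipped downstream of any SCE on that homolog and
    flipped again on minus-strand contig segments.  A ``background`` fraction
    of reads get a uniformly random direction.  Reads covering het SNVs
    report the haplotype allele, flipped with probability ``allele_error``.

    Passing ``templates``/``sces`` replays the same cell inheritance on a
    (possibly corrected) contig set.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0 <= background < 0.5):
        raise ValueError("background must lie in [0, 0.5)")
    rng = np.random.default_rng([seed, 32452843])
    cells = [f"cell{j:03d}" for j in range(n_cells)]
    chroms = genome.chrom_names
    n_chrom = len(chroms)

    if templates is None:
        templates = rng.integers(0, 2, size=(n_cells, n_chrom, 2), dtype=np.int8)
    else:
        templates = np.asarray(templates, dtype=np.int8)
        if templates.shape != (n_cells, n_chrom, 2):
            raise ValueError("templates shape mismatch")
    if sces is None:
        sce_rows = []
        # sce_rate is per cell per chromosome; events split over the two homologs
        counts = rng.poisson(sce_rate / 2.0, size=(n_cells, n_chrom, 2))
        for j in range(n_cells):
            for ci in range(n_chrom):
                for h in range(2):
                    for _ in range(int(counts[j, ci, h])):
                        sce_rows.append(
                            {"cell": cells[j], "chrom": chroms[ci], "hom": h,
                             "pos": int(rng.integers(genome.chrom_lengths[chroms[ci]]))}
                        )
        sces = pd.DataFrame(sce_rows, columns=["cell", "chrom", "hom", "pos"])
    else:
        sces = sces.copy()

    seg = contigs.segments
    seg_contig = seg["contig"].to_numpy()
    contig_names = contigs.contig_names
    contig_index = {c: i for i, c in enumerate(contig_names)}
    clens = contigs.contig_lengths
    clen_arr = np.array([clens[c] for c in contig_names], dtype=np.int64)

    n_reads = n_cells * reads_per_cell
    p_contig = clen_arr / clen_arr.sum()
    r_contig = rng.choice(len(contig_names), size=n_reads, p=p_contig)
    span = np.maximum(clen_arr[r_contig] - read_length, 1)
    r_pos = (rng.random(n_reads) * span).astype(np.int64)
    r_cell = np.repeat(np.arange(n_cells), reads_per_cell)
    r_hom = rng.integers(0, 2, size=n_reads, dtype=np.int8)

    # map contig position -> (chrom, genome start of covered window, seg strand)
    g_pos = np.empty(n_reads, dtype=np.int64)
    g_chrom = np.empty(n_reads, dtype=np.int32)
    g_flip = np.zeros(n_reads, dtype=bool)
    chrom_idx = {c: i for i, c in enumerate(chroms)}
    for c, sub in seg.groupby("contig", sort=False):
        ci = contig_index[c]
        mask = r_contig == ci
        if not mask.any():
            continue
        cs = sub["c_start"].to_numpy()
        which = np.searchsorted(cs, r_pos[mask], side="right") - 1
        srow_start = sub["start"].to_numpy()[which]
        srow_end = sub["end"].to_numpy()[which]
        srow_cs = cs[which]
        srow_minus = (sub["strand"].to_numpy()[which] == "-")
        off = r_pos[mask] - srow_cs
        gp = np.where(srow_minus, srow_end - off - read_length, srow_start + off)
        # clamp windows that run past a segment edge; fine at read_length scale
        gp = np.maximum(gp, 0)
        g_pos[mask] = gp
        g_chrom[mask] = np.array([chrom_idx[x] for x in sub["chrom"].to_numpy()])[which]
        g_flip[mask] = srow_minus

    # template strand of the originating homolog at the read position
    t = templates[r_cell, g_chrom, r_hom].astype(np.int8)  # 0=W,1=C
    if len(sces):
        key = (r_cell.astype(np.int64) * n_chrom + g_chrom) * 2 + r_hom
        order_k = np.argsort(key, kind="stable")
        sorted_key = key[order_k]
        cell_lookup = {c: j for j, c in enumerate(cells)}
        for _, ev in sces.iterrows():
            if ev["cell"] not in cell_lookup or ev["chrom"] not in chrom_idx:
                continue
            ek = (cell_lookup[ev["cell"]] * n_chrom + chrom_idx[ev["chrom"]]) * 2 + int(ev["hom"])
            lo = np.searchsorted(sorted_key, ek, side="left")
            hi = np.searchsorted(sorted_key, ek, side="right")
            sel = order_k[lo:hi]
            hit = sel[g_pos[sel] >= int(ev["pos"])]
            t[hit] ^= 1

    is_bg = rng.random(n_reads) < background
    t_obs = t.copy()
    t_obs[is_bg] = rng.integers(0, 2, size=int(is_bg.sum()), dtype=np.int8)
    # flip on minus-oriented contig segments
    t_obs = np.where(g_flip, 1 - t_obs, t_obs)
    strand = np.where(t_obs == 1, CRICK, WATSON)

    reads = pd.DataFrame(
        {
            "read_id": np.arange(n_reads),
            "cell": np.array(cells, dtype=object)[r_cell],
            "contig": np.array(contig_names, dtype=object)[r_contig],
            "pos": r_pos,
            "strand": strand,
            "mapq": np.full(n_reads, mapq, dtype=np.int16),
            "dup": np.zeros(n_reads, dtype=bool),
        }
    )
    truth = pd.DataFrame(
        {
            "read_id": np.arange(n_reads),
            "hap": (r_hom + 1).astype(np.int8),
            "background": is_bg,
            "chrom": np.array(chroms, dtype=object)[g_chrom],
            "gpos": g_pos,
        }
    )

    # allele observations at covered het SNVs
    al_rows = []
    for ci, chrom in enumerate(chroms):
        mask = g_chrom == ci
        if not mask.any():
            continue
        spos = genome.snv_positions(chrom)
        if spos.size == 0:
            continue
        sub_ids = genome.snvs.index[genome.snvs["chrom"] == chrom].to_numpy()
        lo = np.searchsorted(spos, g_pos[mask])
        hi = np.searchsorted(spos, g_pos[mask] + read_length)
        counts = hi - lo
        if counts.sum() == 0:
            continue
        rid = reads.loc[mask, "read_id"].to_numpy()
        rep_read = np.repeat(rid, counts)
        rep_hom = np.repeat(r_hom[mask], counts)
        snv_local = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        snv_id = sub_ids[snv_local]
        hsub = genome.snvs.loc[genome.snvs["chrom"] == chrom, ["h1", "h2"]].to_numpy()
        alle = hsub[snv_local, rep_hom]
        al_rows.append(
            pd.DataFrame({"read_id": rep_read, "snv_id": snv_id, "allele": alle})
        )
    if al_rows:
        alleles = pd.concat(al_rows, ignore_index=True)
        if allele_error > 0:
            flip = rng.random(len(alleles)) < allele_error
            alleles.loc[flip, "allele"] = 1 - alleles.loc[flip, "allele"]
        alleles["allele"] = alleles["allele"].astype(np.int8)
        alleles["baseq"] = np.int16(baseq)
    else:
        alleles = pd.DataFrame(columns=["read_id", "snv_id", "allele", "baseq"])

    return StrandSeqData(
        reads=reads, alleles=alleles, truth=truth, templates=templates,
        sces=sces, cells=cells, chrom_names=list(chroms),
    )


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------


@dataclass
class LongReadSet:
    """Long reads as allele observations at het SNV sites.

    ``reads``: read_id, chrom, hap (1/2, truth), start, end.
    ``alleles``: read_id, snv_id, allele (0/1 observed).
    """

    reads: pd.DataFrame
    alleles: pd.DataFrame


def simulate_long_reads(
    genome: Genome,
    mean_length: int = 15_000,
    coverage: float = 10.0,
    allele_error: float = 0.0,
    seed: int = 0,
) -> LongReadSet:
    """Draw long reads evenly from H1/H2; report covered SNV alleles.

    Read lengths are exponential with the given mean (floored at 50 bp);
    each covered SNV reports the true haplotype allele with probability
    1 - ``allele_error``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if mean_length < 1:
        raise ValueError("mean_length must be >= 1")
    rng = np.random.default_rng([seed, 49979687])
    total = genome.total_length
    n_reads = max(2, int(round(coverage * total / mean_length)))
    n_reads += n_reads % 2  # exactly even split over haplotypes
    lengths = np.maximum(rng.exponential(mean_length, size=n_reads), 50).astype(np.int64)
    clens = np.array([genome.chrom_lengths[c] for c in genome.chrom_names], dtype=np.int64)
    chrom = rng.choice(len(clens), size=n_reads, p=clens / clens.sum())
    start = (rng.random(n_reads) * np.maximum(clens[chrom] - lengths, 1)).astype(np.int64)
    end = np.minimum(start + lengths, clens[chrom])
    hap = rng.permutation(np.repeat(np.array([1, 2], dtype=np.int8), n_reads // 2))

    reads = pd.DataFrame(
        {
            "read_id": np.arange(n_reads),
            "chrom": np.array(genome.chrom_names, dtype=object)[chrom],
            "hap": hap,
            "start": start,
            "end": end,
        }
    )
    al_rows = []
    for ci, cname in enumerate(genome.chrom_names):
        mask = chrom == ci
        spos = genome.snv_positions(cname)
        if not mask.any() or spos.size == 0:
            continue
        sub_ids = genome.snvs.index[genome.snvs["chrom"] == cname].to_numpy()
        lo = np.searchsorted(spos, start[mask])
        hi = np.searchsorted(spos, end[mask])
        counts = hi - lo
        if counts.sum() == 0:
            continue
        rep_read = np.repeat(reads.loc[mask, "read_id"].to_numpy(), counts)
        rep_hap = np.repeat(hap[mask], counts)
        snv_local = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        hsub = genome.snvs.loc[genome.snvs["chrom"] == cname, ["h1", "h2"]].to_numpy()
        alle = hsub[snv_local, rep_hap - 1]
        al_rows.append(
            pd.DataFrame({"read_id": rep_read, "snv_id": sub_ids[snv_local], "allele": alle})
        )
    if al_rows:
        alleles = pd.concat(al_rows, ignore_index=True)
        if allele_error > 0:
            flip = rng.random(len(alleles)) < allele_error
            alleles.loc[flip, "allele"] = 1 - alleles.loc[flip, "allele"]
        alleles["allele"] = alleles["allele"].astype(np.int8)
    else:
        alleles = pd.DataFrame(columns=["read_id", "snv_id", "allele"])
    return LongReadSet(reads=reads, alleles=alleles)


def subsample_libraries(cells: Sequence[str], fraction: float, seed: int = 0) -> list[str]:
    """Uniform subset (without replacement) of floor(fraction * n) cells."""
    if len(cells) == 0:
        raise ValueError("no cells to subsample")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    k = int(np.floor(fraction * len(cells)))
    rng = np.random.default_rng([seed, 86028121])
    idx = np.sort(rng.choice(len(cells), size=k, replace=False))
    return [cells[i] for i in idx]
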