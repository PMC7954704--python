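"""Assembly and phasing evaluation statistics.

Implements the evaluation toolbox of the phased-assembly workflow: switch
error and Hamming rates against a truth phasing, Phred-scaled consensus
quality (QV) from alignment identity, contig N50, loss-of-heterozygosity
segmentation, collapsed-duplication detection from coverage, common assembly
breaks across assemblies, and segmental-duplication resolution.

Phasing metrics: only SNV sites phased in both callsets are compared.  For
each chromosome the haplotype pairing (H1<->H1 or H1<->H2) minimizing the
Hamming distance is chosen once and reused for the switch-error count.  The
switch error recodes each haplotype into a binary string over neighbouring
SNV pairs (0 = same allele, 1 = different) and counts string differences;
the rate divides by the number of compared SNVs per haplotype (not the
number of pairs), the convention pinned throughout this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# phasing accuracy
# ---------------------------------------------------------------------------


def _shared(test_h1, test_h2, truth_h1, truth_h2):
    t1, t2 = np.asarray(test_h1), np.asarray(test_h2)
    u1, u2 = np.asarray(truth_h1), np.asarray(truth_h2)
    ok = (t1 >= 0) & (t2 >= 0) & (u1 >= 0) & (u2 >= 0)
    return t1[ok], t2[ok], u1[ok], u2[ok]


def best_pairing(test_h1, test_h2, truth_h1, truth_h2) -> bool:
    """True if (test H1 -> truth H2) gives the smaller Hamming distance."""
    t1, t2, u1, u2 = _shared(test_h1, test_h2, truth_h1, truth_h2)
    direct = int((t1 != u1).sum() + (t2 != u2).sum())
    swapped = int((t1 != u2).sum() + (t2 != u1).sum())
    return swapped < direct


def hamming_rate(test_h1, test_h2, truth_h1, truth_h2,
                 pairing: bool | None = None) -> float:
    """Fraction of compared alleles differing from truth (best pairing).

    Returns a fraction; multiply by 100 for the percent form.  ``pairing``
    forces truth-H1<->test-H2 when True (identity when False).
    """
    t1, t2, u1, u2 = _shared(test_h1, test_h2, truth_h1, truth_h2)
    if t1.size == 0:
        raise ValueError("no shared phased sites")
    if pairing is None:
        pairing = best_pairing(test_h1, test_h2, truth_h1, truth_h2)
    if pairing:
        u1, u2 = u2, u1
    n = t1.size
    r1 = (t1 != u1).sum() / n
    r2 = (t2 != u2).sum() / n
    return float((r1 + r2) / 2)


def _switch_string(h: np.ndarray) -> np.ndarray:
    return (h[1:] != h[:-1]).astype(np.int8)


def switch_error_rate(test_h1, test_h2, truth_h1, truth_h2,
                      pairing: bool | None = None) -> float:
    """Switch errors per compared SNV (best Hamming pairing, fraction)."""
    t1, t2, u1, u2 = _shared(test_h1, test_h2, truth_h1, truth_h2)
    if t1.size < 2:
        raise ValueError("need at least 2 shared phased sites")
    if pairing is None:
        pairing = best_pairing(test_h1, test_h2, truth_h1, truth_h2)
    if pairing:
        u1, u2 = u2, u1
    n = t1.size
    d1 = int((_switch_string(t1) != _switch_string(u1)).sum())
    d2 = int((_switch_string(t2) != _switch_string(u2)).sum())
    return float((d1 / n + d2 / n) / 2)


def phasing_metrics_by_chromosome(test: dict, truth: dict) -> pd.DataFrame:
    """Per-chromosome switch/Hamming rates with one pairing per chromosome.

    ``test``/``truth`` map chromosome -> (h1, h2) aligned arrays over shared
    SNV ids (use -1 for unphased sites).  Chromosomes with fewer than 2
    shared sites are excluded with a warning column.
    """
    import warnings

    rows = []
    for chrom in test:
        t1, t2 = test[chrom]
        u1, u2 = truth[chrom]
        sh = _shared(t1, t2, u1, u2)
        if sh[0].size < 2:
            warnings.warn(f"{chrom}: fewer than 2 shared phased sites; excluded")
            continue
        pairing = best_pairing(t1, t2, u1, u2)
        rows.append({
            "chrom": chrom,
            "n_shared": int(sh[0].size),
            "hamming": hamming_rate(t1, t2, u1, u2, pairing),
            "switch": switch_error_rate(t1, t2, u1, u2, pairing),
        })
    return pd.DataFrame(rows, columns=["chrom", "n_shared", "hamming", "switch"])


# ---------------------------------------------------------------------------
# consensus quality
# ---------------------------------------------------------------------------


@dataclass
class QVReport:
    identity: float        # percent
    error_bases: int
    qv: float              # Phred scale; inf when identity is 100%
    bases_per_error: float


def qv_from_alignment(matches: int, mismatches: int, ins_bases: int,
                      del_bases: int) -> QVReport:
    """Phred QV from alignment identity; N-bp indels count as N errors.

    identity = 100 * matches / (matches + mismatches + ins + del) and
    QV = -10 * log10(1 - identity / 100).  Perfect identity yields an
    infinite (capped) QV.
    """
    for v in (matches, mismatches, ins_bases, del_bases):
        if v < 0:
            raise ValueError("negative alignment counts")
    if matches <= 0:
        raise ValueError("matches must be > 0")
    errors = mismatches + ins_bases + del_bases
    total = matches + errors
    identity = 100.0 * matches / total
    if errors == 0:
        return QVReport(identity=100.0, error_bases=0, qv=math.inf,
                        bases_per_error=math.inf)
    qv = -10.0 * math.log10(1.0 - identity / 100.0)
    return QVReport(identity=identity, error_bases=errors, qv=qv,
                    bases_per_error=10.0 ** (qv / 10.0))


def contig_n50(lengths) -> int:
    """Largest L such that contigs of length >= L hold half the total."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("empty length list")
    half = arr.sum() / 2
    return int(arr[np.searchsorted(np.cumsum(arr), half)])


# ---------------------------------------------------------------------------
# loss of heterozygosity
# ---------------------------------------------------------------------------


def detect_loh(positions, het, chrom_length: int, bin_size: int = 200_000,
               slide: int = 10_000, min_seg: int = 200, loh_thresh: float = 0.05,
               quantile: float = 0.25, gain_penalty: float | None = None
               ) -> pd.DataFrame:
    """Segment a chromosome into LOH / NORM intervals from SNV diversity.

    Heterozygosity fraction is computed in ``bin_size`` windows sliding by
    ``slide``; values strictly below the 25th quantile become 0 and strictly
    above become 1 (values equal to the quantile keep 1, a fixed tie rule).
    Binary segmentation (minimizing within-segment variance, minimum segment
    ``min_seg`` bins, split accepted when the variance gain exceeds
    ``gain_penalty``, default 2*log(n)) finds change points; a segment is
    genotyped LOH when its median binarized value is <= ``loh_thresh``.
    Returned segments tile the binned chromosome exactly.
    """
    import warnings

    positions = np.asarray(positions)
    het = np.asarray(het, dtype=float)
    starts = np.arange(0, max(chrom_length - bin_size, 0) + 1, slide)
    if starts.size < min_seg:
        raise ValueError("chromosome too short for the requested segmentation")
    order = np.argsort(positions, kind="stable")
    positions, het = positions[order], het[order]
    chet = np.concatenate([[0.0], np.cumsum(het)])
    lo = np.searchsorted(positions, starts)
    hi = np.searchsorted(positions, starts + bin_size)
    with np.errstate(invalid="ignore"):
        frac = np.where(hi > lo, (chet[hi] - chet[lo]) / np.maximum(hi - lo, 1), 0.0)
    q = float(np.quantile(frac, quantile))
    if np.all(frac == frac[0]):
        warnings.warn("degenerate all-equal diversity; single NORM segment")
        binarized = np.ones_like(frac)
    else:
        binarized = np.where(frac < q, 0.0, 1.0)
    if gain_penalty is None:
        gain_penalty = 2.0 * math.log(len(binarized))
    cuts = sorted(_binary_segment(binarized, 0, len(binarized), min_seg, gain_penalty))
    edges = [0] + cuts + [len(binarized)]
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        med = float(np.median(binarized[a:b]))
        rows.append({
            "start_bin": a, "end_bin": b,
            "start": int(starts[a]),
            "end": int(min(starts[b - 1] + bin_size, chrom_length)),
            "median": med,
            "genotype": "LOH" if med <= loh_thresh else "NORM",
        })
    return pd.DataFrame(rows)


def _sse(c1, c2, a, b) -> float:
    n = b - a
    if n <= 0:
        return 0.0
    s = c1[b] - c1[a]
    s2 = c2[b] - c2[a]
    return float(s2 - s * s / n)


def _binary_segment(x: np.ndarray, a: int, b: int, min_seg: int,
                    penalty: float) -> list[int]:
    """Recursive binary segmentation on [a, b); returns cut indices."""
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def rec(a: int, b: int) -> list[int]:
        if b - a < 2 * min_seg:
            return []
        base = _sse(c1, c2, a, b)
        best_gain, best_k = 0.0, None
        for k in range(a + min_seg, b - min_seg + 1):
            gain = base - _sse(c1, c2, a, k) - _sse(c1, c2, k, b)
            if gain > best_gain + 1e-12:
                best_gain, best_k = gain, k
        if best_k is None or best_gain <= penalty:
            return []
        return rec(a, best_k) + [best_k] + rec(best_k, b)

    return rec(a, b)


# ---------------------------------------------------------------------------
# collapsed duplications
# ---------------------------------------------------------------------------


def detect_collapses(coverage: pd.DataFrame, min_len: int = 15_000,
                     sd_mult: float = 3.0,
                     repeat_annotation: pd.DataFrame | None = None,
                     repeat_frac: float = 0.75) -> pd.DataFrame:
    """Find high-coverage runs indicating collapsed repeats.

    ``coverage`` is a stepwise track (chrom, start, end, coverage).  Maximal
    runs exceeding mean + ``sd_mult`` * SD (length-weighted moments) and at
    least ``min_len`` long are reported; runs covered more than
    ``repeat_frac`` by the repeat annotation are excluded.
    """
    if len(coverage) == 0:
        raise ValueError("empty coverage track")
    lens = (coverage["end"] - coverage["start"]).to_numpy(dtype=float)
    cov = coverage["coverage"].to_numpy(dtype=float)
    mean = float(np.average(cov, weights=lens))
    sd = float(math.sqrt(np.average((cov - mean) ** 2, weights=lens)))
    thresh = mean + sd_mult * sd
    rows = []
    for chrom, sub in coverage.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for _, r in sub.iterrows():
            if r["coverage"] > thresh:
                if cur is not None and r["start"] <= cur[1]:
                    cur = (cur[0], int(r["end"]))
                else:
                    if cur is not None:
                        rows.append((chrom, *cur))
                    cur = (int(r["start"]), int(r["end"]))
            else:
                if cur is not None:
                    rows.append((chrom, *cur))
                    cur = None
        if cur is not None:
            rows.append((chrom, *cur))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out = out[(out["end"] - out["start"]) >= min_len].reset_index(drop=True)
    if repeat_annotation is not None and len(out):
        fracs = []
        for _, r in out.iterrows():
            sub = repeat_annotation[repeat_annotation["chrom"] == r["chrom"]]
            ov = np.minimum(sub["end"], r["end"]) - np.maximum(sub["start"], r["start"])
            fracs.append(float(np.clip(ov, 0, None).sum()) / (r["end"] - r["start"]))
        out = out[np.asarray(fracs) <= repeat_frac].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# common assembly breaks
# ---------------------------------------------------------------------------


def common_breaks(tilings: dict[str, pd.DataFrame], bin_size: int = 500_000,
                  min_contig: int = 100_000,
                  annotations: dict[str, pd.DataFrame] | None = None,
                  slop: int = 10_000) -> pd.DataFrame:
    """Bins where every assembly breaks between consecutive contigs.

    ``tilings`` maps assembly name -> contig intervals on a shared reference
    (chrom, start, end, contig).  Contigs shorter than ``min_contig`` are
    dropped; an assembly break is the gap between consecutive contigs,
    located at the gap midpoint.  A common break is a ``bin_size`` bin
    holding at least one breakpoint from every assembly; the reported region
    spans the first to last breakpoint in the bin, annotated with features
    within ``slop`` bp.
    """
    if len(tilings) < 2:
        raise ValueError("need at least two assemblies")
    bps: dict[str, list[tuple[str, int]]] = {}
    for name, df in tilings.items():
        df = df[(df["end"] - df["start"]) >= min_contig]
        pts = []
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            e = sub["end"].to_numpy()
            s = sub["start"].to_numpy()
            for i in range(len(sub) - 1):
                pts.append((chrom, int((e[i] + s[i + 1]) // 2)))
        bps[name] = pts
    per_bin: dict[tuple[str, int], dict[str, list[int]]] = {}
    for name, pts in bps.items():
        for chrom, p in pts:
            key = (chrom, p // bin_size)
            per_bin.setdefault(key, {}).setdefault(name, []).append(p)
    rows = []
    for (chrom, b), hits in sorted(per_bin.items()):
        if len(hits) < len(tilings):
            continue
        allp = sorted(p for ps in hits.values() for p in ps)
        row = {"chrom": chrom, "bin": b, "start": allp[0], "end": allp[-1] + 1,
               "n_breakpoints": len(allp)}
        if annotations:
            for aname, adf in annotations.items():
                sub = adf[adf["chrom"] == chrom]
                near = ((sub["start"] <= row["end"] + slop)
                        & (sub["end"] >= row["start"] - slop)).any()
                row[aname] = bool(near)
        rows.append(row)
    cols = ["chrom", "bin", "start", "end", "n_breakpoints"] + (
        list(annotations) if annotations else [])
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# segmental duplication resolution
# ---------------------------------------------------------------------------


def sd_resolution(alignments: pd.DataFrame, sds: pd.DataFrame,
                  extensions=(10_000, 20_000, 30_000, 40_000, 50_000),
                  both_flanks: bool = True) -> tuple[float, dict[int, float]]:
    """Average percent of SDs resolved over a grid of minimum extensions.

    An SD is resolved at extension X when a single alignment spans it with at
    least X bp beyond both flanks (or one flank with ``both_flanks=False``).
    Returns (average percent, percent per extension).
    """
    if len(sds) == 0:
        raise ValueError("empty SD set")
    per_x = {}
    for x in extensions:
        resolved = 0
        for _, sd in sds.iterrows():
            sub = alignments[alignments["chrom"] == sd["chrom"]]
            if both_flanks:
                ok = ((sub["start"] <= sd["start"] - x)
                      & (sub["end"] >= sd["end"] + x)).any()
            else:
                ok = (((sub["start"] <= sd["start"] - x) & (sub["end"] >= sd["end"]))
                      | ((sub["start"] <= sd["start"]) & (sub["end"] >= sd["end"] + x))).any()
            resolved += bool(ok)
        per_x[int(x)] = 100.0 * resolved / len(sds)
    return float(np.mean(list(per_x.values()))), per_x
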