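"""Cluster contig bins into chromosomal scaffolds from strand inheritance.

The model: each cluster (ideally one chromosome) has, per Strand-seq cell, a
latent strand state in {WW, WC, CC}; the Watson read count of a bin in a
cell is Binomial(n, p) with p = 1 - eps (WW), 0.5 (WC) or eps (CC), where
``eps`` absorbs symmetric background noise.  Each bin additionally carries a
latent orientation: a minus-oriented bin sees the state flipped WW <-> CC.
An EM algorithm fits the per-cluster-per-cell state distributions, mixing
weights and per-bin cluster/orientation posteriors; the log-likelihood is
non-decreasing by construction and checked every iteration.

Downstream steps mirror the scaffolding workflow: ambiguous and always-WC
contigs are filtered, clusters sharing the same strand inheritance are
merged by connected components, contig orientations are synchronized by
hierarchical clustering on directionality disagreement, contigs are ordered
by strand-state coinheritance (nearest neighbour + 2-opt open-path TSP),
and chimeric / misoriented contigs are detected from bin-level posteriors
and corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp
from scipy.stats import binom
from sklearn.cluster import KMeans

from .simdata import ContigSet
from .strandstate import CC, UNKNOWN, WC, WW, CountMatrix, call_strand_state

_STATES = 3  # WW, WC, CC (canonical order)
_FLIP = np.array([2, 1, 0])  # orientation flip permutes WW <-> CC


@dataclass
class ClusterModel:
    """Fitted EM mixture over contig bins."""

    P: np.ndarray            # bins x K cluster posterior
    orient: np.ndarray       # bins, posterior probability of minus orientation
    theta: np.ndarray        # K x cells x 3 state distributions
    pi: np.ndarray           # K mixing weights
    eps: float
    loglik: list[float]
    counts: CountMatrix

    @property
    def K(self) -> int:
        return self.P.shape[1]


def _loglik_tensor(counts: CountMatrix, eps: float) -> np.ndarray:
    """Per-(bin, cell) binomial log-likelihood under the three canonical states."""
    W = counts.W.astype(float)
    n = counts.n.astype(float)
    ps = np.array([1 - eps, 0.5, eps])
    LL = np.stack([binom.logpmf(W, n, p) for p in ps], axis=-1)
    LL[n == 0] = 0.0  # empty cells carry no information
    return LL


def em_cluster(counts: CountMatrix, K: int, seed: int = 0, max_iter: int = 100,
               tol: float = 1e-6, eps: float = 0.05) -> ClusterModel:
    """Fit the strand-inheritance mixture with EM.

    Initialization is k-means++ on per-bin Watson-fraction vectors with a
    fixed seed; ties and all numerical choices are deterministic.
    """
    W = counts.W.astype(float)
    n = counts.n.astype(float)
    nbins, ncells = W.shape
    if ncells < 2:
        raise ValueError("need at least 2 cells")
    if K > nbins:
        raise ValueError("K exceeds the number of bins")
    if n.sum() == 0:
        raise ValueError("degenerate all-zero count matrix")

    LL = _loglik_tensor(counts, eps)

    # --- init: k-means++ on Watson fractions -------------------------------
    with np.errstate(invalid="ignore"):
        f = np.where(n > 0, W / np.maximum(n, 1), 0.5)
    km = KMeans(n_clusters=K, n_init=1, random_state=int(seed) % (2**31), max_iter=20)
    labels = km.fit_predict(f)
    naive = np.where(f >= 0.75, 0, np.where(f <= 0.25, 2, 1))
    naive[n == 0] = -1
    theta = np.full((K, ncells, _STATES), 1.0 / _STATES)
    for k in range(K):
        member = labels == k
        if not member.any():
            continue
        for s in range(_STATES):
            theta[k, :, s] = (naive[member] == s).sum(axis=0) + 0.5
        theta[k] /= theta[k].sum(axis=1, keepdims=True)
    pi = np.bincount(labels, minlength=K).astype(float) + 1.0
    pi /= pi.sum()

    logliks: list[float] = []
    R = np.zeros((nbins, K, 2))
    prev = -np.inf
    for it in range(max_iter):
        # E-step
        M = np.empty((nbins, K, 2))
        logtheta = np.log(theta)
        for o in range(2):
            LLo = LL[:, :, _FLIP] if o == 1 else LL  # observed under flipped frame
            for k in range(K):
                A = logsumexp(logtheta[k][None, :, :] + LLo, axis=2)  # bins x cells
                M[:, k, o] = A.sum(axis=1)
        logpost = np.log(pi)[None, :, None] + np.log(0.5) + M
        norm = logsumexp(logpost.reshape(nbins, -1), axis=1)
        ll = float(norm.sum())
        logliks.append(ll)
        if ll < prev - 1e-6 * max(1.0, abs(prev)):
            warnings.warn(f"EM log-likelihood decreased at iteration {it}")
        R = np.exp(logpost - norm[:, None, None])
        if it > 0 and abs(ll - prev) <= tol * max(1.0, abs(prev)):
            prev = ll
            break
        prev = ll
        # M-step
        P = R.sum(axis=2)
        pi = P.sum(axis=0) + 1e-8
        pi /= pi.sum()
        new_theta = np.full((K, ncells, _STATES), 1e-3)
        for o in range(2):
            LLo = LL[:, :, _FLIP] if o == 1 else LL
            for k in range(K):
                q = logtheta[k][None, :, :] + LLo
                q = np.exp(q - logsumexp(q, axis=2, keepdims=True))
                new_theta[k] += np.einsum("i,ijs->js", R[:, k, o], q)
        theta = new_theta / new_theta.sum(axis=2, keepdims=True)

    P = R.sum(axis=2)
    orient = R[:, :, 1].sum(axis=1)
    return ClusterModel(P=P, orient=orient, theta=theta, pi=pi, eps=eps,
                        loglik=logliks, counts=counts)


# ---------------------------------------------------------------------------
# filtering & merging
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldSet:
    """Merged clusters with per-contig assignment, orientation and order."""

    contig_table: pd.DataFrame  # contig, cluster, posterior, orientation, order_index
    cluster_members: dict[int, list[str]]
    component_of: np.ndarray    # initial cluster -> merged component id (-1 dropped)
    parity: np.ndarray          # initial cluster frame flip vs component root
    bin_P: np.ndarray | None = None       # bins x components posterior
    bin_orient: np.ndarray | None = None  # bins, minus-posterior in component frame
    distance: dict[int, pd.DataFrame] = field(default_factory=dict)
    low_confidence: dict[int, bool] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_members)


class _UnionFind:
    """Union-find with frame parity (flip of WW/CC between members)."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.parity = [0] * n

    def find(self, x: int) -> tuple[int, int]:
        if self.parent[x] == x:
            return x, 0
        root, par = self.find(self.parent[x])
        self.parent[x] = root
        self.parity[x] ^= par
        return root, self.parity[x]

    def union(self, a: int, b: int, flip: int) -> bool:
        ra, pa = self.find(a)
        rb, pb = self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        self.parity[rb] = pa ^ pb ^ flip
        return True


def _contig_posteriors(P: np.ndarray, bins: pd.DataFrame) -> pd.DataFrame:
    """Length-weighted geometric-mean posterior per contig from bin posteriors."""
    lens = (bins["end"] - bins["start"]).to_numpy().astype(float)
    logP = np.log(np.clip(P, 1e-12, None))
    rows = {}
    for contig, idx in bins.groupby("contig", sort=False).groups.items():
        ii = np.asarray(list(idx))
        w = lens[ii] / lens[ii].sum()
        lp = (w[:, None] * logP[ii]).sum(axis=0)
        lp -= logsumexp(lp)
        rows[contig] = np.exp(lp)
    return pd.DataFrame.from_dict(rows, orient="index")


def _component_posteriors(model: ClusterModel, component_of: np.ndarray,
                          parity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One E-step restricted to retained clusters, folded per component.

    Returns (bins x components posterior, per-bin minus-orientation posterior
    expressed in the component frame).  Restricting the posterior to the
    surviving clusters reassigns bins whose best initial cluster was dropped
    as an overfit fragment.
    """
    LL = _loglik_tensor(model.counts, model.eps)
    kept = [k for k in range(model.K) if component_of[k] >= 0]
    n_comp = int(component_of.max()) + 1
    nbins = LL.shape[0]
    logtheta = np.log(model.theta)
    logpi = np.log(np.clip(model.pi, 1e-12, None))
    M = np.empty((nbins, len(kept), 2))
    for o in range(2):
        LLo = LL[:, :, _FLIP] if o == 1 else LL
        for j, k in enumerate(kept):
            M[:, j, o] = logsumexp(logtheta[k][None, :, :] + LLo, axis=2).sum(axis=1)
    logpost = logpi[kept][None, :, None] + np.log(0.5) + M
    norm = logsumexp(logpost.reshape(nbins, -1), axis=1)
    R = np.exp(logpost - norm[:, None, None])
    bin_P = np.zeros((nbins, n_comp))
    bin_orient = np.zeros(nbins)
    for j, k in enumerate(kept):
        comp = component_of[k]
        bin_P[:, comp] += R[:, j].sum(axis=1)
        # component-frame minus <=> cluster-frame flip XOR cluster parity
        bin_orient += R[:, j, 1 ^ parity[k]]
    return bin_P, bin_orient


def cluster_agreement(theta: np.ndarray, k: int, l: int) -> tuple[float, int]:
    """Fraction of cells whose hard states agree between clusters k and l.

    Returns the best agreement over the two relative frames and the frame
    flip (1 if l must be WW<->CC flipped to match k).
    """
    sk = theta[k].argmax(axis=1)
    sl = theta[l].argmax(axis=1)
    direct = float((sk == sl).mean())
    flipped = float((sk == _FLIP[sl]).mean())
    if flipped > direct:
        return flipped, 1
    return direct, 0


def filter_and_merge(model: ClusterModel, contigs_lengths: dict[str, int] | None = None,
                     prob_th: float = 0.25, remove_always_wc: bool = True,
                     wc_cell_frac: float = 0.8, agreement_th: float = 0.7,
                     desired_clusters: int | None = None,
                     min_contig_size: int = 100_000,
                     min_reads: int = 50, background: float = 0.1) -> ScaffoldSet:
    """Filter contigs and merge clusters sharing strand inheritance.

    Contigs shorter than ``min_contig_size`` are dropped up front.  Clusters
    whose per-cell hard states agree (up to a frame flip) in at least
    ``agreement_th`` of cells are merged via connected components; when
    ``desired_clusters`` is given, the best remaining links keep merging
    until that many components remain.  Contigs whose runner-up posterior
    over *merged* components reaches ``prob_th`` are discarded as ambiguous,
    and contigs genotyped WC in more than ``wc_cell_frac`` of informative
    cells are discarded as haplotype-uninformative (both-homolog signal).
    """
    counts = model.counts
    grid = counts.grid
    if contigs_lengths is None:
        contigs_lengths = {c: int((grid.bins.loc[grid.bins["contig"] == c, "end"]
                                   - grid.bins.loc[grid.bins["contig"] == c, "start"]).sum())
                           for c in grid.contigs}

    live = np.flatnonzero(model.pi > 1e-4)
    K = model.K
    uf = _UnionFind(K)
    edges = []
    for i, k in enumerate(live):
        for l in live[i + 1:]:
            agree, flip = cluster_agreement(model.theta, int(k), int(l))
            edges.append((agree, int(k), int(l), flip))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    n_comp = len(live)
    for agree, k, l, flip in edges:
        if agree < agreement_th:
            break
        if uf.union(k, l, flip):
            n_comp -= 1

    component_of = np.full(K, -1)
    parity = np.zeros(K, dtype=int)
    comp_ids: dict[int, int] = {}
    for k in live:
        root, par = uf.find(int(k))
        comp_ids.setdefault(root, len(comp_ids))
        component_of[k] = comp_ids[root]
        parity[k] = par
    n_comp = len(comp_ids)

    if desired_clusters is not None:
        # report only the most-connected subgraphs: rank components by total
        # mixing mass and drop the rest (overfit fragments, not chromosomes)
        if desired_clusters > n_comp:
            warnings.warn(
                f"desired_clusters={desired_clusters} exceeds live components ({n_comp})")
        else:
            mass = np.zeros(n_comp)
            for k in live:
                mass[component_of[k]] += model.pi[int(k)]
            keep = set(np.argsort(-mass)[:desired_clusters].tolist())
            remap = {}
            for old in sorted(keep):
                remap[old] = len(remap)
            for k in live:
                c = component_of[k]
                component_of[k] = remap.get(c, -1)
            n_comp = len(remap)

    bin_P, bin_orient = _component_posteriors(model, component_of, parity)
    cpost = _contig_posteriors(bin_P, grid.bins)
    merged = cpost.to_numpy()

    # per-contig per-cell hard states for the always-WC rule
    Wc, Cc, contig_list = counts.contig_totals()
    states = call_strand_state(Wc, Cc, background=background, min_reads=min_reads)
    contig_idx = {c: i for i, c in enumerate(contig_list)}

    rows = []
    for ci, contig in enumerate(cpost.index):
        length = contigs_lengths.get(contig, 0)
        post = merged[ci]
        order = np.argsort(-post)
        best, second = order[0], (order[1] if n_comp > 1 else order[0])
        reason = None
        if length < min_contig_size:
            reason = "too_short"
        elif n_comp > 1 and post[second] >= prob_th:
            reason = "ambiguous"
        elif remove_always_wc:
            st = states[contig_idx[contig]]
            informative = st != UNKNOWN
            if informative.sum() > 0 and (st[informative] == WC).mean() > wc_cell_frac:
                reason = "always_wc"
        rows.append({"contig": contig, "cluster": int(best) if reason is None else -1,
                     "posterior": float(post[best]), "discard_reason": reason,
                     "orientation": None, "order_index": None, "length": length})
    table = pd.DataFrame(rows)
    members = {
        int(k): sorted(table.loc[table["cluster"] == k, "contig"])
        for k in sorted(table.loc[table["cluster"] >= 0, "cluster"].unique())
    }
    return ScaffoldSet(contig_table=table, cluster_members=members,
                       component_of=component_of, parity=parity,
                       bin_P=bin_P, bin_orient=bin_orient)


# ---------------------------------------------------------------------------
# orientation & ordering
# ---------------------------------------------------------------------------


def directionality_distance(states: np.ndarray) -> np.ndarray:
    """Pairwise disagreement among WW/CC-informative cells.

    ``states`` is contigs x cells (codes); cells where either contig is WC
    or unknown are ignored.  Pairs with no informative cell get 0.5.
    """
    nc = states.shape[0]
    D = np.full((nc, nc), 0.5)
    np.fill_diagonal(D, 0.0)
    informative = (states == WW) | (states == CC)
    for a in range(nc):
        for b in range(a + 1, nc):
            both = informative[a] & informative[b]
            if both.sum() == 0:
                continue
            d = float((states[a, both] != states[b, both]).mean())
            D[a, b] = D[b, a] = d
    return D


def sync_orientation(states: np.ndarray, lengths: np.ndarray,
                     contig_ids: list[str]) -> dict[str, str]:
    """Split contigs into plus/minus groups and flip the minor-length group.

    Agglomerative (average-linkage) clustering on the pairwise
    directionality-disagreement distance separates misoriented contigs,
    whose WW/CC states oppose the rest in every cell.  The group with the
    larger total length defines the canonical plus orientation.  When the two
    groups are not actually opposed (mean inter-group distance <= 0.5, i.e.
    no contig consistently disagrees), nothing is flipped.
    """
    nc = len(contig_ids)
    if nc == 1:
        return {contig_ids[0]: "+"}
    D = directionality_distance(states)
    cond = D[np.triu_indices(nc, 1)]
    Z = linkage(cond, method="average")
    groups = fcluster(Z, t=2, criterion="maxclust")
    g1 = np.flatnonzero(groups == 1)
    g2 = np.flatnonzero(groups == 2)
    if len(g1) == 0 or len(g2) == 0:
        return {c: "+" for c in contig_ids}
    inter = float(D[np.ix_(g1, g2)].mean())
    if inter <= 0.5:
        return {c: "+" for c in contig_ids}
    len1 = float(lengths[g1].sum())
    len2 = float(lengths[g2].sum())
    if len1 > len2 or (len1 == len2 and min(contig_ids[i] for i in g1) < min(contig_ids[i] for i in g2)):
        minus = g2
    else:
        minus = g1
    out = {c: "+" for c in contig_ids}
    for i in minus:
        out[contig_ids[i]] = "-"
    return out


def coinheritance_distance(states: np.ndarray) -> np.ndarray:
    """D[a, b] = fraction of informative cells where the states differ."""
    nc = states.shape[0]
    D = np.zeros((nc, nc))
    known = states != UNKNOWN
    for a in range(nc):
        for b in range(a + 1, nc):
            both = known[a] & known[b]
            if both.sum() == 0:
                D[a, b] = D[b, a] = 1.0
                continue
            d = float((states[a, both] != states[b, both]).mean())
            D[a, b] = D[b, a] = d
    return D


def path_cost(D: np.ndarray, order: list[int]) -> float:
    return float(sum(D[order[i], order[i + 1]] for i in range(len(order) - 1)))


def _two_opt(D: np.ndarray, order: list[int]) -> list[int]:
    improved = True
    best = list(order)
    while improved:
        improved = False
        for i in range(len(best) - 1):
            for j in range(i + 1, len(best)):
                cand = best[:i] + best[i:j + 1][::-1] + best[j + 1:]
                if path_cost(D, cand) < path_cost(D, best) - 1e-12:
                    best = cand
                    improved = True
    return best


def order_contigs(states: np.ndarray, contig_ids: list[str],
                  method: str = "tsp") -> tuple[list[str], np.ndarray, bool]:
    """Order contigs by strand-state coinheritance.

    SCEs are cell-private strand switches, so nearby contigs share states
    more often than distant ones; the open-path order minimizing total
    coinheritance distance recovers the physical order.  ``tsp`` runs
    nearest-neighbour construction from every start plus 2-opt refinement;
    ``greedy`` stops after nearest-neighbour chaining.  Returns the order,
    the distance matrix and a low-confidence flag (True when the distance
    matrix is all zero, i.e. no SCEs to order by).
    """
    nc = len(contig_ids)
    D = coinheritance_distance(states)
    if nc <= 2:
        return list(contig_ids), D, bool(np.all(D[np.triu_indices(nc, 1)] == 0)) if nc == 2 else True
    off = D[np.triu_indices(nc, 1)]
    if np.all(off == 0):
        return list(contig_ids), D, True
    best_order, best_cost = None, np.inf
    for start in range(nc):
        left = set(range(nc))
        cur = start
        left.remove(cur)
        order = [cur]
        while left:
            cands = sorted(left, key=lambda j: (D[cur, j], j))
            cur = cands[0]
            left.remove(cur)
            order.append(cur)
        if method == "tsp":
            order = _two_opt(D, order)
        c = path_cost(D, order)
        if c < best_cost - 1e-12:
            best_cost, best_order = c, order
    if best_order[0] > best_order[-1]:  # canonical direction
        best_order = best_order[::-1]
    return [contig_ids[i] for i in best_order], D, False


# ---------------------------------------------------------------------------
# misassembly detection & correction
# ---------------------------------------------------------------------------


@dataclass
class AssemblyErrorReport:
    chimeras: pd.DataFrame        # contig, breakpoint (contig bp), bin boundary, clusters
    misorientations: pd.DataFrame  # contig, start, end (contig bp)

    @property
    def empty(self) -> bool:
        return len(self.chimeras) == 0 and len(self.misorientations) == 0


def detect_assembly_errors(model: ClusterModel, scaffolds: ScaffoldSet,
                           reads: pd.DataFrame | None = None,
                           switch_frac: float = 0.25, min_reads: int = 20,
                           background: float = 0.1) -> AssemblyErrorReport:
    """Flag chimeric and internally misoriented contigs from bin posteriors.

    A chimera shows contiguous bin blocks of one contig assigned to
    different merged clusters; a misoriented interval shows bins whose
    orientation posterior opposes the contig consensus, corroborated by
    WW<->CC state switches at the same bin boundary in at least
    ``switch_frac`` of WW/CC-informative cells.  Breakpoints fall on bin
    boundaries; when the per-cell ``reads`` are provided each breakpoint is
    refined to read resolution by pooling the cells whose hard states
    disagree across the boundary (Crick-state cells contribute with flipped
    directions) and maximizing the two-segment binomial split score, so that
    corrections leave no bin-scale residue.
    """
    counts = model.counts
    bins = counts.grid.bins
    if scaffolds.bin_P is not None:
        Pm, bin_orient = scaffolds.bin_P, scaffolds.bin_orient
    else:
        Pm, bin_orient = _component_posteriors(model, scaffolds.component_of,
                                               scaffolds.parity)
    bin_comp = Pm.argmax(axis=1)

    chim_rows, mis_rows = [], []
    Wb, Cb = counts.W, counts.C
    min_informative = max(5, Wb.shape[1] // 10)
    cells = counts.cells
    read_groups = (dict(tuple(reads.groupby("contig", sort=False)))
                   if reads is not None else {})

    def refine(rsub, gl: int, gr: int, lo: int, hi: int) -> int | None:
        """Read-level breakpoint between global bins gl (left) and gr (right)."""
        from .strandstate import _refine_breakpoint

        sl = call_strand_state(Wb[gl], Cb[gl], background, 10)
        sr = call_strand_state(Wb[gr], Cb[gr], background, 10)
        inf = (np.isin(sl, (WW, CC)) & np.isin(sr, (WW, CC)) & (sl != sr))
        if inf.sum() < 3:
            return None
        keep = {cells[i] for i in np.flatnonzero(inf)}
        flip = {cells[i] for i in np.flatnonzero(inf & (sl == CC))}
        m = rsub[(rsub["pos"] >= lo) & (rsub["pos"] < hi) & rsub["cell"].isin(keep)]
        if len(m) < 20:
            return None
        w = ((m["strand"].to_numpy() == "-") ^ m["cell"].isin(flip).to_numpy()).astype(float)
        p = m["pos"].to_numpy()
        order = np.argsort(p, kind="stable")
        return _refine_breakpoint(p[order], w[order], lo, hi, "WW", "CC", background)

    def switch_ok(ia: int, ib: int) -> bool | None:
        """WW<->CC switch fraction between two bins; None = uninformative."""
        sa = call_strand_state(Wb[ia], Cb[ia], background, min_reads)
        sb_ = call_strand_state(Wb[ib], Cb[ib], background, min_reads)
        informative = ((sa == WW) | (sa == CC)) & ((sb_ == WW) | (sb_ == CC))
        if informative.sum() < min_informative:
            return None
        switch = (sa != sb_) & informative
        return float(switch.sum()) / float(informative.sum()) >= switch_frac

    for contig, sub in bins.groupby("contig", sort=False):
        ii = sub.index.to_numpy()
        if len(ii) < 2:
            continue
        row = scaffolds.contig_table[scaffolds.contig_table["contig"] == contig]
        if len(row) and row.iloc[0]["discard_reason"] == "too_short":
            continue
        comps = bin_comp[ii].copy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # bins without a confident assignment (runt or low-coverage bins)
        # follow their neighbour instead of triggering a breakpoint
        conf = Pm[ii].max(axis=1)
        for j in range(1, len(ii)):
            if conf[j] < 0.6:
                comps[j] = comps[j - 1]
        for j in range(len(ii) - 2, -1, -1):
            if conf[j] < 0.6:
                comps[j] = comps[j + 1]
        # a bin straddling a true breakpoint is a mixture of two signals and
        # can stray to an unrelated cluster; absorb single-bin foreign blocks
        # flanked by one and the same component
        for j in range(1, len(ii) - 1):
            if comps[j] != comps[j - 1] and comps[j - 1] == comps[j + 1]:
                comps[j] = comps[j - 1]
        # chimera: block structure of merged-cluster assignment.  A single
        # straddling bin between two *different* components is the breakpoint
        # bin itself: report one breakpoint at its midpoint.
        rsub = read_groups.get(contig)

        def refine_pair(a: int, b: int) -> int | None:
            if rsub is None:
                return None
            return refine(rsub, int(ii[a]), int(ii[b]),
                          int(starts[a]), int(ends[b]))

        change = list(np.flatnonzero(comps[1:] != comps[:-1]))
        c = 0
        while c < len(change):
            j = change[c]
            if (c + 1 < len(change) and change[c + 1] == j + 1
                    and comps[j] != comps[j + 2]):
                bp = refine_pair(j, j + 2)
                if bp is None:
                    bp = int((starts[j + 1] + ends[j + 1]) // 2)
                chim_rows.append({
                    "contig": contig, "breakpoint": int(bp),
                    "bin_left": int(ii[j]), "bin_right": int(ii[j + 2]),
                    "cluster_left": int(comps[j]), "cluster_right": int(comps[j + 2]),
                })
                c += 2
                continue
            bp = refine_pair(j, j + 1)
            if bp is None:
                bp = int(starts[j + 1])
            chim_rows.append({
                "contig": contig, "breakpoint": int(bp),
                "bin_left": int(ii[j]), "bin_right": int(ii[j + 1]),
                "cluster_left": int(comps[j]), "cluster_right": int(comps[j + 1]),
            })
            c += 1
        # misorientation: opposing-orientation bin runs, examined within each
        # single-component block (a chimera's parts have unrelated frames)
        flips = bin_orient[ii] > 0.5
        lens = (ends - starts).astype(float)
        block_edges = [0] + [int(c) + 1 for c in change] + [len(ii)]
        for bs, be in zip(block_edges[:-1], block_edges[1:]):
            if be - bs < 2:
                continue
            mis_rows.extend(_misoriented_runs(
                contig, ii, starts, ends, flips, lens, bs, be, switch_ok,
                refine_pair))
    return AssemblyErrorReport(
        chimeras=pd.DataFrame(chim_rows, columns=["contig", "breakpoint", "bin_left",
                                                  "bin_right", "cluster_left", "cluster_right"]),
        misorientations=pd.DataFrame(mis_rows, columns=["contig", "start", "end"]),
    )


def _misoriented_runs(contig, ii, starts, ends, flips, lens, bs, be, switch_ok,
                      refine_pair=None):
    """Opposing-orientation runs within one component block [bs, be).

    The canonical frame is the majority by length, except when that choice
    would place the "misoriented" bins in two runs touching both block ends
    while the opposite choice yields fewer runs: an inverted internal
    interval is the expected error mode, and a mixed boundary bin can tip a
    near-half majority the wrong way.  Each run must be a proper subset of
    the block and is corroborated by WW<->CC switches at its boundaries; the
    immediate neighbour may be the mixed breakpoint bin, so the comparison
    falls back one bin outward/inward (the 1-bin tolerance is unchanged).
    """
    fl = flips[bs:be]
    ln = lens[bs:be]
    n = be - bs

    def runs_for(cons):
        opp = fl != cons
        out = []
        j = 0
        while j < n:
            if not opp[j]:
                j += 1
                continue
            j2 = j
            while j2 + 1 < n and opp[j2 + 1]:
                j2 += 1
            out.append((j, j2))
            j = j2 + 1
        return out

    majority = bool((ln * fl).sum() > ln.sum() / 2)
    cand = {c: runs_for(c) for c in (majority, not majority)}
    consensus = majority
    if len(cand[not majority]) != 0 and len(cand[not majority]) < len(cand[majority]):
        consensus = not majority
    rows = []
    for j, j2 in cand[consensus]:
        if j2 - j + 1 >= n:
            continue  # whole block: handled by contig-level orientation sync
        ok = []
        if j > 0:
            for a, b in ((j - 1, j), (j - 2, j), (j - 1, min(j + 1, j2))):
                if a < 0:
                    continue
                res = switch_ok(int(ii[bs + a]), int(ii[bs + b]))
                if res is not None:
                    ok.append(res)
                    break
            else:
                ok.append(False)
        if j2 < n - 1:
            for a, b in ((j2, j2 + 1), (j2, j2 + 2), (max(j2 - 1, j), j2 + 1)):
                if b >= n:
                    continue
                res = switch_ok(int(ii[bs + a]), int(ii[bs + b]))
                if res is not None:
                    ok.append(res)
                    break
            else:
                ok.append(False)
        if ok and all(ok):
            start = int(starts[bs + j])
            end = int(ends[bs + j2])
            if refine_pair is not None:
                if j > 0:
                    r = refine_pair(bs + j - 1, bs + j)
                    if r is not None:
                        start = int(r)
                if j2 < n - 1:
                    r = refine_pair(bs + j2, bs + j2 + 1)
                    if r is not None:
                        end = int(r)
            rows.append({"contig": contig, "start": start, "end": end})
    return rows


def apply_corrections(contigs: ContigSet, report: AssemblyErrorReport,
                      sequences: dict[str, str] | None = None,
                      ) -> tuple[ContigSet, dict[str, str] | None, pd.DataFrame]:
    """Split chimeras and reverse-complement misoriented intervals.

    Returns the corrected contig set (truth segments remapped through the
    corrections), corrected sequences when given, and a rename log.  An
    empty report returns the input unchanged.  Overlapping correction
    intervals on one contig are rejected.
    """
    from .simdata import revcomp

    actions: dict[str, list[tuple[str, int, int]]] = {}
    for _, r in report.chimeras.iterrows():
        actions.setdefault(r["contig"], []).append(("split", int(r["breakpoint"]), int(r["breakpoint"])))
    for _, r in report.misorientations.iterrows():
        actions.setdefault(r["contig"], []).append(("flip", int(r["start"]), int(r["end"])))
    for contig, acts in actions.items():
        ivals = sorted((a, b) for _, a, b in acts if a != b)
        for (a1, b1), (a2, b2) in zip(ivals, ivals[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping correction intervals on {contig}")

    log_rows = []
    new_frames = []
    new_seqs: dict[str, str] | None = {} if sequences is not None else None
    for contig in contigs.contig_names:
        sub = contigs.segments[contigs.segments["contig"] == contig]
        acts = sorted(actions.get(contig, []), key=lambda t: t[1])
        seq = sequences.get(contig) if sequences else None
        if not acts:
            new_frames.append(sub)
            if new_seqs is not None and seq is not None:
                new_seqs[contig] = seq
            continue
        # flips first (coordinates unchanged), then splits
        segs = [dict(r) for _, r in sub.iterrows()]
        for kind, a, b in acts:
            if kind == "flip":
                segs = _flip_segments(segs, a, b)
                if seq is not None:
                    seq = seq[:a] + revcomp(seq[a:b]) + seq[b:]
                log_rows.append({"contig": contig, "action": "flip", "start": a, "end": b,
                                 "result": contig})
        splits = sorted(a for kind, a, _ in acts if kind == "split")
        if splits:
            bounds = [0] + splits + [sum(s["end"] - s["start"] for s in segs)]
            for pi in range(len(bounds) - 1):
                name = f"{contig}.{pi + 1}"
                part = _slice_segments(segs, bounds[pi], bounds[pi + 1], name)
                new_frames.append(pd.DataFrame(part))
                if new_seqs is not None and seq is not None:
                    new_seqs[name] = seq[bounds[pi]:bounds[pi + 1]]
                log_rows.append({"contig": contig, "action": "split",
                                 "start": bounds[pi], "end": bounds[pi + 1], "result": name})
        else:
            df = pd.DataFrame(segs)
            df["seg"] = np.arange(len(df))
            new_frames.append(df)
            if new_seqs is not None and seq is not None:
                new_seqs[contig] = seq
    segments = pd.concat(new_frames, ignore_index=True)
    segments = segments[["contig", "seg", "chrom", "start", "end", "strand"]]
    segments = segments.sort_values(["contig", "seg"], kind="stable").reset_index(drop=True)
    corrected = ContigSet(segments=segments, errors=pd.DataFrame(
        columns=["type", "contig", "start", "end"]))
    return corrected, new_seqs, pd.DataFrame(
        log_rows, columns=["contig", "action", "start", "end", "result"])


def _seg_len(s: dict) -> int:
    return int(s["end"]) - int(s["start"])


def _slice_one(s: dict, lo: int, hi: int) -> dict:
    """Sub-interval [lo, hi) in segment-local contig coordinates."""
    out = dict(s)
    if s["strand"] == "+":
        out["start"] = int(s["start"]) + lo
        out["end"] = int(s["start"]) + hi
    else:
        out["start"] = int(s["end"]) - hi
        out["end"] = int(s["end"]) - lo
    return out


def _iter_slices(segs: list[dict], a: int, b: int):
    """Yield (seg, local_lo, local_hi) covering contig interval [a, b)."""
    off = 0
    for s in segs:
        L = _seg_len(s)
        lo = max(a - off, 0)
        hi = min(b - off, L)
        if hi > lo:
            yield s, lo, hi
        off += L


def _slice_segments(segs: list[dict], a: int, b: int, name: str) -> list[dict]:
    out = []
    for k, (s, lo, hi) in enumerate(_iter_slices(segs, a, b)):
        ns = _slice_one(s, lo, hi)
        ns["contig"] = name
        ns["seg"] = k
        out.append(ns)
    return out


def _flip_segments(segs: list[dict], a: int, b: int) -> list[dict]:
    """Reverse-complement contig interval [a, b) at the segment level."""
    total = sum(_seg_len(s) for s in segs)
    head = _slice_segments(segs, 0, a, segs[0]["contig"]) if a > 0 else []
    mid = _slice_segments(segs, a, b, segs[0]["contig"])
    tail = _slice_segments(segs, b, total, segs[0]["contig"]) if b < total else []
    for s in mid:
        s["strand"] = "-" if s["strand"] == "+" else "+"
    mid = mid[::-1]
    out = head + mid + tail
    for k, s in enumerate(out):
        s["seg"] = k
    return out
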