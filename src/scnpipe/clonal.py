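"""Collective analysis of integer copy-number profiles.

Each profile is reduced to its change points (segment boundaries with a
sign and a positional confidence interval).  Pooled per sign, the CP
intervals are covered by a minimal set of stabbing points; each stabbing
point is a binary feature, giving two features x cells incidence tables.
Feature sharing between two cells is scored by one-sided Fisher's exact
tests (one per sign) whose combined p-value p_c defines the pairwise
dissimilarity ln(p_c).  Hierarchical clustering builds the cell tree; a
row-constrained permutation null yields per-pair FDRs; cohesive branches
with enough widely shared features are called clones, and the procedure
recurses within clones (on the reduced tables) to find subclones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import stats

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_NSHARE_MIN = 3
DEFAULT_SHARE_PCT = 0.8
DEFAULT_MIN_CLONE_SIZE = 3
DEFAULT_HALFWIDTH = 2
DEFAULT_N_PERM = 100
DEFAULT_LINKAGE = "average"
LINKAGES = ("single", "complete", "average", "ward")


@dataclass
class ChangePoint:
    """One change point of one cell: inclusive bin interval and sign."""
    cell_id: str
    lo: int
    hi: int
    sign: int  # +1 gain, -1 loss crossing in increasing coordinate


@dataclass
class IncidenceTables:
    """Two binary feature-by-cell matrices, one per change-point sign."""
    cells: list
    pos_points: np.ndarray  # stabbing points (bin indices), ascending
    neg_points: np.ndarray
    pos: np.ndarray  # (n_pos_features, n_cells) uint8
    neg: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def pooled(self) -> np.ndarray:
        """All feature rows, positive sign first."""
        return np.vstack([self.pos, self.neg]) if self.pos.size or self.neg.size else \
            np.zeros((0, self.n_cells), dtype=np.uint8)

    def restrict(self, cell_idx) -> "IncidenceTables":
        """Columns restricted to ``cell_idx``; constant rows removed."""
        cell_idx = np.asarray(cell_idx)
        out = []
        for mat, pts in ((self.pos, self.pos_points), (self.neg, self.neg_points)):
            sub = mat[:, cell_idx] if mat.size else mat.reshape(0, len(cell_idx))
            rowsum = sub.sum(axis=1)
            keep = (rowsum > 0) & (rowsum < len(cell_idx))
            out.append((sub[keep], pts[keep]))
        return IncidenceTables(cells=[self.cells[i] for i in cell_idx],
                               pos_points=out[0][1], neg_points=out[1][1],
                               pos=out[0][0], neg=out[1][0])


@dataclass
class Clone:
    clone_id: str
    kind: str  # "hard" or "soft"
    cells: list
    node: int  # tree node index


@dataclass
class CloneResult:
    cells: list
    dissimilarity: np.ndarray
    linkage: np.ndarray
    fdr: np.ndarray
    clones: list               # top-level hard and soft clones
    subclones: list            # clones found within clones (ids like "C1.1")
    assignments: pd.DataFrame  # cell_id, clone_id, clone_type, subclone_id
    null_sample: np.ndarray | None = None

    @property
    def hard_clones(self) -> list:
        return [c for c in self.clones if c.kind == "hard"]


# ---------------------------------------------------------------------------
# change points and features

def changepoints_from_cn(cn, chrom, cell_id: str = "cell",
                         halfwidth: int = DEFAULT_HALFWIDTH) -> list[ChangePoint]:
    """Change points of an integer CN vector: one per adjacent unequal
    intra-chromosomal pair, interval +-halfwidth around the right bin."""
    cn = np.asarray(cn)
    chrom = np.asarray(chrom)
    cps = []
    bounds = [0] + [i for i in range(1, cn.size) if chrom[i] != chrom[i - 1]] + [cn.size]
    for ci in range(len(bounds) - 1):
        lo_c, hi_c = bounds[ci], bounds[ci + 1]
        for b in range(lo_c + 1, hi_c):
            if cn[b] != cn[b - 1]:
                cps.append(ChangePoint(
                    cell_id=cell_id, lo=max(lo_c, b - halfwidth),
                    hi=min(hi_c - 1, b + halfwidth),
                    sign=1 if cn[b] > cn[b - 1] else -1))
    return cps


def extract_changepoints(profile, halfwidth: int = DEFAULT_HALFWIDTH) -> list[ChangePoint]:
    """Change points of a quantized, merged CNProfile.

    Uses the segmentation confidence interval carried by the profile when
    present; otherwise +-halfwidth bins around the boundary, clipped to
    the chromosome.
    """
    if getattr(profile, "changepoints", None):
        return [ChangePoint(cell_id=profile.cell_id, lo=cp.ci_lo, hi=cp.ci_hi,
                            sign=cp.sign) for cp in profile.changepoints]
    return changepoints_from_cn(profile.cn, profile.chrom, cell_id=profile.cell_id,
                                halfwidth=halfwidth)


def minimal_stabbing(intervals) -> list[int]:
    """Smallest set of points such that every [lo, hi] interval contains one.

    Greedy: sort by right endpoint ascending; take the right endpoint of
    each interval not yet stabbed.  O(k log k); provably minimal.
    """
    ivs = sorted((int(lo), int(hi)) for lo, hi in intervals)
    for lo, hi in ivs:
        if lo > hi:
            raise ValueError(f"invalid interval [{lo}, {hi}]")
    ivs.sort(key=lambda iv: iv[1])
    points = []
    last = None
    for lo, hi in ivs:
        if last is None or lo > last:
            last = hi
            points.append(hi)
    return points


def build_incidence(changepoints: list[ChangePoint], cells: list) -> IncidenceTables:
    """Reduce all cells' change points to the two incidence tables.

    Stabbing points are computed per sign over the pooled CP intervals;
    entry (feature, cell) is 1 iff some CP of that cell and sign has an
    interval containing the feature's point (a CP interval containing
    several stabbing points marks all of them).
    """
    cell_index = {c: i for i, c in enumerate(cells)}
    mats = {}
    pts = {}
    for sign in (1, -1):
        cps = [cp for cp in changepoints if cp.sign == sign]
        points = np.array(minimal_stabbing([(cp.lo, cp.hi) for cp in cps]), dtype=int)
        points.sort()
        mat = np.zeros((points.size, len(cells)), dtype=np.uint8)
        for cp in cps:
            j = cell_index[cp.cell_id]
            lo = np.searchsorted(points, cp.lo, side="left")
            hi = np.searchsorted(points, cp.hi, side="right")
            mat[lo:hi, j] = 1
        mats[sign], pts[sign] = mat, points
    return IncidenceTables(cells=list(cells), pos_points=pts[1], neg_points=pts[-1],
                           pos=mats[1], neg=mats[-1])


# ---------------------------------------------------------------------------
# dissimilarity, tree, null, FDR

def _sign_pvalues(mat: np.ndarray, table: stats.FisherTailTable | None = None) -> np.ndarray:
    """One-sided Fisher p-values for all cell pairs of one sign's table."""
    n_features, n_cells = mat.shape
    if n_features == 0:
        return np.ones((n_cells, n_cells))
    m = mat.astype(np.int64)
    both = m.T @ m
    n_per_cell = m.sum(axis=0)
    if table is not None:
        p = table.p_greater(both, n_per_cell[:, None], n_per_cell[None, :])
    else:
        p = stats.fisher_exact_greater(
            both, n_per_cell[:, None] - both, n_per_cell[None, :] - both,
            n_features - n_per_cell[:, None] - n_per_cell[None, :] + both)
    return np.asarray(p)


def pair_dissimilarity(tables: IncidenceTables, combine: str = "fisher",
                       _tail_tables=None) -> np.ndarray:
    """Symmetric cells x cells matrix of ln(p_c); diagonal set to 0."""
    if tables.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if _tail_tables is None:
        _tail_tables = (None, None)
    p_pos = _sign_pvalues(tables.pos, _tail_tables[0])
    p_neg = _sign_pvalues(tables.neg, _tail_tables[1])
    d = stats.log_dissimilarity(p_pos, p_neg, combine)
    d = np.asarray(d, dtype=float)
    np.fill_diagonal(d, 0.0)
    return d


def cluster_tree(d: np.ndarray, linkage: str = DEFAULT_LINKAGE) -> np.ndarray:
    """Hierarchical clustering of the dissimilarity matrix.

    Dissimilarities are non-positive; single/complete/average linkage
    heights are shift-equivariant, so clustering runs on the shifted
    matrix and heights are shifted back.  Ward runs on the shifted matrix
    as-is (heights then live on the shifted scale).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    d = np.asarray(d, dtype=float)
    if d.shape[0] < 2:
        raise ValueError("need at least 2 cells to build a tree")
    shift = -stats.LOG_P_FLOOR
    condensed = squareform(d + shift, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    if linkage != "ward":
        z = z.copy()
        z[:, 2] -= shift
    return z


def _row_shuffled(mat: np.ndarray, rng) -> np.ndarray:
    """Independently permute the entries within every row (exact row sums)."""
    if mat.size == 0:
        return mat
    return rng.permuted(mat, axis=1)


def null_distribution(tables: IncidenceTables, n_perm: int = DEFAULT_N_PERM,
                      rng=None, combine: str = "fisher") -> np.ndarray:
    """Pooled null dissimilarities from row-constrained table randomization.

    Every permutation shuffles the entries within each feature row of
    both tables (row marginals preserved exactly, column marginals on
    average), recomputes all pairwise dissimilarities, and contributes
    the off-diagonal values to the pooled sample.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    tails = (_tail_table_for(tables.pos), _tail_table_for(tables.neg))
    iu = np.triu_indices(tables.n_cells, k=1)
    out = []
    for _ in range(n_perm):
        perm = IncidenceTables(cells=tables.cells, pos_points=tables.pos_points,
                               neg_points=tables.neg_points,
                               pos=_row_shuffled(tables.pos, rng),
                               neg=_row_shuffled(tables.neg, rng))
        d = pair_dissimilarity(perm, combine, _tail_tables=tails)
        out.append(d[iu])
    return np.concatenate(out)


_MAX_TABLE_FEATURES = 400


def _tail_table_for(mat: np.ndarray):
    if 0 < mat.shape[0] <= _MAX_TABLE_FEATURES:
        return stats.FisherTailTable(mat.shape[0])
    return None


def pair_fdr(d: np.ndarray, null_sample: np.ndarray) -> np.ndarray:
    """Per-pair FDR of the observed dissimilarities against the null.

    FDR(t) = [fraction of null <= t] / [fraction of observed <= t],
    monotonized so that more negative dissimilarities never receive a
    larger FDR, and capped at 1.
    """
    null_sample = np.sort(np.asarray(null_sample, dtype=float))
    if null_sample.size == 0:
        raise ValueError("null sample is empty")
    n_cells = d.shape[0]
    iu = np.triu_indices(n_cells, k=1)
    obs = d[iu]
    order = np.argsort(obs, kind="stable")
    sorted_obs = obs[order]
    frac_obs = np.searchsorted(sorted_obs, sorted_obs, side="right") / obs.size
    frac_null = np.searchsorted(null_sample, sorted_obs, side="right") / null_sample.size
    raw = frac_null / frac_obs
    q = np.minimum.accumulate(raw[::-1])[::-1]  # min over all t' >= t
    q = np.clip(q, 0.0, 1.0)
    fdr_pairs = np.empty_like(obs)
    fdr_pairs[order] = q
    fdr = np.ones_like(d)
    fdr[iu] = fdr_pairs
    fdr[(iu[1], iu[0])] = fdr_pairs
    np.fill_diagonal(fdr, 0.0)
    return fdr


# ---------------------------------------------------------------------------
# clones

def _tree_nodes(z: np.ndarray, n_leaves: int):
    """Member lists and child pairs for every node (leaves 0..n-1 first)."""
    members = [[i] for i in range(n_leaves)]
    children = [None] * n_leaves
    for i, (a, b, _, _) in enumerate(z):
        a, b = int(a), int(b)
        members.append(members[a] + members[b])
        children.append((a, b))
    parent = [None] * len(members)
    for node, ch in enumerate(children):
        if ch is not None:
            parent[ch[0]] = node
            parent[ch[1]] = node
    return members, children, parent


def _cohesion(z, fdr, members, children, threshold):
    """cohesive[node]: all within-branch pairwise FDR < threshold."""
    n_nodes = len(members)
    cohesive = [True] * n_nodes
    max_fdr = [0.0] * n_nodes
    for node in range(len(children)):
        ch = children[node]
        if ch is None:
            max_fdr[node] = 0.0
            continue
        a, b = ch
        cross = fdr[np.ix_(members[a], members[b])].max()
        max_fdr[node] = max(max_fdr[a], max_fdr[b], float(cross))
        cohesive[node] = max_fdr[node] < threshold
    return cohesive


def _shared_feature_count(pooled: np.ndarray, member_idx, share_pct: float) -> int:
    if pooled.shape[0] == 0:
        return 0
    frac = pooled[:, member_idx].mean(axis=1)
    return int((frac >= share_pct).sum())


def detect_clones(z: np.ndarray, fdr: np.ndarray, tables: IncidenceTables,
                  fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
                  nshare_min: int = DEFAULT_NSHARE_MIN,
                  share_pct: float = DEFAULT_SHARE_PCT,
                  min_clone_size: int = DEFAULT_MIN_CLONE_SIZE,
                  clone_prefix: str = "C") -> list[Clone]:
    """Hard and soft clone calls on the cell tree.

    A branch is cohesive iff every within-branch pair has FDR below
    threshold.  Hard clone: a cohesive branch without a cohesive parent
    that has at least ``nshare_min`` features present in at least
    ``share_pct`` of its cells.  Soft clone: the outermost branch
    satisfying the feature-sharing condition whose parent does not and
    that contains a hard-clonal branch among its descendants.  Clones
    smaller than ``min_clone_size`` cells are suppressed.
    """
    n_leaves = tables.n_cells
    members, children, parent = _tree_nodes(z, n_leaves)
    cohesive = _cohesion(z, fdr, members, children, fdr_threshold)
    pooled = tables.pooled()
    shares = [_shared_feature_count(pooled, m, share_pct) >= nshare_min
              for m in members]

    hard_nodes = []
    for node in range(len(members)):
        if len(members[node]) < min_clone_size:
            continue
        par = parent[node]
        if cohesive[node] and (par is None or not cohesive[par]) and shares[node]:
            hard_nodes.append(node)

    hard_descendant = [False] * len(members)
    for node in range(len(members)):
        if node in hard_nodes:
            hard_descendant[node] = True
        ch = children[node]
        if ch is not None and (hard_descendant[ch[0]] or hard_descendant[ch[1]]):
            hard_descendant[node] = True

    soft_nodes = []
    for node in range(len(members)):
        if node in hard_nodes or len(members[node]) < min_clone_size:
            continue
        par = parent[node]
        ch = children[node]
        contains_hard = ch is not None and (hard_descendant[ch[0]] or hard_descendant[ch[1]])
        if shares[node] and (par is None or not shares[par]) and contains_hard:
            soft_nodes.append(node)

    clones = []
    counter = 1
    for node in sorted(hard_nodes, key=lambda nd: min(members[nd])):
        clones.append(Clone(clone_id=f"{clone_prefix}{counter}", kind="hard",
                            cells=[tables.cells[i] for i in sorted(members[node])],
                            node=node))
        counter += 1
    for node in sorted(soft_nodes, key=lambda nd: min(members[nd])):
        clones.append(Clone(clone_id=f"{clone_prefix}{counter}", kind="soft",
                            cells=[tables.cells[i] for i in sorted(members[node])],
                            node=node))
        counter += 1
    return clones


def detect_subclones(clone: Clone, tables: IncidenceTables, rng=None,
                     combine: str = "fisher", n_perm: int = DEFAULT_N_PERM,
                     linkage: str = DEFAULT_LINKAGE,
                     fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
                     nshare_min: int = DEFAULT_NSHARE_MIN,
                     share_pct: float = DEFAULT_SHARE_PCT,
                     min_clone_size: int = DEFAULT_MIN_CLONE_SIZE) -> list[Clone]:
    """Re-run clone finding within one clone's cells.

    The incidence tables are restricted to the clone's columns, constant
    rows (all 0 or all 1) are removed, and dissimilarity, tree, null and
    FDR are recomputed on the restriction; the resulting hard clones are
    the subclones.
    """
    if len(clone.cells) < 2 * min_clone_size:
        return []
    idx = [tables.cells.index(c) for c in clone.cells]
    sub = tables.restrict(idx)
    if sub.pos.shape[0] == 0 and sub.neg.shape[0] == 0:
        return []
    d = pair_dissimilarity(sub, combine)
    z = cluster_tree(d, linkage)
    null = null_distribution(sub, n_perm=n_perm, rng=rng, combine=combine)
    fdr = pair_fdr(d, null)
    subclones = detect_clones(z, fdr, sub, fdr_threshold=fdr_threshold,
                              nshare_min=nshare_min, share_pct=share_pct,
                              min_clone_size=min_clone_size,
                              clone_prefix=f"{clone.clone_id}.")
    return [Clone(clone_id=c.clone_id, kind="hard", cells=c.cells, node=c.node)
            for c in subclones if c.kind == "hard"]


def clonal_analysis(changepoints: list[ChangePoint], cells: list, rng=None,
                    combine: str = "fisher", linkage: str = DEFAULT_LINKAGE,
                    n_perm: int = DEFAULT_N_PERM,
                    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
                    nshare_min: int = DEFAULT_NSHARE_MIN,
                    share_pct: float = DEFAULT_SHARE_PCT,
                    min_clone_size: int = DEFAULT_MIN_CLONE_SIZE,
                    subclone_recursion: int = 1) -> CloneResult:
    """Full collective analysis: features -> dissimilarity -> tree -> FDR -> clones."""
    if rng is None:
        rng = np.random.default_rng()
    tables = build_incidence(changepoints, cells)
    d = pair_dissimilarity(tables, combine)
    z = cluster_tree(d, linkage)
    null = null_distribution(tables, n_perm=n_perm, rng=rng, combine=combine)
    fdr = pair_fdr(d, null)
    clones = detect_clones(z, fdr, tables, fdr_threshold=fdr_threshold,
                           nshare_min=nshare_min, share_pct=share_pct,
                           min_clone_size=min_clone_size)
    subclones = []
    if subclone_recursion >= 1:
        for clone in clones:
            if clone.kind != "hard":
                continue
            subclones.extend(detect_subclones(
                clone, tables, rng=rng, combine=combine, n_perm=n_perm,
                linkage=linkage, fdr_threshold=fdr_threshold, nshare_min=nshare_min,
                share_pct=share_pct, min_clone_size=min_clone_size))

    assignments = _assignments(cells, clones, subclones)
    return CloneResult(cells=list(cells), dissimilarity=d, linkage=z, fdr=fdr,
                       clones=clones, subclones=subclones,
                       assignments=assignments, null_sample=null)


def _assignments(cells, clones, subclones) -> pd.DataFrame:
    clone_id = {c: None for c in cells}
    clone_type = {c: None for c in cells}
    sub_id = {c: None for c in cells}
    # soft first so hard labels override on overlap (hard nests inside soft)
    for clone in sorted(clones, key=lambda c: c.kind != "soft"):
        for cell in clone.cells:
            clone_id[cell] = clone.clone_id
            clone_type[cell] = clone.kind
    for sc in subclones:
        for cell in sc.cells:
            sub_id[cell] = sc.clone_id
    return pd.DataFrame({
        "cell_id": list(cells),
        "clone_id": [clone_id[c] for c in cells],
        "clone_type": [clone_type[c] for c in cells],
        "subclone_id": [sub_id[c] for c in cells],
    })
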