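"""Joint expression-uptake correlation clustering and candidate ranking.

The central inference step: sugar uptake-rate profiles and transporter
expression profiles, measured across the same induction conditions, are
fused into one matrix of standardized row profiles, clustered hierarchically
with Pearson-correlation distance d = 1 - r, and each sugar's transporter
candidates are ranked by their correlation with the sugar's uptake profile.
A transporter whose expression tracks a sugar's uptake across conditions
co-clusters with that sugar; functional redundancy (several transporters
summing into one uptake profile) and post-transcriptionally regulated
transporters weaken or break this signal, which the ranking report makes
visible rather than hiding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, log_transform, standardize_rows
from .uptake import UptakeRateMatrix

__all__ = [
    "TransformConfig",
    "JointProfile",
    "DissimilarityMatrix",
    "Dendrogram",
    "RankedGene",
    "CandidateRanking",
    "pearson",
    "build_joint_profile",
    "correlation_distance_matrix",
    "average_linkage_cluster",
    "cut_clusters",
    "rank_candidates",
]


def pearson(x, y) -> float:
    """Product-moment correlation; NaN sentinel when either profile is constant.

    A constant profile has zero variance, so r is undefined; callers flag
    such rows instead of dropping them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pearson: length mismatch")
    if x.size < 3:
        raise ValueError("pearson: need >= 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(dx @ dy) / (sx * sy)
    return float(min(1.0, max(-1.0, r)))


@dataclass(frozen=True)
class TransformConfig:
    """Pre-clustering transforms applied to each block (uptake, expression)."""

    log2: bool = True
    pseudocount: float = 1.0
    normalize: str = "zscore"  # {"zscore", "none"}

    def apply(self, m: ExpressionMatrix) -> ExpressionMatrix:
        if self.log2:
            m = log_transform(m, self.pseudocount)
        if self.normalize == "zscore":
            m = standardize_rows(m)
        elif self.normalize != "none":
            raise ValueError(f"unknown normalize option {self.normalize!r}")
        return m


@dataclass(frozen=True)
class JointProfile:
    """Fused sugar + gene profile matrix over shared conditions.

    Row labels carry a role tag; ``tagged_labels`` ("sugar:lactose",
    "gene:cdt-1") are the unique row identifiers used by the dendrogram.
    """

    labels: tuple[str, ...]
    roles: tuple[str, ...]  # "sugar" | "gene" per row
    conditions: tuple[str, ...]
    values: np.ndarray
    constant_rows: frozenset[str] = field(default_factory=frozenset)  # tagged

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.roles) or self.values.shape != (
            len(self.labels),
            len(self.conditions),
        ):
            raise ValueError("joint profile shape mismatch")
        if len(set(self.tagged_labels)) != len(self.labels):
            raise ValueError("duplicate row labels after role tagging")

    @property
    def tagged_labels(self) -> tuple[str, ...]:
        return tuple(f"{role}:{lab}" for role, lab in zip(self.roles, self.labels))

    def row(self, tagged: str) -> np.ndarray:
        return self.values[self.tagged_labels.index(tagged)]

    @property
    def sugars(self) -> tuple[str, ...]:
        return tuple(l for l, r in zip(self.labels, self.roles) if r == "sugar")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(l for l, r in zip(self.labels, self.roles) if r == "gene")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.tagged_labels), columns=list(self.conditions)
        )


def build_joint_profile(
    uptake: UptakeRateMatrix,
    expr: ExpressionMatrix,
    config: TransformConfig = TransformConfig(),
) -> JointProfile:
    """Restrict both matrices to shared conditions, transform, concatenate.

    Condition order follows the uptake matrix.  Both blocks pass through the
    same log / z-score transforms independently, so a sugar row identical to
    a gene row stays identical after the transform.
    """
    shared = [c for c in uptake.conditions if c in set(expr.conditions)]
    if len(shared) < 3:
        raise ValueError(
            "need >= 3 shared conditions; uptake has "
            f"{uptake.conditions}, expression has {expr.conditions}"
        )
    urows = uptake.rates.loc[:, shared]
    if urows.isna().any().any():
        missing = [
            (s, c) for s in urows.index for c in shared if pd.isna(urows.loc[s, c])
        ]
        raise ValueError(f"uptake matrix has missing cells on shared conditions: {missing}")
    ublock = config.apply(ExpressionMatrix(urows.astype(float)))
    eblock = config.apply(ExpressionMatrix(expr.data.loc[:, shared].astype(float)))
    labels = tuple(ublock.genes) + tuple(eblock.genes)
    roles = ("sugar",) * len(ublock.genes) + ("gene",) * len(eblock.genes)
    values = np.vstack([ublock.values, eblock.values])
    constant = frozenset(f"sugar:{s}" for s in ublock.constant_rows) | frozenset(
        f"gene:{g}" for g in eblock.constant_rows
    )
    return JointProfile(labels, roles, tuple(shared), values, constant)


@dataclass(frozen=True)
class DissimilarityMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray
    flagged_pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("dissimilarity shape mismatch")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("dissimilarity must be symmetric with zero diagonal")


def correlation_distance_matrix(jp: JointProfile) -> DissimilarityMatrix:
    """d(i,j) = 1 - r(i,j), in [0, 2]; constant rows get d = 1 (r := 0), flagged."""
    n = len(jp.labels)
    tagged = jp.tagged_labels
    d = np.zeros((n, n))
    flagged: set[tuple[str, str]] = set()
    const = [t in jp.constant_rows or np.ptp(jp.values[i]) == 0 for i, t in enumerate(tagged)]
    for i in range(n):
        for j in range(i + 1, n):
            if const[i] or const[j]:
                dij = 1.0
                flagged.add((tagged[i], tagged[j]))
            else:
                dij = 1.0 - pearson(jp.values[i], jp.values[j])
            d[i, j] = d[j, i] = dij
    return DissimilarityMatrix(tagged, d, frozenset(flagged))


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree.

    Cluster ids follow the scipy convention: leaves are 0..n-1 in input
    order, the cluster created by merge i is id n+i.  ``merges`` lists
    (id_a, id_b, height) with id_a < id_b and nondecreasing heights.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError("dendrogram must have n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("non-monotone merge heights")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def members(self, cid: int) -> list[int]:
        """Leaf indices under cluster ``cid``, in dendrogram display order."""
        n = self.n_leaves
        if cid < n:
            return [cid]
        a, b, _ = self.merges[cid - n]
        return self.members(a) + self.members(b)

    @property
    def leaf_order(self) -> list[int]:
        return self.members(self.n_leaves + len(self.merges) - 1)

    def to_linkage(self) -> np.ndarray:
        """scipy.cluster.hierarchy-compatible linkage matrix."""
        sizes = {i: 1 for i in range(self.n_leaves)}
        rows = []
        for k, (a, b, h) in enumerate(self.merges):
            sizes[self.n_leaves + k] = sizes[a] + sizes[b]
            rows.append([a, b, h, sizes[self.n_leaves + k]])
        return np.asarray(rows, dtype=float)

    def to_newick(self) -> str:
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}

        def node(cid: int) -> str:
            if cid < n:
                return self.labels[cid].replace(" ", "_")
            a, b, h = self.merges[cid - n]
            heights[cid] = h
            parts = ",".join(
                f"{node(c)}:{max(h - heights[c], 0.0):.6g}" for c in (a, b)
            )
            return f"({parts})"

        return node(n + len(self.merges) - 1) + ";"


def average_linkage_cluster(
    d: DissimilarityMatrix, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering with deterministic smallest-index tie-break.

    ``average`` (UPGMA) defines the inter-cluster distance as the unweighted
    mean over all cross pairs of the original dissimilarities; it is
    computed from exact cross-pair sums, so merging is associative and the
    result matches a brute-force re-scan.  ``complete`` and ``single`` are
    provided as alternatives.  Ties in the minimum distance are broken by
    the lexicographically smallest (id_a, id_b) pair, making the output
    platform-independent.
    """
    if linkage not in {"average", "complete", "single"}:
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(d.labels)
    if n < 2:
        raise ValueError("need >= 2 items to cluster")
    stat = d.matrix.astype(float).copy()  # cross-pair sums (average) or min/max
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    pos = {i: i for i in range(n)}  # id -> row in stat
    active = list(range(n))  # ids, ascending (creation order)
    merges: list[tuple[int, int, float]] = []
    last_h = 0.0
    while len(active) > 1:
        best = None  # (height, id_a, id_b)
        for ia in range(len(active)):
            for ib in range(ia + 1, len(active)):
                a, b = active[ia], active[ib]
                s = stat[pos[a], pos[b]]
                h = s / (sizes[a] * sizes[b]) if linkage == "average" else s
                cand = (h, a, b)
                if best is None or cand < best:
                    best = cand
        h, a, b = best
        h = max(h, last_h)  # guard fp jitter; average linkage is monotone
        last_h = h
        new = n + len(merges)
        merges.append((a, b, float(h)))
        # fold b's row into a's row, reuse a's slot for the new cluster
        pa, pb = pos[a], pos[b]
        if linkage == "average":
            stat[pa, :] = stat[pa, :] + stat[pb, :]
        elif linkage == "complete":
            stat[pa, :] = np.maximum(stat[pa, :], stat[pb, :])
        else:
            stat[pa, :] = np.minimum(stat[pa, :], stat[pb, :])
        stat[:, pa] = stat[pa, :]
        sizes[new] = sizes[a] + sizes[b]
        pos[new] = pa
        active.remove(a)
        active.remove(b)
        active.append(new)
    return Dendrogram(tuple(d.labels), tuple(merges))


def cut_clusters(
    dend: Dendrogram, k: int | None = None, height: float | None = None
) -> dict[str, int]:
    """Cut the dendrogram into flat clusters.

    Exactly one of ``k`` (number of clusters) or ``height`` (merge-height
    threshold; merges at height <= threshold are applied) may be given.
    Cluster ids are 1-based, ordered by each cluster's first leaf in the
    dendrogram display order (top-to-bottom in a heatmap).
    """
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    n = dend.n_leaves
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        applied = dend.merges[: n - k]
    else:
        if height < 0:
            raise ValueError("height must be >= 0")
        applied = tuple(m for m in dend.merges if m[2] <= height)
    parent = {}

    def find(x: int) -> int:
        while x in parent:
            x = parent[x]
        return x

    for idx, (a, b, _) in enumerate(applied):
        # merges must be applied as a prefix for k-cuts; height cuts on a
        # monotone dendrogram select a prefix too
        parent[a] = parent[b] = n + idx
    order = dend.leaf_order
    cluster_of_leaf = {leaf: find(leaf) for leaf in range(n)}
    cluster_id: dict[int, int] = {}
    for leaf in order:
        root = cluster_of_leaf[leaf]
        if root not in cluster_id:
            cluster_id[root] = len(cluster_id) + 1
    return {dend.labels[leaf]: cluster_id[cluster_of_leaf[leaf]] for leaf in range(n)}


@dataclass(frozen=True)
class RankedGene:
    gene: str
    pearson_r: float  # NaN for constant profiles
    distance: float
    same_cluster: bool
    rank: int


@dataclass(frozen=True)
class CandidateRanking:
    sugar: str
    entries: tuple[RankedGene, ...]

    @property
    def top(self) -> RankedGene:
        return self.entries[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    sugar=self.sugar,
                    gene=e.gene,
                    pearson_r=e.pearson_r,
                    distance=e.distance,
                    same_cluster=e.same_cluster,
                    rank=e.rank,
                )
                for e in self.entries
            ]
        )


def rank_candidates(
    jp: JointProfile, dend: Dendrogram, k: int = 5
) -> list[CandidateRanking]:
    """Per-sugar transporter ranking by Pearson r with the uptake profile.

    Genes are sorted by descending r; genes with undefined r (constant
    expression across the tested conditions) keep the NaN sentinel and sink
    to the bottom.  ``same_cluster`` reports co-membership at the k-cluster
    cut — the visual criterion of the heatmap analysis.
    """
    if not jp.sugars or not jp.genes:
        raise ValueError("joint profile needs >= 1 sugar row and >= 1 gene row")
    assignment = cut_clusters(dend, k=k)
    tagged = jp.tagged_labels
    rankings = []
    for sugar in jp.sugars:
        srow = jp.row(f"sugar:{sugar}")
        s_const = f"sugar:{sugar}" in jp.constant_rows
        scored = []
        for gi, gene in enumerate(jp.genes):
            gt = f"gene:{gene}"
            if s_const or gt in jp.constant_rows:
                r = float("nan")
            else:
                r = pearson(srow, jp.row(gt))
            dist = 1.0 if math.isnan(r) else 1.0 - r
            same = assignment[f"sugar:{sugar}"] == assignment[gt]
            sort_key = (-r if not math.isnan(r) else float("inf"), gi)
            scored.append((sort_key, gene, r, dist, same))
        scored.sort(key=lambda t: t[0])
        entries = tuple(
            RankedGene(gene, r, dist, same, rank)
            for rank, (_, gene, r, dist, same) in enumerate(scored, start=1)
        )
        rankings.append(CandidateRanking(sugar, entries))
    return rankings
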