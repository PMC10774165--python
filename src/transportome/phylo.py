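"""Distance-based phylogenetics for transporter protein families.

Implements the classical workflow used to place uncharacterized transporters
among characterized relatives: Poisson-corrected amino-acid distances with
pairwise deletion of gaps, Saitou-Nei neighbor joining, nonparametric
bootstrap support on the bipartitions of the NJ tree, and a rule-based
clade assignment of query sequences from a reference labelling.

Distances and NJ are implemented here (they are the numerical substance the
downstream clade calls depend on); tree storage and Newick serialisation
delegate to dendropy, and aligned-FASTA I/O to Biopython.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "PhyloDistanceMatrix",
    "PhyloTree",
    "poisson_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "assign_clades",
    "tree_distance_matrix",
]

MISSING_CHARS = frozenset("-X.")


@dataclass(frozen=True)
class Alignment:
    """Aligned amino-acid sequences ('-' gaps, 'X' unknown residues)."""

    names: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names / sequences length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        object.__setattr__(
            self, "sequences", tuple(s.upper() for s in self.sequences)
        )

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_array(self) -> np.ndarray:
        """(n_seq, n_sites) byte matrix for vectorised distance computation."""
        return np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype="S1"
        ).reshape(self.n_sequences, self.n_sites)

    def resample_columns(self, columns) -> "Alignment":
        arr = self.to_array()[:, np.asarray(columns, dtype=int)]
        seqs = tuple(bytes(row).decode("ascii") for row in arr)
        return Alignment(self.names, seqs)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(
            tuple(r.id for r in records), tuple(str(r.seq) for r in records)
        )

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=n, description="")
            for n, s in zip(self.names, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")


def poisson_distance(
    a: str, b: str, p_cap: float = 0.99
) -> tuple[float, int, bool]:
    """Poisson-corrected distance d = -ln(1 - p) with pairwise deletion.

    Sites where either sequence has a gap ('-') or unknown residue ('X')
    are excluded for this pair only.  p is the proportion of differing
    residues among the compared sites.  Saturated pairs (p >= p_cap) are
    capped at -ln(1 - p_cap) and flagged, since the correction diverges.

    Returns (distance, n_sites_compared, capped).
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal (aligned) length")
    aa = np.frombuffer(a.upper().encode("ascii"), dtype="S1")
    bb = np.frombuffer(b.upper().encode("ascii"), dtype="S1")
    missing = np.zeros(aa.shape, dtype=bool)
    for ch in MISSING_CHARS:
        cb = ch.encode("ascii")
        missing |= (aa == cb) | (bb == cb)
    valid = ~missing
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no overlapping sites (all-gap pair)")
    p = float(((aa != bb) & valid).sum()) / n
    capped = p >= p_cap
    if capped:
        p = p_cap
    return float(-np.log1p(-p)), n, capped


@dataclass(frozen=True)
class PhyloDistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray
    n_sites: np.ndarray | None = None  # compared sites per pair
    cap_flags: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        m = self.matrix
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(m)):
            raise ValueError("distance matrix must be finite")


def distance_matrix(aln: Alignment, p_cap: float = 0.99) -> PhyloDistanceMatrix:
    """All-pairs Poisson-corrected distances with pairwise deletion."""
    if aln.n_sequences < 2:
        raise ValueError("need >= 2 sequences")
    arr = aln.to_array()
    missing = np.zeros(arr.shape, dtype=bool)
    for ch in MISSING_CHARS:
        missing |= arr == ch.encode("ascii")
    n = aln.n_sequences
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    caps: set[tuple[str, str]] = set()
    for i in range(n):
        sites[i, i] = int((~missing[i]).sum())
        for j in range(i + 1, n):
            valid = ~(missing[i] | missing[j])
            nv = int(valid.sum())
            if nv == 0:
                raise ValueError(
                    f"no overlapping sites for pair ({aln.names[i]}, {aln.names[j]})"
                )
            p = float(((arr[i] != arr[j]) & valid).sum()) / nv
            if p >= p_cap:
                p = p_cap
                caps.add((aln.names[i], aln.names[j]))
            d[i, j] = d[j, i] = -np.log1p(-p)
            sites[i, j] = sites[j, i] = nv
    return PhyloDistanceMatrix(tuple(aln.names), d, sites, frozenset(caps))


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths; wraps a dendropy Tree.

    ``supports`` maps canonical bipartitions (the leaf-name side not
    containing the alphabetically first leaf) to bootstrap support in
    [0, 1]; it is populated by :func:`bootstrap_support`.
    """

    tree: dendropy.Tree
    n_negative_clamped: int = 0
    supports: dict[frozenset, float] | None = None

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )

    def bipartitions(self) -> dict[frozenset, float]:
        """Non-trivial bipartitions -> subtending branch length.

        Each internal edge splits the leaves in two; the canonical key is
        the frozenset of names on the side *not* containing the anchor
        (alphabetically first) leaf.  Trivial splits (one leaf) excluded.
        """
        names = set(self.leaf_names)
        anchor = min(names)
        out: dict[frozenset, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if anchor in side:
                side = frozenset(names - side)
            if 2 <= len(side) <= len(names) - 2:
                out[side] = float(node.edge.length or 0.0)
        return out

    def to_newick(self) -> str:
        if self.supports is not None:
            names = set(self.leaf_names)
            anchor = min(names)
            for node in self.tree.preorder_node_iter():
                if node.parent_node is None or node.is_leaf():
                    continue
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                if anchor in side:
                    side = frozenset(names - side)
                if side in self.supports:
                    node.label = f"{self.supports[side]:.4g}"
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
        )

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, source: str, is_path: bool = False) -> "PhyloTree":
        kwargs = dict(
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        if is_path:
            tree = dendropy.Tree.get(path=str(source), **kwargs)
        else:
            tree = dendropy.Tree.get(data=source, **kwargs)
        tree.is_rooted = False
        pt = cls(tree)
        # recover supports stored as internal node labels, if any
        supports: dict[frozenset, float] = {}
        names = set(pt.leaf_names)
        anchor = min(names)
        for node in tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf() or node.label is None:
                continue
            try:
                sup = float(node.label)
            except ValueError:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if anchor in side:
                side = frozenset(names - side)
            if 2 <= len(side) <= len(names) - 2:
                supports[side] = sup
        if supports:
            pt.supports = supports
        return pt


def tree_distance_matrix(tree: PhyloTree) -> PhyloDistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances of a tree.

    On a tree these are additive by construction, so running
    :func:`neighbor_joining` on them must reproduce the tree.
    """
    pdm = tree.tree.phylogenetic_distance_matrix()
    labels = tuple(sorted(tree.leaf_names))
    taxa = {t.label: t for t in tree.tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float(pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]]))
    return PhyloDistanceMatrix(labels, d)


def neighbor_joining(dm: PhyloDistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; consistent on additive distances.

    At each step the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j
    (r_i = sum_k d(i,k)) is joined; ties in Q are broken by the smallest
    (i, j) pair in node-creation order, for bit-reproducible output.
    Negative branch-length estimates are clamped to zero and counted.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    taxa = dendropy.TaxonNamespace([str(l) for l in dm.labels])
    tree = dendropy.Tree(taxon_namespace=taxa)
    clamped = 0

    def _len(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return float(x)

    nodes = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(str(label)))
        nodes.append(node)
    if n == 2:
        root = dendropy.Node()
        half = float(dm.matrix[0, 1]) / 2.0
        for node in nodes:
            root.add_child(node)
            node.edge.length = _len(half)
        tree.seed_node = root
        tree.is_rooted = False
        return PhyloTree(tree, clamped)

    d = dm.matrix.astype(float).copy()
    active = list(range(n))  # indices into d / nodes, ascending creation order
    pos_nodes = {i: nodes[i] for i in range(n)}
    next_id = n
    # grow d as needed
    size = 2 * n
    full = np.zeros((size, size))
    full[:n, :n] = d
    pos = {i: i for i in range(n)}
    slot = n

    while len(active) > 3:
        m = len(active)
        idx = [pos[a] for a in active]
        sub = full[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        best = None
        for ia in range(m):
            for ib in range(ia + 1, m):
                cand = (q[ia, ib], active[ia], active[ib])
                if best is None or cand < best:
                    best = cand
        _, a, b = best
        ia, ib = active.index(a), active.index(b)
        dab = sub[ia, ib]
        la = 0.5 * dab + (r[ia] - r[ib]) / (2 * (m - 2))
        lb = dab - la
        parent = dendropy.Node()
        parent.add_child(pos_nodes[a])
        pos_nodes[a].edge.length = _len(la)
        parent.add_child(pos_nodes[b])
        pos_nodes[b].edge.length = _len(lb)
        # distances from the new node to every other active node
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (full[pos[a], pos[c]] + full[pos[b], pos[c]] - dab)
            full[slot, pos[c]] = full[pos[c], slot] = dc
        pos[next_id] = slot
        pos_nodes[next_id] = parent
        slot += 1
        active.remove(a)
        active.remove(b)
        active.append(next_id)
        next_id += 1

    # final three-way join
    a, b, c = active
    dab = full[pos[a], pos[b]]
    dac = full[pos[a], pos[c]]
    dbc = full[pos[b], pos[c]]
    root = dendropy.Node()
    for x, lx in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        root.add_child(pos_nodes[x])
        pos_nodes[x].edge.length = _len(lx)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree, clamped)


def bootstrap_support(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    p_cap: float = 0.99,
) -> PhyloTree:
    """Nonparametric bootstrap support for the NJ tree of ``aln``.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    replicate's NJ tree contributes its bipartitions.  The support of each
    internal edge of the original tree is the fraction of usable replicates
    containing the same leaf-set split.  Replicates in which some pair has
    no overlapping (non-gap) sites are skipped with a warning and removed
    from the denominator.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    original = neighbor_joining(distance_matrix(aln, p_cap=p_cap))
    target = set(original.bipartitions())
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_sites, size=aln.n_sites)
        rep = aln.resample_columns(cols)
        try:
            rep_tree = neighbor_joining(distance_matrix(rep, p_cap=p_cap))
        except ValueError as exc:
            warnings.warn(f"bootstrap replicate skipped: {exc}")
            continue
        used += 1
        rep_bps = set(rep_tree.bipartitions())
        for bp in target & rep_bps:
            counts[bp] += 1
    if used == 0:
        raise ValueError("all bootstrap replicates failed")
    original.supports = {bp: counts[bp] / used for bp in target}
    return original


def assign_clades(
    tree: PhyloTree,
    reference_labels: dict[str, str],
    support_threshold: float = 0.5,
    queries: list[str] | None = None,
) -> dict[str, str]:
    """Assign query leaves to reference clades, or "unplaced".

    A query is assigned to clade X iff it sits inside the smallest subtree
    (bipartition side) that contains every reference member of clade X, no
    reference member of any other clade, and whose subtending edge has
    bootstrap support >= ``support_threshold`` (edges without a support
    value count as fully supported).  Queries on the backbone between
    clades, or inside mixed subtrees, come back "unplaced" — the honest
    answer for sequences that fall outside the recognised families.
    """
    leaves = set(tree.leaf_names)
    refs = {k: v for k, v in reference_labels.items() if k in leaves}
    clades = set(refs.values())
    if len(clades) < 2:
        raise ValueError("reference labels must cover >= 2 clades")
    if queries is None:
        queries = sorted(leaves - set(refs))
    else:
        collisions = set(queries) & set(refs)
        if collisions:
            raise ValueError(f"query names collide with reference names: {sorted(collisions)}")
        queries = sorted(queries)
    members = {cl: {n for n, c in refs.items() if c == cl} for cl in clades}
    bps = tree.bipartitions()
    supports = tree.supports or {}

    def sides() -> list[frozenset]:
        out = []
        for bp in bps:
            sup = supports.get(bp, 1.0)
            if sup < support_threshold:
                continue
            out.append(bp)
            out.append(frozenset(leaves - bp))
        # leaf edges: the one-leaf side lets a singleton clade resolve to the
        # leaf itself; the complement side matters when one clade's members
        # are everything-but-one-leaf.  Trivial splits always have support 1.
        for leaf in leaves:
            out.append(frozenset([leaf]))
            out.append(frozenset(leaves - {leaf}))
        return out

    best_side: dict[str, frozenset | None] = {}
    for cl in clades:
        candidates = [
            s
            for s in sides()
            if members[cl] <= s and not any(members[o] & s for o in clades - {cl})
        ]
        best_side[cl] = min(candidates, key=len) if candidates else None

    out: dict[str, str] = {}
    for q in queries:
        hit = [cl for cl in sorted(clades) if best_side[cl] and q in best_side[cl]]
        out[q] = hit[0] if hit else "unplaced"
    return out
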