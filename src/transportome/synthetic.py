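"""Synthetic transportome simulator.

Generates every input of the pipeline — transporter expression matrices,
sugar depletion assays, aligned protein sequences, and qPCR Ct tables —
with the statistical structure the analysis assumes, so each stage and the
end-to-end inference can be tested without external data.

The generative model for uptake is strictly additive: when several
transporters carry the same sugar, the observed uptake rate is the sum of
the individual transporters' rates.  Each transporter contributes its
activity (transport capacity per expression unit) times its condition
activity, which equals its expression for transcriptionally coupled
transporters and a constant for decoupled ones — the minimal model of a
post-transcriptionally regulated transporter whose activity ignores its
own transcript level.  Expression is a condition snapshot: basal level,
times a fold-induction on inducing conditions, times a carbon-catabolite
repression (CCR) factor on the repressing condition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, QpcrTable
from .phylo import Alignment, PhyloTree
from .uptake import DEPLETED, UptakeAssay, UptakeRateMatrix

__all__ = [
    "TransportomeSpec",
    "SimulatedTruth",
    "simulate_transportome",
    "simulate_uptake_assays",
    "simulate_alignment",
    "simulate_qpcr",
    "random_tree",
    "neurospora_like",
    "dedicated_transporters",
    "redundant_pair",
    "DEFAULT_CONDITIONS",
    "DEFAULT_SUGARS",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# 15 induction conditions: starvation control, a CCR-triggering preferred
# sugar, monosaccharide inducers, and polysaccharides.
DEFAULT_CONDITIONS = (
    "no_carbon",
    "sucrose",
    "glucose",
    "galactose",
    "galacturonic_acid",
    "mannose",
    "xylose",
    "arabinose",
    "rhamnose",
    "cellulose",
    "glucomannan",
    "pectin",
    "xylan",
    "arabinan",
    "polygalacturonic_acid",
)

# the ten assayed sugars
DEFAULT_SUGARS = (
    "glucose",
    "galactose",
    "galacturonic_acid",
    "mannose",
    "xylose",
    "arabinose",
    "rhamnose",
    "cellobiose",
    "lactose",
    "mannobiose",
)


@dataclass(frozen=True)
class TransportomeSpec:
    """Ground-truth description of a simulated sugar transportome.

    ``activity[t, s]`` is transporter t's capacity for sugar s in
    nmol min^-1 mg^-1 per expression unit; ``induction`` maps a transporter
    index to {condition: fold}.  ``decoupled`` transporters have constant
    activity (their expression is ignored for uptake); ``constitutive``
    transporters have induction-independent expression.  ``ccr_condition``
    names the repressing condition, where every transporter not in
    ``ccr_exempt`` is multiplied by ``ccr_factor``.
    """

    n_transporters: int = 44
    n_sugars: int = 10
    condition_labels: tuple[str, ...] = DEFAULT_CONDITIONS
    sugar_names: tuple[str, ...] = DEFAULT_SUGARS
    transporter_names: tuple[str, ...] = ()
    activity: np.ndarray | None = None
    induction: dict[int, dict[str, float]] = field(default_factory=dict)
    basal_expression: np.ndarray | None = None
    ccr_condition: str | None = "sucrose"
    ccr_factor: float = 0.2
    ccr_exempt: frozenset[int] = frozenset()
    decoupled: frozenset[int] = frozenset()
    constitutive: frozenset[int] = frozenset()
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transporters < 1 or self.n_sugars < 1:
            raise ValueError("n_transporters and n_sugars must be positive")
        if not self.transporter_names:
            names = tuple(f"stp-{i + 1:02d}" for i in range(self.n_transporters))
            object.__setattr__(self, "transporter_names", names)
        if len(self.transporter_names) != self.n_transporters:
            raise ValueError("transporter_names length mismatch")
        if len(self.sugar_names) != self.n_sugars:
            raise ValueError("sugar_names length mismatch")
        if self.activity is None:
            object.__setattr__(
                self, "activity", np.zeros((self.n_transporters, self.n_sugars))
            )
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.shape != (self.n_transporters, self.n_sugars):
            raise ValueError("activity matrix shape mismatch")
        if np.any(act < 0):
            raise ValueError("activity must be nonnegative")
        if self.basal_expression is None:
            object.__setattr__(
                self, "basal_expression", np.ones(self.n_transporters)
            )
        basal = np.asarray(self.basal_expression, dtype=float)
        object.__setattr__(self, "basal_expression", basal)
        if basal.shape != (self.n_transporters,) or np.any(basal <= 0):
            raise ValueError("basal_expression must be positive per transporter")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        idx = set(range(self.n_transporters))
        if not (set(self.decoupled) <= idx and set(self.constitutive) <= idx):
            raise ValueError("decoupled/constitutive indices out of range")
        if self.ccr_condition is not None and self.ccr_condition not in self.condition_labels:
            raise ValueError(f"ccr_condition {self.ccr_condition!r} not in condition_labels")
        if not 0 < self.ccr_factor <= 1:
            raise ValueError("ccr_factor must be in (0, 1]")
        for t, folds in self.induction.items():
            if t not in idx:
                raise ValueError(f"induction index {t} out of range")
            unknown = set(folds) - set(self.condition_labels)
            if unknown:
                raise ValueError(f"unknown induction conditions: {sorted(unknown)}")


@dataclass(frozen=True)
class SimulatedTruth:
    """Simulator output: expression, true and observed uptake, assignment."""

    spec: TransportomeSpec
    expression: ExpressionMatrix
    uptake_true: UptakeRateMatrix
    uptake_observed: UptakeRateMatrix
    assignment: dict[str, dict[str, float]]  # sugar -> transporter -> share

    def assignment_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.assignment, fh, indent=1, sort_keys=True)

    def dominant_transporter(self, sugar: str) -> str:
        shares = self.assignment[sugar]
        return max(sorted(shares), key=lambda t: shares[t])


def _expression_values(spec: TransportomeSpec) -> np.ndarray:
    nt, nc = spec.n_transporters, len(spec.condition_labels)
    e = np.tile(spec.basal_expression[:, None], (1, nc))
    cidx = {c: i for i, c in enumerate(spec.condition_labels)}
    for t, folds in spec.induction.items():
        if t in spec.constitutive:
            continue
        for cond, fold in folds.items():
            e[t, cidx[cond]] *= fold
    if spec.ccr_condition is not None:
        j = cidx[spec.ccr_condition]
        for t in range(nt):
            if t not in spec.ccr_exempt:
                e[t, j] *= spec.ccr_factor
    return e


def simulate_transportome(spec: TransportomeSpec) -> SimulatedTruth:
    """Build expression, noise-free and noisy uptake, and the true assignment.

    uptake_true(s, c) = sum_t activity[t, s] * act(t, c), with act = the
    expression value for coupled transporters and the basal level (a
    constant) for decoupled ones.  Observed uptake multiplies each cell by
    an independent mean-1 lognormal factor with coefficient of variation
    ``noise_cv``.  Deterministic given ``spec.seed``.
    """
    orphan = np.flatnonzero(spec.activity.sum(axis=0) == 0)
    if orphan.size:
        names = [spec.sugar_names[i] for i in orphan]
        raise ValueError(f"orphan sugar has no transporter: {names}")
    expr = _expression_values(spec)
    act = expr.copy()
    for t in spec.decoupled:
        act[t, :] = spec.basal_expression[t]
    uptake = spec.activity.T @ act  # (n_sugars, n_conditions)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_cv > 0:
        sigma = math.sqrt(math.log1p(spec.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=uptake.shape)
    else:
        noise = np.ones_like(uptake)
    observed = uptake * noise

    mean_act = act.mean(axis=1)
    assignment: dict[str, dict[str, float]] = {}
    for s, sugar in enumerate(spec.sugar_names):
        contrib = spec.activity[:, s] * mean_act
        total = contrib.sum()
        assignment[sugar] = {
            spec.transporter_names[t]: float(contrib[t] / total)
            for t in np.flatnonzero(contrib > 0)
        }

    conds = list(spec.condition_labels)
    ones = pd.DataFrame(1, index=list(spec.sugar_names), columns=conds, dtype=int)
    return SimulatedTruth(
        spec=spec,
        expression=ExpressionMatrix.from_arrays(
            spec.transporter_names, conds, expr
        ),
        uptake_true=UptakeRateMatrix(
            pd.DataFrame(uptake, index=list(spec.sugar_names), columns=conds), ones
        ),
        uptake_observed=UptakeRateMatrix(
            pd.DataFrame(observed, index=list(spec.sugar_names), columns=conds),
            ones.copy(),
        ),
        assignment=assignment,
    )


def simulate_uptake_assays(
    truth: SimulatedTruth,
    volume_L: float = 0.003,
    biomass_mg: float = 2.0,
    c0_uM: float = 100.0,
    n_replicates: int = 3,
    seed: int = 0,
    noise_cv: float = 0.0,
    t_end_min: float = 15.0,
) -> list[UptakeAssay]:
    """Forward-simulate two-point depletion assays from the true rates.

    C(t_end) = C(0) - rate * t_end * DW / (V * 1000), in uM.  Replicate
    noise is multiplicative lognormal on the rate (``noise_cv = 0`` gives
    assays whose two-point reduction recovers the true rates exactly).
    Implied negative concentrations are clamped to 0 and the assay flagged
    "depleted".
    """
    if volume_L <= 0 or biomass_mg <= 0 or c0_uM <= 0:
        raise ValueError("volume, biomass and c0 must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    assays = []
    for sugar in truth.uptake_true.sugars:
        for cond in truth.uptake_true.conditions:
            rate = float(truth.uptake_true.rates.loc[sugar, cond])
            for rep in range(1, n_replicates + 1):
                r = rate
                if sigma > 0:
                    r *= float(rng.lognormal(-0.5 * sigma**2, sigma))
                c_end = c0_uM - r * t_end_min * biomass_mg / (volume_L * 1000.0)
                flags: frozenset[str] = frozenset()
                if c_end < 0:
                    c_end = 0.0
                    flags = frozenset([DEPLETED])
                assays.append(
                    UptakeAssay(
                        sugar=sugar,
                        condition=cond,
                        replicate=rep,
                        volume_L=volume_L,
                        biomass_mg=biomass_mg,
                        time_min=(0.0, t_end_min),
                        conc_uM=(c0_uM, c_end),
                        flags=flags,
                    )
                )
    return assays


def simulate_alignment(
    tree: "PhyloTree | dendropy.Tree | str",
    n_sites: int,
    seed: int = 0,
    gap_fraction: float = 0.0,
) -> Alignment:
    """Evolve i.i.d. sites under the equal-rate 20-state amino-acid model.

    Branch lengths are expected substitutions per site.  Along a branch of
    length b the probability that a site's state is unchanged is
    1/20 + (19/20) exp(-20 b / 19), otherwise it moves uniformly to one of
    the 19 other residues; the expected observed p-distance between two
    leaves at path length b is therefore (19/20)(1 - exp(-20 b / 19)).
    Optional gaps are inserted uniformly at random per sequence.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be positive")
    if isinstance(tree, PhyloTree):
        dtree = tree.tree
    elif isinstance(tree, dendropy.Tree):
        dtree = tree
    else:
        dtree = dendropy.Tree.get(data=str(tree), schema="newick")
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {}
    leaf_seqs: dict[str, np.ndarray] = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            state = rng.integers(0, 20, size=n_sites)
        else:
            b = float(node.edge.length or 0.0)
            parent = states[id(node.parent_node)]
            p_same = 1.0 / 20.0 + (19.0 / 20.0) * math.exp(-20.0 * b / 19.0)
            change = rng.random(n_sites) >= p_same
            state = parent.copy()
            if change.any():
                # uniform over the 19 non-parent states
                shift = rng.integers(1, 20, size=int(change.sum()))
                state[change] = (parent[change] + shift) % 20
        states[id(node)] = state
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = state
    alpha = np.frombuffer(AA_ALPHABET.encode("ascii"), dtype="S1")
    names = sorted(leaf_seqs)
    seqs = []
    for name in names:
        chars = alpha[leaf_seqs[name]].copy()
        if gap_fraction > 0:
            gaps = rng.random(n_sites) < gap_fraction
            chars[gaps] = b"-"
        seqs.append(bytes(bytearray().join(chars)).decode("ascii"))
    return Alignment(tuple(names), tuple(seqs))


def random_tree(
    n_taxa: int,
    seed: int = 0,
    bl_range: tuple[float, float] = (0.1, 2.0),
    names: tuple[str, ...] | None = None,
) -> PhyloTree:
    """Random unrooted binary tree with uniform branch lengths.

    Topology is grown by attaching each new leaf to a uniformly chosen
    existing edge; branch lengths are drawn i.i.d. from ``bl_range``.  The
    leaf-to-leaf path lengths of such a tree form an additive distance
    matrix, the regime in which neighbor joining is provably consistent.
    """
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    if names is None:
        names = tuple(f"t{i + 1}" for i in range(n_taxa))
    if len(names) != n_taxa:
        raise ValueError("names length mismatch")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace(list(names))
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    for name in names[:3]:
        root.add_child(dendropy.Node(taxon=taxa.get_taxon(name)))
    for name in names[3:]:
        edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
        child = edges[int(rng.integers(0, len(edges)))]
        parent = child.parent_node
        mid = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(mid)
        mid.add_child(child)
        mid.add_child(dendropy.Node(taxon=taxa.get_taxon(name)))
    lo, hi = bl_range
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(lo, hi))
    tree.is_rooted = False
    return PhyloTree(tree)


def simulate_qpcr(
    n_samples: int,
    true_fold: float,
    ref_ct_mean: float = 18.0,
    seed: int = 0,
    sigma_ct: float = 0.0,
    base_dct: float = 2.0,
) -> QpcrTable:
    """Simulate a two-group qPCR Ct table with technical triplicates.

    The calibrator group has dCT = ``base_dct``; the treatment group's dCT
    is shifted by -log2(true_fold), so the 2^-ddCT reduction of a
    noise-free table returns ``true_fold`` exactly.  ``sigma_ct`` is the
    additive Gaussian technical noise per Ct measurement.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for group, dct in (
        ("treatment", base_dct - math.log2(true_fold)),
        ("calibrator", base_dct),
    ):
        for i in range(1, n_samples + 1):
            sid = f"{group}_{i}"
            for gene, level in (("target", ref_ct_mean + dct), ("reference", ref_ct_mean)):
                cts = level + (
                    rng.normal(0.0, sigma_ct, size=3) if sigma_ct > 0 else np.zeros(3)
                )
                rows.append(
                    dict(
                        sample_id=sid,
                        group=group,
                        gene=gene,
                        ct1=cts[0],
                        ct2=cts[1],
                        ct3=cts[2],
                    )
                )
    return QpcrTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# presets


def _filler_induction(
    rng: np.random.Generator,
    indices: list[int],
    conditions: tuple[str, ...],
    n_conditions: int = 2,
) -> dict[int, dict[str, float]]:
    """Decoy transporters: induced on small random condition sets, no activity."""
    inducible = [c for c in conditions if c not in ("no_carbon", "sucrose")]
    out: dict[int, dict[str, float]] = {}
    for t in indices:
        chosen = rng.choice(len(inducible), size=n_conditions, replace=False)
        folds = rng.uniform(3.0, 15.0, size=n_conditions)
        out[t] = {inducible[c]: float(f) for c, f in zip(chosen, folds)}
    return out


def neurospora_like(noise_cv: float = 0.1, seed: int = 0) -> TransportomeSpec:
    """Paper-scale preset: 44 transporters, 10 sugars, 15 conditions.

    Encodes the qualitative structure of a fungal sugar transportome:
    dedicated arabinose and galacturonic-acid transporters, two redundant
    cellodextrin transporters moonlighting on lactose/mannobiose, a minor
    lactose+galactose side-activity transporter, redundant glucose and
    xylose carriers, a constitutive transporter, a CCR-exempt glucose
    transporter, and one decoupled (post-transcriptionally regulated)
    rhamnose transporter whose expression carries no information about its
    activity.  The remaining transporters are expression decoys with no
    activity on the assayed sugars.
    """
    conds = DEFAULT_CONDITIONS
    sugars = DEFAULT_SUGARS
    named = [
        "lat-1",        # 0: arabinose
        "gat-1",        # 1: galacturonic acid
        "cdt-1",        # 2: cellodextrins + lactose
        "cdt-2",        # 3: cellodextrins + lactose, also xylan-induced
        "ncu00809",     # 4: minor lactose + galactose
        "frt-1",        # 5: rhamnose, decoupled
        "hgt-1",        # 6: glucose
        "hgt-2",        # 7: glucose
        "glt-1",        # 8: glucose, CCR-exempt
        "xyt-1",        # 9: xylose
        "an25",         # 10: xylose, constitutive
        "xat-1",        # 11: xylose + arabinose
        "mst-1",        # 12: mannose
        "cbt-1",        # 13: decoy near the cellodextrin cluster
    ]
    n_t = 44
    rng = np.random.default_rng(seed + 1_000_003)
    names = tuple(named + [f"ncu9{i:04d}" for i in range(n_t - len(named))])

    s = {x: i for i, x in enumerate(sugars)}
    A = np.zeros((n_t, len(sugars)))
    A[0, s["arabinose"]] = 1.0
    A[0, s["galactose"]] = 0.2
    A[1, s["galacturonic_acid"]] = 1.0
    A[2, s["cellobiose"]] = 0.6
    A[2, s["lactose"]] = 0.5
    A[2, s["mannobiose"]] = 0.4
    A[3, s["cellobiose"]] = 0.4
    A[3, s["lactose"]] = 0.4
    A[3, s["mannobiose"]] = 0.5
    A[4, s["lactose"]] = 0.15
    A[4, s["galactose"]] = 0.5
    A[5, s["rhamnose"]] = 1.0
    A[6, s["glucose"]] = 0.5
    A[7, s["glucose"]] = 0.3
    A[8, s["glucose"]] = 0.4
    A[9, s["xylose"]] = 0.5
    A[10, s["xylose"]] = 0.3
    A[11, s["xylose"]] = 0.4
    A[11, s["arabinose"]] = 0.1
    A[12, s["mannose"]] = 1.0

    induction: dict[int, dict[str, float]] = {
        0: {"arabinose": 20.0, "arabinan": 15.0},
        1: {"galacturonic_acid": 20.0, "pectin": 15.0, "polygalacturonic_acid": 15.0},
        2: {"cellulose": 20.0},
        3: {"cellulose": 18.0, "xylan": 10.0},
        4: {"arabinose": 12.0, "galactose": 12.0},
        5: {"glucose": 2.0},  # decoupled: expression uninformative
        6: {"glucose": 10.0},
        7: {"glucose": 8.0},
        8: {"glucose": 4.0},
        9: {"xylose": 10.0, "xylan": 8.0},
        11: {"xylose": 8.0, "arabinose": 4.0},
        12: {"mannose": 10.0, "glucomannan": 8.0},
        13: {"cellulose": 12.0},
    }
    induction.update(_filler_induction(rng, list(range(len(named), n_t)), conds))
    basal = np.ones(n_t)
    basal[10] = 8.0  # constitutive, high transcript level
    return TransportomeSpec(
        n_transporters=n_t,
        n_sugars=len(sugars),
        condition_labels=conds,
        sugar_names=sugars,
        transporter_names=names,
        activity=A,
        induction=induction,
        basal_expression=basal,
        ccr_condition="sucrose",
        ccr_factor=0.2,
        ccr_exempt=frozenset({8}),
        decoupled=frozenset({5}),
        constitutive=frozenset({10}),
        noise_cv=noise_cv,
        seed=seed,
    )


def dedicated_transporters(
    noise_cv: float = 0.1, seed: int = 0, n_transporters: int = 44
) -> TransportomeSpec:
    """Benchmark preset: exactly one dedicated transporter per sugar.

    Transporter i < 10 carries sugar i alone (unit activity) and is induced
    on its own single condition; the other transporters are decoys induced
    on two-condition sets (never collinear with a single-condition
    profile).  At zero noise each sugar's uptake profile is exactly
    proportional to its transporter's expression profile, so correlation
    ranking must place the dedicated transporter first with r = 1.
    """
    conds = DEFAULT_CONDITIONS
    sugars = DEFAULT_SUGARS
    n_s = len(sugars)
    if n_transporters < n_s:
        raise ValueError("need at least one transporter per sugar")
    inducible = [c for c in conds if c not in ("no_carbon", "sucrose")]
    rng = np.random.default_rng(seed + 2_000_003)
    A = np.zeros((n_transporters, n_s))
    induction: dict[int, dict[str, float]] = {}
    for i in range(n_s):
        A[i, i] = 1.0
        induction[i] = {inducible[i]: 20.0}
    induction.update(
        _filler_induction(rng, list(range(n_s, n_transporters)), conds)
    )
    return TransportomeSpec(
        n_transporters=n_transporters,
        n_sugars=n_s,
        condition_labels=conds,
        sugar_names=sugars,
        activity=A,
        induction=induction,
        ccr_condition="sucrose",
        ccr_factor=0.2,
        noise_cv=noise_cv,
        seed=seed,
    )


def redundant_pair(noise_cv: float = 0.0, seed: int = 0) -> TransportomeSpec:
    """Two equal-share transporters with disjoint induction carrying one sugar.

    The uptake profile is the mean of the two expression profiles, so
    neither transporter alone correlates perfectly with uptake while the
    sum of the two expression rows does — the functional-redundancy
    failure mode of single-gene correlation.
    """
    conds = DEFAULT_CONDITIONS
    A = np.array([[0.5], [0.5]])
    return TransportomeSpec(
        n_transporters=2,
        n_sugars=1,
        condition_labels=conds,
        sugar_names=("lactose",),
        transporter_names=("tpa-1", "tpb-1"),
        activity=A,
        induction={0: {"arabinose": 10.0}, 1: {"xylose": 10.0}},
        ccr_condition="sucrose",
        noise_cv=noise_cv,
        seed=seed,
    )


PRESETS = {
    "neurospora_like": neurospora_like,
    "dedicated": dedicated_transporters,
    "redundant_pair": redundant_pair,
}
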