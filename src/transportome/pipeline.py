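"""End-to-end orchestration: simulate/load -> rates -> cluster -> rank -> report.

The pipeline fixes the stage order and file names so a run is reproducible
from its manifest alone: every random stage derives its seed from the one
master seed, and rerunning the same config yields byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import (
    CandidateRanking,
    TransformConfig,
    average_linkage_cluster,
    build_joint_profile,
    correlation_distance_matrix,
    cut_clusters,
    rank_candidates,
)
from .expression import ExpressionMatrix
from .phylo import Alignment, PhyloTree, assign_clades, bootstrap_support, distance_matrix, neighbor_joining
from .synthetic import PRESETS, simulate_transportome, simulate_uptake_assays
from .uptake import build_uptake_matrix, read_assays_csv, write_assays_csv

__all__ = ["RunConfig", "RunResult", "run_pipeline", "make_report"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``preset``) or (``expression_tsv`` + ``assays_csv``)
    must be given.  The alignment/clade inputs are optional; without them
    the clade column of the report reads "n/a".
    """

    outdir: str
    preset: str | None = None
    expression_tsv: str | None = None
    assays_csv: str | None = None
    alignment_fasta: str | None = None
    clade_refs_tsv: str | None = None
    noise_cv: float = 0.1
    seed: int = 0
    k: int = 5
    linkage: str = "average"
    t_end_min: float = 15.0
    log2: bool = True
    pseudocount: float = 1.0
    normalize: str = "zscore"
    bootstrap_reps: int = 100
    clade_support_threshold: float = 0.5
    decoupling_r_threshold: float = 0.5
    n_replicates: int = 3

    def __post_init__(self) -> None:
        simulated = self.preset is not None
        loaded = self.expression_tsv is not None and self.assays_csv is not None
        if simulated == loaded:
            raise ValueError("give either a simulator preset or expression+assay paths")
        if simulated and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; known: {sorted(PRESETS)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunResult:
    config: RunConfig
    uptake: object
    joint: object
    dendrogram: object
    clusters: dict[str, int]
    rankings: list[CandidateRanking]
    clades: dict[str, str] | None
    report_md: str
    paths: dict[str, str] = field(default_factory=dict)


def _stage_seed(master: int, stage: int) -> int:
    return (master * 1000 + stage) % (2**31 - 1)


def run_pipeline(cfg: RunConfig) -> RunResult:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def emit(name: str) -> Path:
        p = outdir / name
        paths[name] = str(p)
        return p

    # --- inputs -----------------------------------------------------------
    if cfg.preset is not None:
        spec = PRESETS[cfg.preset](noise_cv=cfg.noise_cv, seed=_stage_seed(cfg.seed, 1))
        truth = simulate_transportome(spec)
        assays = simulate_uptake_assays(
            truth,
            n_replicates=cfg.n_replicates,
            seed=_stage_seed(cfg.seed, 2),
            noise_cv=cfg.noise_cv,
            t_end_min=cfg.t_end_min,
        )
        expr = truth.expression
        expr.to_tsv(emit("expression.tsv"))
        write_assays_csv(assays, emit("assays.csv"))
        truth.assignment_to_json(emit("true_assignment.json"))
    else:
        expr = ExpressionMatrix.from_tsv(cfg.expression_tsv)
        assays = read_assays_csv(cfg.assays_csv)
        truth = None

    # --- rates ------------------------------------------------------------
    uptake = build_uptake_matrix(assays, t_end_min=cfg.t_end_min)
    uptake.to_tsv(emit("uptake_rates.tsv"), emit("uptake_flags.json"))

    # --- joint clustering -------------------------------------------------
    tconf = TransformConfig(cfg.log2, cfg.pseudocount, cfg.normalize)
    joint = build_joint_profile(uptake, expr, tconf)
    dist = correlation_distance_matrix(joint)
    dend = average_linkage_cluster(dist, linkage=cfg.linkage)
    clusters = cut_clusters(dend, k=cfg.k)
    rankings = rank_candidates(joint, dend, k=cfg.k)

    ordered = joint.to_frame().iloc[dend.leaf_order]
    ordered.index.name = "row"
    ordered.to_csv(emit("joint_matrix.tsv"), sep="\t", float_format="%.10g")
    with open(emit("dendrogram.nwk"), "w") as fh:
        fh.write(dend.to_newick() + "\n")
    pd.Series(clusters, name="cluster").rename_axis("row").to_csv(
        emit("clusters.tsv"), sep="\t"
    )
    pd.concat([r.to_frame() for r in rankings]).to_csv(
        emit("rankings.tsv"), sep="\t", index=False, float_format="%.10g"
    )

    # --- phylogeny (optional) ---------------------------------------------
    clades = None
    if cfg.alignment_fasta is not None:
        aln = Alignment.from_fasta(cfg.alignment_fasta)
        if cfg.bootstrap_reps > 0:
            tree = bootstrap_support(
                aln, n_reps=cfg.bootstrap_reps, seed=_stage_seed(cfg.seed, 3)
            )
        else:
            tree = neighbor_joining(distance_matrix(aln))
        tree.write_newick(emit("tree.nwk"))
        if cfg.clade_refs_tsv is not None:
            refs_df = pd.read_csv(cfg.clade_refs_tsv, sep="\t", header=None, comment="#")
            refs = dict(zip(refs_df[0].astype(str), refs_df[1].astype(str)))
            clades = assign_clades(
                tree, refs, support_threshold=cfg.clade_support_threshold
            )
            pd.Series(clades, name="clade").rename_axis("query").to_csv(
                emit("clades.tsv"), sep="\t"
            )

    # --- report + manifest --------------------------------------------------
    report = make_report(
        rankings,
        clades,
        clusters,
        uptake=uptake,
        constant_rows=joint.constant_rows,
        decoupling_r_threshold=cfg.decoupling_r_threshold,
    )
    emit("report.md").write_text(report)
    manifest = dict(
        package_version=__version__,
        config=asdict(cfg),
        stage_seeds={
            "simulate": _stage_seed(cfg.seed, 1),
            "assays": _stage_seed(cfg.seed, 2),
            "bootstrap": _stage_seed(cfg.seed, 3),
        },
        outputs=sorted(paths),
    )
    with open(emit("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return RunResult(cfg, uptake, joint, dend, clusters, rankings, clades, report, paths)


def make_report(
    rankings: list[CandidateRanking],
    clades: dict[str, str] | None,
    cut: dict[str, int],
    uptake=None,
    constant_rows: frozenset = frozenset(),
    decoupling_r_threshold: float = 0.5,
    top_n: int = 5,
) -> str:
    """Human-readable per-sugar candidate summary (markdown).

    Flags (i) constant-expression genes, whose correlation is undefined, and
    (ii) decoupling suspects: sugars with nonzero uptake whose best gene
    correlation stays below the threshold — the signature of a transporter
    regulated post-transcriptionally rather than at the transcript level.
    """
    lines = ["# Transporter candidate report", ""]
    if not rankings:
        lines.append("WARNING: no sugars ranked (empty input).")
        return "\n".join(lines) + "\n"
    for ranking in rankings:
        sugar = ranking.sugar
        lines.append(f"## {sugar}")
        lines.append("")
        max_uptake = None
        if uptake is not None and sugar in uptake.sugars:
            max_uptake = float(uptake.rates.loc[sugar].max())
        finite = [e.pearson_r for e in ranking.entries if not math.isnan(e.pearson_r)]
        best_r = max(finite) if finite else float("-inf")
        suspect = best_r < decoupling_r_threshold and (max_uptake is None or max_uptake > 0)
        if f"sugar:{sugar}" in constant_rows:
            lines.append(
                "- NOTE: uptake profile is constant across conditions; "
                "correlations are undefined."
            )
        if suspect:
            lines.append(
                f"- DECOUPLING SUSPECT: measurable uptake but max gene correlation "
                f"r = {best_r if finite else float('nan'):.3f} < "
                f"{decoupling_r_threshold} — consider post-transcriptional regulation."
            )
        lines.append("")
        lines.append("| rank | gene | r | same cluster | clade | flags |")
        lines.append("|---|---|---|---|---|---|")
        for e in ranking.entries[:top_n]:
            clade = (clades or {}).get(e.gene, "n/a")
            flags = "constant" if f"gene:{e.gene}" in constant_rows else ""
            r_txt = "nan" if math.isnan(e.pearson_r) else f"{e.pearson_r:.3f}"
            lines.append(
                f"| {e.rank} | {e.gene} | {r_txt} | "
                f"{'yes' if e.same_cluster else 'no'} | {clade} | {flags} |"
            )
        lines.append("")
    return "\n".join(lines) + "\n"


def is_decoupling_suspect(
    ranking: CandidateRanking, max_uptake: float, r_threshold: float = 0.5
) -> bool:
    """True when a sugar shows uptake but no well-correlated gene."""
    finite = [e.pearson_r for e in ranking.entries if not math.isnan(e.pearson_r)]
    best = max(finite) if finite else float("-inf")
    return max_uptake > 0 and best < r_threshold
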