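"""End-to-end orchestration of the CRE-discovery analysis.

A single config drives the full chain: response classification into the
26 pattern clusters, selection of the concordant clusters (all-up and
all-down), ZOOPS motif discovery in their promoters, degenerate scanning
of the whole promoter universe, cluster- and community-level Fisher
enrichment, per-condition co-expression networks intersected and
partitioned into regulatory modules, and the edge-sharing permutation
test. Every intermediate artifact is written as plain text so reruns
with identical configs are byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coexpression import correlation_network, intersect_networks, z_transform
from .communities import greedy_modularity, regulatory_modules
from .datasets import (
    read_annotation_tsv,
    read_expression_tsv,
    read_matrix_tsv,
    read_promoters_fasta,
    write_gene_list,
    write_matrix_tsv,
)
from .enrichment import (
    cluster_motif_enrichment,
    community_motif_enrichment,
    edge_sharing_permutation,
    term_enrichment_sea,
)
from .motifs import PLANT_CRE_CATALOGUE, consensus_iupac, discover_motifs, match_known
from .response import assign_clusters, call_differential, cluster_index, combine_h2o2
from .scan import genes_with_motif, scan_promoters
from .simulate import SimConfig, simulate_study

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("crenet")


class PipelineError(RuntimeError):
    """A stage failure, carrying the name of the stage that aborted."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a full run needs; synthetic mode or file inputs.

    In synthetic mode (default) inputs come from the seeded generators in
    ``simulate``; otherwise ``expression_paths`` (condition -> TSV),
    ``timeseries_paths`` (condition -> TSV) and ``promoters_path`` must
    point at existing files.
    """

    synthetic: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    expression_paths: dict[str, str] = field(default_factory=dict)
    timeseries_paths: dict[str, str] = field(default_factory=dict)
    promoters_path: str | None = None
    annotation_path: str | None = None

    fc_threshold: float = 1.0
    alpha: float | None = None  # pure fold-change classification by default
    tau: float = 0.6
    correlation_mode: str = "signed"
    min_module_size: int = 6
    motif_widths: tuple[int, ...] = tuple(range(6, 13))
    n_motifs: int = 3
    max_sites: int = 10
    strands: str = "fwd"
    n_permutations: int = 999
    seed: int = 0
    outdir: str = "crenet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        from .simulate import MotifSpec

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = dict(raw.pop("sim", {}))
        if sim_raw.get("motif_specs") is not None:
            sim_raw["motif_specs"] = tuple(
                MotifSpec(**s) if isinstance(s, dict) else MotifSpec(*s)
                for s in sim_raw["motif_specs"]
            )
        for key in ("conditions", "community_sizes"):
            if sim_raw.get(key) is not None:
                sim_raw[key] = tuple(sim_raw[key])
        if "seed" in raw and "seed" not in sim_raw:
            sim_raw["seed"] = raw["seed"]
        if "motif_widths" in raw:
            raw["motif_widths"] = tuple(raw["motif_widths"])
        return cls(sim=SimConfig(**sim_raw), **raw)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(plain(asdict(self)), sort_keys=True))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, str(err)) from err
            log.info("stage %s done (%.2f s)", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@dataclass
class PipelineResult:
    """Handles to the main in-memory products of a run."""

    calls: pd.DataFrame
    clusters: pd.DataFrame
    discovered: list
    presence: pd.DataFrame
    cluster_enrichment: pd.DataFrame
    modules: list
    community_enrichment: pd.DataFrame
    permutation: object
    outdir: Path


def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic:
        study = simulate_study(cfg.sim)
        return study.response, study.timeseries, study.promoters, study
    expression = {}
    for cond, path in cfg.expression_paths.items():
        if not Path(path).exists():
            raise PipelineError("load-expression", f"missing expression file {path}")
        expression[cond] = read_expression_tsv(path)
    timeseries = {}
    for cond, path in cfg.timeseries_paths.items():
        if not Path(path).exists():
            raise PipelineError("load-timeseries", f"missing time-series file {path}")
        timeseries[cond] = read_matrix_tsv(path)
    if cfg.promoters_path is None or not Path(cfg.promoters_path).exists():
        raise PipelineError("scan", f"missing promoter file {cfg.promoters_path}")
    promoters = read_promoters_fasta(cfg.promoters_path)
    return expression, timeseries, promoters, None


@_stage("classify")
def _classify(cfg: PipelineConfig, expression) -> tuple[pd.DataFrame, pd.DataFrame]:
    per_cond = {}
    for cond in expression:
        per_cond[cond] = call_differential(
            expression[cond], cond, fc_threshold=cfg.fc_threshold, alpha=cfg.alpha
        )
    if "h2o2_1h" in per_cond and "h2o2_5h" in per_cond:
        per_cond["h2o2"] = combine_h2o2(per_cond["h2o2_1h"], per_cond["h2o2_5h"])
    rows = [
        {
            "gene": c.gene,
            "condition": c.condition,
            "log2fc": c.log2fc,
            "p": c.p,
            "q": c.q,
            "code": c.code,
            "discordant": c.discordant,
        }
        for calls in per_cond.values()
        for c in calls
    ]
    calls_df = pd.DataFrame(rows)
    codes = calls_df.pivot(index="gene", columns="condition", values="code")
    needed = ["developmental", "salt", "h2o2"]
    missing = [c for c in needed if c not in codes.columns]
    if missing:
        raise ValueError(f"conditions missing for cluster assignment: {missing}")
    assignments = assign_clusters(codes[needed].astype(int))
    clusters_df = pd.DataFrame(
        {
            "gene": [a.gene for a in assignments],
            "dev": [a.pattern[0] for a in assignments],
            "salt": [a.pattern[1] for a in assignments],
            "h2o2": [a.pattern[2] for a in assignments],
            "cluster": [a.cluster if a.cluster is not None else 0 for a in assignments],
        }
    ).sort_values("gene", kind="stable")
    return calls_df, clusters_df


@_stage("network")
def _networks(cfg: PipelineConfig, timeseries):
    nets = []
    for cond, matrix in timeseries.items():
        z = z_transform(matrix)
        nets.append(correlation_network(z, cfg.tau, mode=cfg.correlation_mode, label=cond))
    return nets, intersect_networks(nets)


@_stage("communities")
def _communities(cfg: PipelineConfig, intersection):
    partition = greedy_modularity(intersection)
    modules = regulatory_modules(partition, min_size=cfg.min_module_size)
    return partition, modules


@_stage("discover")
def _discover(cfg: PipelineConfig, promoters, cluster_genes):
    seqs = {g: promoters[g] for g in cluster_genes if g in promoters}
    if not seqs:
        raise ValueError("no promoters available for the selected cluster")
    return discover_motifs(
        seqs,
        widths=cfg.motif_widths,
        n_motifs=cfg.n_motifs,
        max_sites=cfg.max_sites,
    )


@_stage("scan")
def _scan(cfg: PipelineConfig, promoters, patterns):
    presence = pd.DataFrame(
        {
            pat: [g in genes_with_motif(promoters, pat, cfg.strands) for g in promoters]
            for pat in patterns
        },
        index=list(promoters),
    ).astype(int)
    occurrences = [
        occ for pat in patterns for occ in scan_promoters(promoters, pat, cfg.strands)
    ]
    return presence, occurrences


@_stage("enrich")
def _enrich(cfg: PipelineConfig, cluster_genes, universe, presence, modules):
    cluster_res = cluster_motif_enrichment(cluster_genes, universe, presence)
    cluster_df = pd.DataFrame(
        {
            "motif": [r.feature for r in cluster_res],
            "in_cluster_with_motif": [r.table.a for r in cluster_res],
            "outside_with_motif": [r.table.b for r in cluster_res],
            "in_cluster_without_motif": [r.table.c for r in cluster_res],
            "outside_without_motif": [r.table.d for r in cluster_res],
            "p": [r.p for r in cluster_res],
            "q": [r.q for r in cluster_res],
        }
    )
    comms = {m.id: set(m.members) for m in modules}
    comm_df = (
        community_motif_enrichment(comms, universe, presence)
        if comms
        else pd.DataFrame(columns=["community", "motif", "n_with_motif", "size", "p"])
    )
    return cluster_df, comm_df


@_stage("permute")
def _permute(cfg: PipelineConfig, intersection, presence):
    sub = presence.loc[[g for g in intersection.nodes if g in presence.index]]
    return edge_sharing_permutation(
        intersection.edges(), sub, n_permutations=cfg.n_permutations, seed=cfg.seed
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write all artifacts under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        log.info("crenet %s, seed %d", __version__, cfg.seed)
        cfg.to_yaml(outdir / "config.yaml")

        expression, timeseries, promoters, study = _load_inputs(cfg)

        calls_df, clusters_df = _classify(cfg, expression)
        calls_df.to_csv(outdir / "response_calls.tsv", sep="\t", index=False)
        clusters_df.to_csv(outdir / "clusters.tsv", sep="\t", index=False)

        all_up = set(clusters_df.loc[clusters_df["cluster"] == cluster_index(1, 1, 1), "gene"])
        all_down = set(clusters_df.loc[clusters_df["cluster"] == cluster_index(-1, -1, -1), "gene"])
        write_gene_list(sorted(all_up), outdir / "cluster_all_up_genes.txt")
        write_gene_list(sorted(all_down), outdir / "cluster_all_down_genes.txt")

        if cfg.synthetic:
            # restrict the network stage to the classifier's all-up genes,
            # mirroring the per-cluster co-expression analysis
            timeseries = {
                cond: m.loc[[g for g in m.index if g in all_up]]
                for cond, m in timeseries.items()
            }
        nets, intersection = _networks(cfg, timeseries)
        for net in nets:
            pd.DataFrame(net.edges(), columns=["gene_a", "gene_b"]).to_csv(
                outdir / f"network_{net.label}.tsv", sep="\t", index=False
            )
        pd.DataFrame(intersection.edges(), columns=["gene_a", "gene_b"]).to_csv(
            outdir / "network_intersection.tsv", sep="\t", index=False
        )

        partition, modules = _communities(cfg, intersection)
        pd.Series(partition.membership, name="community").rename_axis("gene").sort_index().to_csv(
            outdir / "partition.tsv", sep="\t"
        )
        pd.DataFrame(
            {
                "community": [m.id for m in modules],
                "size": [m.size for m in modules],
                "members": [",".join(sorted(m.members)) for m in modules],
            }
        ).to_csv(outdir / "modules.tsv", sep="\t", index=False)

        discovered = _discover(cfg, promoters, all_up)
        patterns = [consensus_iupac(m) for m in discovered]
        with open(outdir / "motifs.txt", "w") as fh_m:
            for model, pat in zip(discovered, patterns):
                known = match_known(model, PLANT_CRE_CATALOGUE, seed=cfg.seed)
                fh_m.write(
                    f"motif {pat} width={model.width} lambda={model.lam:.4f} "
                    f"score={model.score:.4f} sites={len(model.sites)} "
                    f"best_known={known.name} sim={known.score:.3f} p={known.p:.4g}\n"
                )
                write_matrix_tsv(
                    pd.DataFrame(model.theta, index=list("ACGT")),
                    outdir / f"ppm_{pat}.tsv",
                )

        presence, occurrences = _scan(cfg, promoters, patterns)
        write_matrix_tsv(presence, outdir / "motif_presence.tsv")
        pd.DataFrame(
            [(o.gene, o.offset, o.strand, o.word) for o in occurrences],
            columns=["gene", "offset", "strand", "word"],
        ).to_csv(outdir / "occurrences.tsv", sep="\t", index=False)

        universe = set(promoters)
        cluster_enr, comm_enr = _enrich(cfg, all_up, universe, presence, modules)
        cluster_enr.to_csv(outdir / "cluster_enrichment.tsv", sep="\t", index=False)
        comm_enr.to_csv(outdir / "community_enrichment.tsv", sep="\t", index=False)

        if cfg.annotation_path:
            annotation = read_annotation_tsv(cfg.annotation_path)
            sea = term_enrichment_sea(all_up, universe, annotation, fdr=None)
            pd.DataFrame(
                [(r.feature, r.table.a, r.p, r.q) for r in sea],
                columns=["term", "query_hits", "p", "q"],
            ).to_csv(outdir / "sea_enrichment.tsv", sep="\t", index=False)

        perm = _permute(cfg, intersection, presence)
        (outdir / "permutation.txt").write_text(
            f"observed_share_fraction\t{perm.observed:.6f}\n"
            f"null_mean\t{perm.null_mean:.6f}\n"
            f"n_permutations\t{perm.n_permutations}\n"
            f"p\t{perm.p:.6g}\n"
        )

        _write_report(outdir, cfg, clusters_df, modules, patterns, cluster_enr, perm)
        return PipelineResult(
            calls_df, clusters_df, discovered, presence, cluster_enr, modules, comm_enr, perm, outdir
        )
    finally:
        log.removeHandler(fh)
        fh.close()


def _write_report(outdir, cfg, clusters_df, modules, patterns, cluster_enr, perm):
    n_per_cluster = clusters_df[clusters_df["cluster"] > 0]["cluster"].value_counts().sort_index()
    lines = [
        f"crenet {__version__} analysis report (seed {cfg.seed})",
        "",
        f"genes classified: {len(clusters_df)}",
        f"responsive genes (non-null pattern): {int((clusters_df['cluster'] > 0).sum())}",
        "genes per cluster: " + ", ".join(f"{c}:{n}" for c, n in n_per_cluster.items()),
        f"regulatory modules (size >= {cfg.min_module_size}): "
        + ", ".join(f"module {m.id} ({m.size} genes)" for m in modules),
        f"discovered motifs: {', '.join(patterns) if patterns else 'none'}",
        "",
        "cluster-enrichment (motif, p, q):",
    ]
    for _, row in cluster_enr.iterrows():
        lines.append(f"  {row['motif']}\t{row['p']:.3g}\t{row['q']:.3g}")
    lines += [
        "",
        f"edge sharing: observed={perm.observed:.4f} null_mean={perm.null_mean:.4f} "
        f"p={perm.p:.4g} (B={perm.n_permutations})",
        "",
    ]
    (outdir / "report.txt").write_text("\n".join(lines))
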