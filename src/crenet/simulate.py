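"""Seeded synthetic data with known ground truth.

Three generators emulate the statistical structure of the study design
this pipeline targets: (a) replicated treatment/control log2 expression
with planted ternary response codes per condition, (b) short per-condition
time series with planted co-expressed communities driven by smooth latent
curves, and (c) fixed-length promoters with degenerate motifs implanted
preferentially inside chosen communities. Every generator draws from its
own RNG stream derived from ``SimConfig.seed``, so identical configs give
bit-identical outputs while the three fixtures stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionSet
from .scan import IUPAC_SETS, _validate_pattern

__all__ = [
    "MotifSpec",
    "SimConfig",
    "Truth",
    "generate_response_dataset",
    "generate_timeseries",
    "generate_promoters",
    "simulate_study",
    "SimStudy",
]

#: Replicated response conditions: the two senescence assays plus the two
#: oxidative-stress sampling times that are later combined by the and/or rule.
RESPONSE_CONDITIONS = ("developmental", "salt", "h2o2_1h", "h2o2_5h")
#: Time-series conditions (the oxidative series stands in for both peroxide
#: sampling times, as a single 24-h stress course).
TIMESERIES_CONDITIONS = ("developmental", "salt", "oxidative")

# distinct RNG stream ids per generator
_STREAM_RESPONSE, _STREAM_TIMESERIES, _STREAM_PROMOTERS = 1, 2, 3


class ConfigurationError(ValueError):
    """Raised when a SimConfig is internally inconsistent."""


@dataclass(frozen=True)
class MotifSpec:
    """One motif to implant: IUPAC pattern, in-community rate, background rate.

    ``community`` selects the target community; ``None`` means the spec is
    assigned to a community positionally when a study is simulated.
    """

    pattern: str
    q_in: float
    q_out: float
    community: int | None = None

    def __post_init__(self) -> None:
        _validate_pattern(self.pattern)
        if not (0.0 <= self.q_out <= self.q_in <= 1.0):
            raise ConfigurationError(
                f"need 0 <= q_out <= q_in <= 1, got q_in={self.q_in}, q_out={self.q_out}"
            )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults encode the emulated design: three biological replicates,
    ~2-fold decision threshold with planted effects well above it, six
    time points per stress course, three planted regulatory modules, and
    500-bp promoters at plant-like GC content.
    """

    n_genes: int = 1000
    n_replicates: int = 3
    conditions: tuple[str, ...] = RESPONSE_CONDITIONS
    effect_log2fc: float = 2.0
    noise_sd: float = 0.25
    responder_fraction: float = 0.3
    frac_all_up: float = 0.08
    frac_all_down: float = 0.04
    n_timepoints: int = 6
    n_communities: int = 3
    community_sizes: tuple[int, ...] | None = None
    factor_amplitude: float = 1.0
    promoter_length: int = 500
    gc_content: float = 0.36
    motif_specs: tuple[MotifSpec, ...] = (
        MotifSpec("CACGTGT", 0.60, 0.05),
        MotifSpec("AAGTCAA", 0.60, 0.10),
        MotifSpec("TCSTYGACG", 0.50, 0.02),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigurationError("gc_content must lie strictly in (0, 1)")
        if self.noise_sd < 0 or self.effect_log2fc < 0:
            raise ConfigurationError("noise_sd and effect_log2fc must be >= 0")
        if self.frac_all_up + self.frac_all_down > 1:
            raise ConfigurationError("frac_all_up + frac_all_down must be <= 1")
        if self.community_sizes is not None and sum(self.community_sizes) > self.n_genes:
            raise ConfigurationError("community sizes must sum to <= n_genes")
        if self.motif_specs and self.promoter_length < max(
            len(s.pattern) for s in self.motif_specs
        ):
            raise ConfigurationError("promoter_length shorter than the longest motif")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class Truth:
    """Planted ground truth recorded alongside the generated data.

    ``response_codes``: genes x conditions ternary matrix (includes the
    combined ``h2o2`` column by the and/or rule). ``partition``: gene ->
    community id, -1 for genes outside any community. ``motif_sites``:
    (gene, pattern, offset) triples for every implanted instance.
    """

    response_codes: pd.DataFrame | None = None
    partition: pd.Series | None = None
    motif_sites: list[tuple[str, str, int]] = field(default_factory=list)


def _plant_codes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the ternary gene x condition truth table.

    A fixed fraction of genes responds concordantly in every condition
    (up or down) — the cross-talk signal the downstream analysis looks
    for — and the remaining genes respond independently per condition.
    """
    genes = cfg.gene_ids()
    n = cfg.n_genes
    n_up = round(cfg.frac_all_up * n)
    n_down = round(cfg.frac_all_down * n)
    order = rng.permutation(n)
    codes = pd.DataFrame(0, index=genes, columns=list(cfg.conditions) + ["h2o2"], dtype=int)

    all_up = [genes[i] for i in order[:n_up]]
    all_down = [genes[i] for i in order[n_up : n_up + n_down]]
    rest = [genes[i] for i in order[n_up + n_down :]]
    codes.loc[all_up, :] = 1
    codes.loc[all_down, :] = -1

    p = cfg.responder_fraction / 2.0
    for g in rest:
        dev, salt, h2o2 = rng.choice([-1, 0, 1], size=3, p=[p, 1 - 2 * p, p])
        codes.loc[g, "developmental"] = dev
        codes.loc[g, "salt"] = salt
        codes.loc[g, "h2o2"] = h2o2
        if h2o2 != 0:
            # express the combined code at each sampling time with prob 0.75,
            # forcing at least one so the and/or rule reconstructs it exactly
            b1, b2 = rng.random(2) < 0.75
            if not (b1 or b2):
                b1 = True
            codes.loc[g, "h2o2_1h"] = h2o2 if b1 else 0
            codes.loc[g, "h2o2_5h"] = h2o2 if b2 else 0
    return codes


def generate_response_dataset(
    cfg: SimConfig,
) -> tuple[dict[str, ExpressionSet], Truth]:
    """Replicated treatment/control log2 expression per condition.

    Responder genes have mean treated-control difference exactly
    ``code * effect_log2fc``; replicate noise is i.i.d. Gaussian with SD
    ``noise_sd`` on the log2 scale (microarray convention).
    """
    rng = cfg.rng(_STREAM_RESPONSE)
    codes = _plant_codes(cfg, rng)
    genes = cfg.gene_ids()
    baseline = rng.normal(8.0, 1.0, size=cfg.n_genes)

    datasets: dict[str, ExpressionSet] = {}
    for cond in cfg.conditions:
        cols, meta = [], []
        vals = np.empty((cfg.n_genes, 2 * cfg.n_replicates))
        shift = codes[cond].to_numpy() * cfg.effect_log2fc
        for r in range(1, cfg.n_replicates + 1):
            cols.append(f"{cond}:treated:{r}")
            meta.append((cond, "treated", str(r)))
        for r in range(1, cfg.n_replicates + 1):
            cols.append(f"{cond}:control:{r}")
            meta.append((cond, "control", str(r)))
        noise = rng.normal(0.0, cfg.noise_sd, size=vals.shape) if cfg.noise_sd > 0 else 0.0
        base = np.repeat(baseline[:, None], 2 * cfg.n_replicates, axis=1)
        base[:, : cfg.n_replicates] += shift[:, None]
        vals = base + noise
        values = pd.DataFrame(vals, index=genes, columns=cols)
        samples = pd.DataFrame(meta, columns=["condition", "arm", "replicate"], index=cols)
        datasets[cond] = ExpressionSet(values=values, samples=samples)
    return datasets, Truth(response_codes=codes)


def _smooth_orthogonal_curves(
    rng: np.random.Generator, n_timepoints: int, k: int
) -> np.ndarray:
    """k zero-mean, pairwise-orthogonal smooth curves, unit SD, as columns.

    Curves start as random low-frequency sinusoid mixtures and are then
    centred and Gram-Schmidt orthogonalized (the zero-mean subspace is
    closed under linear combination), so distinct communities have
    exactly zero Pearson correlation in the noiseless limit.
    """
    if k > n_timepoints - 1:
        raise ConfigurationError(
            f"cannot plant {k} mutually orthogonal communities on {n_timepoints} timepoints"
        )
    t = np.linspace(0.0, 1.0, n_timepoints)
    curves = np.empty((n_timepoints, k))
    col = 0
    attempts = 0
    while col < k:
        attempts += 1
        if attempts > 100 * k:  # pragma: no cover - pathological rng state
            raise RuntimeError("failed to orthogonalize latent curves")
        amp = rng.normal(size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        c = sum(a * np.sin(2 * np.pi * (h + 1) * t + ph) for h, (a, ph) in enumerate(zip(amp, phase)))
        c = c - c.mean()
        for j in range(col):
            c -= (c @ curves[:, j]) / (curves[:, j] @ curves[:, j]) * curves[:, j]
        if np.std(c) < 1e-8:
            continue
        curves[:, col] = c / c.std()
        col += 1
    return curves


def _community_sizes(cfg: SimConfig, n_genes: int) -> list[int]:
    if cfg.community_sizes is not None:
        if sum(cfg.community_sizes) > n_genes:
            raise ConfigurationError("community sizes exceed available genes")
        return list(cfg.community_sizes)
    if cfg.n_communities > n_genes:
        raise ConfigurationError("more communities than genes")
    base = n_genes // cfg.n_communities
    sizes = [base] * cfg.n_communities
    for i in range(n_genes - base * cfg.n_communities):
        sizes[i] += 1
    return sizes


def generate_timeseries(
    cfg: SimConfig, genes: Sequence[str] | None = None
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Per-condition gene x timepoint matrices with planted communities.

    Genes in community c follow ``loading * f_c(t) + noise`` with positive
    loadings and condition-specific latent curves f_c; the same partition
    drives all three conditions so the planted communities survive network
    intersection. Genes outside every community follow private random
    smooth curves.
    """
    if cfg.n_timepoints < 4:
        raise ConfigurationError("need at least 4 timepoints")
    rng = cfg.rng(_STREAM_TIMESERIES)
    genes = list(genes) if genes is not None else cfg.gene_ids()
    sizes = _community_sizes(cfg, len(genes))

    perm = rng.permutation(len(genes))
    membership = np.full(len(genes), -1, dtype=int)
    pos = 0
    for cid, size in enumerate(sizes):
        membership[perm[pos : pos + size]] = cid
        pos += size
    partition = pd.Series(membership, index=genes, name="community")

    timepoint_cols = [f"t{i}" for i in range(cfg.n_timepoints)]
    out: dict[str, pd.DataFrame] = {}
    for cond in TIMESERIES_CONDITIONS:
        curves = _smooth_orthogonal_curves(rng, cfg.n_timepoints, len(sizes))
        vals = np.empty((len(genes), cfg.n_timepoints))
        loadings = cfg.factor_amplitude * rng.uniform(0.75, 1.25, size=len(genes))
        for i, cid in enumerate(membership):
            if cid >= 0:
                profile = loadings[i] * curves[:, cid]
            else:
                profile = cfg.factor_amplitude * _smooth_orthogonal_curves(rng, cfg.n_timepoints, 1)[:, 0]
            vals[i] = profile
        if cfg.noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.noise_sd, size=vals.shape)
        out[cond] = pd.DataFrame(vals, index=genes, columns=timepoint_cols)
    return out, partition


def generate_promoters(
    genes: Sequence[str],
    partition: Mapping[str, int] | pd.Series | None,
    motif_specs: Sequence[MotifSpec],
    cfg: SimConfig,
) -> tuple[dict[str, str], list[tuple[str, str, int]]]:
    """Fixed-length promoters with implanted degenerate motif instances.

    Background bases are i.i.d. at the configured GC content. For each
    spec, a uniformly sampled expansion of its pattern is written over the
    background (promoter length stays fixed) at a uniform offset with
    probability ``q_in`` for community members and ``q_out`` otherwise,
    forward strand only. Every implant event is recorded; a later implant
    may overwrite an earlier overlapping one.
    """
    rng = cfg.rng(_STREAM_PROMOTERS)
    L = cfg.promoter_length
    for spec in motif_specs:
        if len(spec.pattern) > L:
            raise ConfigurationError(f"pattern {spec.pattern!r} longer than promoter")
    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    part = dict(partition.items()) if partition is not None else {}

    promoters: dict[str, str] = {}
    sites: list[tuple[str, str, int]] = []
    for gene in genes:
        seq = rng.choice(bases, size=L, p=probs)
        for spec in motif_specs:
            member = part.get(gene, -1) == spec.community
            q = spec.q_in if member else spec.q_out
            if q > 0 and rng.random() < q:
                word = "".join(
                    rng.choice(sorted(IUPAC_SETS[sym])) for sym in spec.pattern
                )
                off = int(rng.integers(0, L - len(word) + 1))
                seq[off : off + len(word)] = list(word)
                sites.append((gene, spec.pattern, off))
        promoters[gene] = "".join(seq)
    return promoters, sites


@dataclass
class SimStudy:
    """Bundle of one coherent synthetic study: all inputs plus the truth."""

    config: SimConfig
    response: dict[str, ExpressionSet]
    timeseries: dict[str, pd.DataFrame]
    promoters: dict[str, str]
    truth: Truth
    all_up_genes: list[str]


def simulate_study(cfg: SimConfig) -> SimStudy:
    """One coherent end-to-end fixture.

    The genes planted as up-regulated in every condition form the
    time-series universe and are partitioned into communities; motif
    specs are attached to those communities positionally (unless pinned),
    and promoters are generated for the whole gene universe.
    """
    response, truth = generate_response_dataset(cfg)
    codes = truth.response_codes
    all_up = list(
        codes.index[
            (codes["developmental"] == 1) & (codes["salt"] == 1) & (codes["h2o2"] == 1)
        ]
    )
    ts_cfg = cfg
    if cfg.community_sizes is None and cfg.n_communities > max(len(all_up), 1):
        ts_cfg = replace(cfg, n_communities=max(1, len(all_up)))
    timeseries, partition = generate_timeseries(ts_cfg, genes=all_up)

    community_ids = sorted({int(c) for c in partition.unique() if c >= 0})
    specs = []
    for i, spec in enumerate(cfg.motif_specs):
        target = spec.community
        if target is None:
            target = community_ids[i % len(community_ids)] if community_ids else -1
        specs.append(replace(spec, community=target))

    full_partition = pd.Series(-1, index=cfg.gene_ids(), name="community")
    full_partition.loc[partition.index] = partition
    promoters, sites = generate_promoters(cfg.gene_ids(), full_partition, specs, cfg)

    truth.partition = full_partition
    truth.motif_sites = sites
    return SimStudy(
        config=cfg,
        response=response,
        timeseries=timeseries,
        promoters=promoters,
        truth=truth,
        all_up_genes=all_up,
    )
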