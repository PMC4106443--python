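"""Ternary response classification and the 26-cluster assignment.

Each gene is called up (+1), down (-1), or unresponsive (0) per condition
with an inclusive 2-fold rule on the log2 scale, optionally gated by a
BH-FDR significance filter from a (paired) t-test. The two peroxide
sampling times are combined with an and/or rule, and the resulting
(developmental, salt, h2o2) ternary triple indexes one of the 26
non-null response clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionSet
from .enrichment import bh_fdr

__all__ = [
    "ResponseCall",
    "ClusterAssignment",
    "call_differential",
    "combine_h2o2",
    "assign_clusters",
    "cluster_index",
    "cluster_pattern",
    "overlap_stats",
    "OverlapStats",
]


@dataclass(frozen=True)
class ResponseCall:
    """Per-gene differential call in one condition."""

    gene: str
    condition: str
    log2fc: float
    p: float
    q: float
    code: int
    discordant: bool = False


# --- ternary cluster numbering ------------------------------------------------
# Base-3 index over (dev, salt, h2o2) with h2o2 the most significant digit and
# the digit map -1 -> 0, 0 -> 1, +1 -> 2. The all-zero pattern (raw index 14 of
# 1..27) is removed and higher indices shift down, yielding clusters 1..26 with
# (-,-,-) -> 1, dev-only-up -> 14 and (+,+,+) -> 26.

_DIGIT = {-1: 0, 0: 1, 1: 2}


def cluster_index(dev: int, salt: int, h2o2: int) -> int | None:
    """Cluster 1..26 for a ternary triple; ``None`` for the null pattern."""
    for c in (dev, salt, h2o2):
        if c not in (-1, 0, 1):
            raise ValueError(f"non-ternary response code {c!r}")
    if dev == salt == h2o2 == 0:
        return None
    raw = 1 + 9 * _DIGIT[h2o2] + 3 * _DIGIT[salt] + _DIGIT[dev]
    return raw - 1 if raw > 14 else raw


def cluster_pattern(index: int) -> tuple[int, int, int]:
    """Inverse of :func:`cluster_index` (1..26 -> ternary triple)."""
    if not 1 <= index <= 26:
        raise ValueError(f"cluster index {index} outside 1..26")
    raw = index + 1 if index >= 14 else index
    raw -= 1
    inv = {0: -1, 1: 0, 2: 1}
    return inv[raw % 3], inv[(raw // 3) % 3], inv[raw // 9]


@dataclass(frozen=True)
class ClusterAssignment:
    gene: str
    pattern: tuple[int, int, int]  # (dev, salt, h2o2)
    cluster: int | None  # 1..26, None iff pattern == (0, 0, 0)


def _settle_degenerate_p(p: np.ndarray, diffs: np.ndarray) -> np.ndarray:
    """Replace NaN t-test p-values from zero-variance genes.

    A zero-variance, nonzero difference is evidence as strong as it gets
    (p -> 0); zero variance with zero difference carries no evidence (p = 1).
    """
    p = p.copy()
    nan = ~np.isfinite(p)
    p[nan & (np.abs(diffs) > 0)] = 0.0
    p[nan & (np.abs(diffs) == 0)] = 1.0
    return p


def call_differential(
    expr: ExpressionSet,
    condition: str,
    fc_threshold: float = 1.0,
    alpha: float | None = 0.05,
) -> list[ResponseCall]:
    """Differential calls for one condition with the inclusive 2-fold rule.

    log2fc = mean(treated) - mean(control). The p-value comes from a
    paired t-test when both arms carry the same replicate labels (the
    replicated-design case), otherwise from a two-sample t-test; q is the
    BH-FDR over genes. ``code = sign(log2fc)`` when ``|log2fc| >=
    fc_threshold`` and (if ``alpha`` is not None) ``q <= alpha``.

    ``alpha=None`` disables the significance gate, reproducing pure
    fold-change classification.
    """
    if condition not in expr.conditions():
        raise KeyError(f"unknown condition {condition!r}")
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    treated = expr.arm(condition, "treated")
    control = expr.arm(condition, "control")
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError(
            f"condition {condition!r} needs >=2 replicates per arm "
            f"(got {treated.shape[1]} treated, {control.shape[1]} control)"
        )
    t_arr, c_arr = treated.to_numpy(float), control.to_numpy(float)
    log2fc = t_arr.mean(axis=1) - c_arr.mean(axis=1)

    meta = expr.samples
    t_reps = sorted(meta.loc[treated.columns, "replicate"])
    c_reps = sorted(meta.loc[control.columns, "replicate"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if t_reps == c_reps:
            res = stats.ttest_rel(t_arr, c_arr, axis=1)
        else:
            res = stats.ttest_ind(t_arr, c_arr, axis=1)
    p = _settle_degenerate_p(np.asarray(res.pvalue, dtype=float), log2fc)
    q = bh_fdr(p)

    codes = np.where(np.abs(log2fc) >= fc_threshold, np.sign(log2fc), 0).astype(int)
    if alpha is not None:
        codes[q > alpha] = 0
    return [
        ResponseCall(g, condition, float(log2fc[i]), float(p[i]), float(q[i]), int(codes[i]))
        for i, g in enumerate(expr.genes)
    ]


def combine_h2o2(
    calls_1h: list[ResponseCall], calls_5h: list[ResponseCall]
) -> list[ResponseCall]:
    """Combine the 1-h and 5-h peroxide calls with the and/or rule.

    Non-zero if either sampling time is non-zero; concordant non-zero
    codes keep their sign; discordant codes resolve to the sign of the
    larger |log2fc| and are flagged.
    """
    by_1h = {c.gene: c for c in calls_1h}
    by_5h = {c.gene: c for c in calls_5h}
    if set(by_1h) != set(by_5h):
        missing = set(by_1h) ^ set(by_5h)
        raise ValueError(f"gene universes differ between timepoints (e.g. {sorted(missing)[:3]})")
    out = []
    for gene in by_1h:
        a, b = by_1h[gene], by_5h[gene]
        discordant = False
        if a.code == 0 and b.code == 0:
            chosen = a if abs(a.log2fc) >= abs(b.log2fc) else b
            code = 0
        elif a.code != 0 and b.code != 0 and a.code != b.code:
            chosen = a if abs(a.log2fc) >= abs(b.log2fc) else b
            code = chosen.code
            discordant = True
        else:
            chosen = a if a.code != 0 else b
            code = chosen.code
        out.append(
            ResponseCall(
                gene, "h2o2", chosen.log2fc, chosen.p, chosen.q, code, discordant
            )
        )
    return out


def assign_clusters(codes: pd.DataFrame) -> list[ClusterAssignment]:
    """Assign each gene its 1..26 cluster from a (dev, salt, h2o2) code table.

    ``codes`` must have columns ``developmental``, ``salt``, ``h2o2``
    holding ternary values; the all-zero pattern maps to ``cluster=None``.
    """
    out = []
    for gene, row in codes.iterrows():
        pattern = (int(row["developmental"]), int(row["salt"]), int(row["h2o2"]))
        out.append(ClusterAssignment(str(gene), pattern, cluster_index(*pattern)))
    return out


@dataclass(frozen=True)
class OverlapStats:
    n_a: int
    n_b: int
    n_intersection: int
    pct_of_a: float  # |A & B| / |A| as a percentage
    chi2_p: float
    fisher_p: float


def overlap_stats(set_a: set, set_b: set, universe: set) -> OverlapStats:
    """Set overlap with independence tests on the implied 2x2 table."""
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - len(set_a | set_b)
    table = np.array([[a, b], [c, d]])
    if set_a:
        pct = 100.0 * a / len(set_a)
    else:
        pct = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            chi2_p = float(stats.chi2_contingency(table).pvalue)
        except ValueError:  # a zero margin: independence test undefined
            chi2_p = float("nan")
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return OverlapStats(len(set_a), len(set_b), a, pct, chi2_p, fisher_p)
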