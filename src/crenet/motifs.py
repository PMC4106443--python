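"""Motif discovery in promoter sets by ZOOPS expectation-maximization.

The site model is ZOOPS — zero or one occurrence per sequence: with
probability ``lambda`` a sequence carries exactly one motif instance at a
uniformly chosen offset, otherwise it is pure background. EM alternates a
per-sequence posterior over {no site, site at each offset} with
re-estimation of the position probability matrix and of ``lambda``;
``lambda`` is capped so the expected total number of sites never exceeds
``max_sites``. Candidate models are summarized as IUPAC consensus
patterns and compared to a catalogue of known cis-regulatory elements by
ungapped column alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .scan import IUPAC_SETS, reverse_complement

__all__ = [
    "MotifModel",
    "zoops_em",
    "discover_motifs",
    "consensus_iupac",
    "match_known",
    "MotifMatch",
    "PLANT_CRE_CATALOGUE",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGT"

#: Small catalogue of well-characterized plant promoter elements used by the
#: examples and the pipeline's motif-annotation step.
PLANT_CRE_CATALOGUE: tuple[tuple[str, str], ...] = (
    ("G-box", "CACGTG"),
    ("ABRE-core", "ACGTGGC"),
    ("W-box", "TTGACC"),
    ("GCC-box", "GCCGCC"),
    ("DRE/CRT", "RCCGAC"),
    ("TELO-box", "AAACCCTA"),
    ("site-II", "TGGGCY"),
)


def _encode(seqs: Mapping[str, str]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Integer-encode sequences into a padded matrix (pad/N -> 4)."""
    ids = list(seqs)
    if not ids:
        raise ValueError("empty promoter set")
    lengths = np.array([len(seqs[g]) for g in ids])
    X = np.full((len(ids), int(lengths.max())), 4, dtype=np.int8)
    for i, g in enumerate(ids):
        row = [_BASE_INDEX.get(b, 4) for b in seqs[g].upper()]
        X[i, : len(row)] = row
    return ids, X, lengths


def _background_from(X: np.ndarray) -> np.ndarray:
    counts = np.bincount(X[X < 4].ravel(), minlength=4).astype(float)
    if counts.sum() == 0:
        raise ValueError("sequences contain no A/C/G/T bases")
    counts[counts == 0] = 0.5  # keep log-odds finite on skewed inputs
    return counts / counts.sum()


def _seed_theta(word: str, confidence: float = 0.85) -> np.ndarray:
    theta = np.full((4, len(word)), (1.0 - confidence) / 3.0)
    for k, b in enumerate(word.upper()):
        theta[_BASE_INDEX[b], k] = confidence
    return theta


@dataclass
class MotifModel:
    """Converged ZOOPS motif model.

    ``theta`` is the 4 x w position probability matrix (rows A, C, G, T),
    ``lam`` the per-sequence site prior, ``score`` the per-column
    log-likelihood ratio of the model against pure background (comparable
    across widths), and ``sites`` the hard calls at posterior > 0.5.
    """

    width: int
    theta: np.ndarray
    lam: float
    background: np.ndarray
    sites: list[tuple[str, int, float]]
    score: float
    log_likelihood: float
    ll_trace: list[float] = field(default_factory=list, repr=False)
    n_iter: int = 0

    @property
    def consensus(self) -> str:
        """Modal word: the most probable base at every column."""
        return "".join(_BASES[i] for i in self.theta.argmax(axis=0))


def zoops_em(
    seqs: Mapping[str, str],
    width: int,
    init: str | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
    max_sites: int = 10,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-3,
) -> MotifModel:
    """Fit one ZOOPS motif model by EM from a given start.

    ``init`` is either a seed word of length ``width`` (converted to a
    near-deterministic starting matrix) or a 4 x ``width`` probability
    matrix. The 0-order background defaults to the base composition of
    the input set. Stops when the relative log-likelihood change drops
    below ``tol`` or after ``max_iter`` iterations; the log likelihood is
    non-decreasing across iterations (EM guarantee).
    """
    ids, X, lengths = _encode(seqs)
    n, l_max = X.shape
    w = int(width)
    if w < 1:
        raise ValueError("width must be positive")
    if w > lengths.min():
        raise ValueError(
            f"motif width {w} exceeds shortest sequence ({int(lengths.min())})"
        )
    if isinstance(init, str):
        if len(init) != w:
            raise ValueError("seed word length must equal width")
        theta = _seed_theta(init)
    else:
        theta = np.asarray(init, dtype=float).copy()
        if theta.shape != (4, w):
            raise ValueError(f"init matrix must be 4 x {w}")
        theta = theta / theta.sum(axis=0, keepdims=True)
    bg = _background_from(X) if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    real = X[X < 4]
    if real.size and np.ptp(real) == 0:
        import warnings

        warnings.warn("zero-entropy input: motif model is degenerate", UserWarning)

    m_max = l_max - w + 1
    m_i = (lengths - w + 1).astype(float)  # valid offsets per sequence
    lam_cap = min(1.0, max_sites / n)
    lam = min(0.5, lam_cap)

    # constant background log-likelihood of every sequence
    log_bg = np.log(bg)
    ll_bg_per_seq = np.array(
        [log_bg[X[i, X[i] < 4]].sum() for i in range(n)]
    )
    ll_bg_total = float(ll_bg_per_seq.sum())

    def window_scores(th: np.ndarray) -> np.ndarray:
        """Log likelihood-ratio of a site at each offset, -inf where invalid."""
        lr = np.full((5, w), -np.inf)
        lr[:4] = np.log(th) - log_bg[:, None]
        s = np.zeros((n, m_max))
        for k in range(w):
            s += lr[X[:, k : k + m_max], k]
        return s

    ll_trace: list[float] = []
    z = np.zeros((n, m_max))
    prev_ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        s = window_scores(theta)
        # E-step in log space: mix (1-lam) background with lam/m_i per offset
        with np.errstate(divide="ignore"):
            log_prior_site = np.where(m_i > 0, np.log(lam) - np.log(m_i), -np.inf)
        lam = min(lam, 1.0 - 1e-12)
        a = s + log_prior_site[:, None]  # log weight of each offset
        log_no_site = np.log1p(-lam)
        a_max = np.maximum(a.max(axis=1), log_no_site)
        a_max = np.where(np.isfinite(a_max), a_max, 0.0)
        denom = np.exp(log_no_site - a_max) + np.exp(a - a_max[:, None]).sum(axis=1)
        z = np.exp(a - a_max[:, None]) / denom[:, None]
        p_site = z.sum(axis=1)
        ll = float((np.log(denom) + a_max).sum()) + ll_bg_total
        ll_trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll

        # M-step
        lam = float(min(p_site.mean(), lam_cap))
        lam = max(lam, 1e-12)
        counts = np.zeros((5, w))
        zr = z.ravel()
        for k in range(w):
            counts[:, k] = np.bincount(
                X[:, k : k + m_max].ravel(), weights=zr, minlength=5
            )[:5]
        c = counts[:4] + pseudocount * bg[:, None]
        theta = c / c.sum(axis=0, keepdims=True)

    sites = [
        (ids[i], int(j), float(z[i, j]))
        for i in range(n)
        for j in (np.argmax(z[i]),)
        if z[i, j] > 0.5
    ]
    score = (ll_trace[-1] - ll_bg_total) / w
    return MotifModel(
        width=w,
        theta=theta,
        lam=lam,
        background=bg,
        sites=sites,
        score=float(score),
        log_likelihood=float(ll_trace[-1]),
        ll_trace=ll_trace,
        n_iter=it,
    )


def _seed_words(
    seqs: Mapping[str, str], width: int, n_starts: int, min_seqs: int = 2
) -> list[str]:
    """Data-driven starting words: w-mers present in >= min_seqs sequences,
    ranked by the number of sequences containing them (deterministic)."""
    counter: Counter[str] = Counter()
    for seq in seqs.values():
        seen = set()
        seq = seq.upper()
        for j in range(len(seq) - width + 1):
            word = seq[j : j + width]
            if "N" not in word and word not in seen:
                seen.add(word)
                counter[word] += 1
    ranked = sorted(
        (w_ for w_, c in counter.items() if c >= min_seqs),
        key=lambda w_: (-counter[w_], w_),
    )
    return ranked[:n_starts]


def discover_motifs(
    seqs: Mapping[str, str],
    widths: Sequence[int] = tuple(range(6, 13)),
    n_motifs: int = 1,
    max_sites: int = 10,
    n_starts: int = 30,
    screen_iters: int = 30,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> list[MotifModel]:
    """Iteratively discover motifs, masking each one's sites in turn.

    For each requested motif, EM is run from the top data-driven seed
    words at every width; starts are screened with a short EM and the
    best-scoring candidate is refined to convergence. Called sites are
    then masked (replaced by N) before the next motif is sought, so
    reported motifs never overlap. Models come back ranked by score.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    working = {g: s.upper() for g, s in seqs.items()}
    models: list[MotifModel] = []
    for _ in range(n_motifs):
        best: MotifModel | None = None
        for w in widths:
            if w > min(len(s) for s in working.values()):
                continue
            for word in _seed_words(working, w, n_starts):
                cand = zoops_em(
                    working, w, word, tol=tol, max_iter=screen_iters, max_sites=max_sites
                )
                if best is None or cand.score > best.score:
                    best = cand
        if best is None:
            break
        best = zoops_em(
            working, best.width, best.theta, tol=tol, max_iter=max_iter, max_sites=max_sites
        )
        models.append(best)
        for gene, off, _ in best.sites:
            s = working[gene]
            working[gene] = s[:off] + "N" * best.width + s[off + best.width :]
    return sorted(models, key=lambda m: -m.score)


_SET_TO_SYM = {frozenset(v): k for k, v in IUPAC_SETS.items()}


def consensus_iupac(model: MotifModel | np.ndarray, cover: float = 0.25) -> str:
    """Minimal IUPAC pattern covering all bases with frequency >= ``cover``.

    A uniform column (all four bases qualifying) becomes ``N``. Because
    every column sums to one, at least one base always qualifies at the
    default threshold.
    """
    theta = model.theta if isinstance(model, MotifModel) else np.asarray(model, float)
    out = []
    for col in theta.T:
        bases = frozenset(_BASES[i] for i in range(4) if col[i] >= cover)
        if not bases:  # cover > 0.25 can empty a column; fall back to the mode
            bases = frozenset(_BASES[int(np.argmax(col))])
        out.append(_SET_TO_SYM[bases])
    return "".join(out)


def _pattern_to_ppm(pattern: str) -> np.ndarray:
    cols = []
    for sym in pattern.upper():
        allowed = IUPAC_SETS[sym]
        col = np.array([1.0 if b in allowed else 0.0 for b in _BASES])
        cols.append(col / col.sum())
    return np.stack(cols, axis=1)


def _rc_ppm(ppm: np.ndarray) -> np.ndarray:
    # reverse columns and swap A<->T, C<->G rows
    return ppm[[3, 2, 1, 0], ::-1]


def _column_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _best_alignment(cand: np.ndarray, ref: np.ndarray, min_overlap: int) -> tuple[float, int]:
    w1, w2 = cand.shape[1], ref.shape[1]
    best, best_off = -np.inf, 0
    for off in range(-(w2 - min_overlap), w1 - min_overlap + 1):
        lo1, hi1 = max(0, off), min(w1, off + w2)
        if hi1 - lo1 < min_overlap:
            continue
        cols = [
            _column_corr(cand[:, k], ref[:, k - off]) for k in range(lo1, hi1)
        ]
        score = float(np.mean(cols))
        if score > best:
            best, best_off = score, off
    return best, best_off


@dataclass(frozen=True)
class MotifMatch:
    name: str
    score: float
    offset: int
    orientation: str  # "+" or "-"
    p: float


def match_known(
    model: MotifModel | np.ndarray,
    catalogue: Sequence[tuple[str, str | np.ndarray]] = PLANT_CRE_CATALOGUE,
    min_overlap: int = 4,
    n_shuffles: int = 200,
    seed: int = 0,
) -> MotifMatch:
    """Best ungapped alignment of a candidate motif against known CREs.

    Each catalogue entry (IUPAC pattern or 4 x w PPM) is scored in both
    orientations by the mean per-column Pearson correlation of
    probability vectors over the aligned overlap. Significance is an
    empirical p-value against column-shuffled catalogue motifs.
    """
    if not catalogue:
        raise ValueError("empty motif catalogue")
    cand = model.theta if isinstance(model, MotifModel) else np.asarray(model, float)
    refs = [
        (name, _pattern_to_ppm(p) if isinstance(p, str) else np.asarray(p, float))
        for name, p in catalogue
    ]

    def best_over(refs_mats) -> tuple[float, str, int, str]:
        top = (-np.inf, "", 0, "+")
        for name, ppm in refs_mats:
            for orient, mat in (("+", ppm), ("-", _rc_ppm(ppm))):
                sc, off = _best_alignment(cand, mat, min_overlap)
                if sc > top[0]:
                    top = (sc, name, off, orient)
        return top

    obs_score, name, offset, orient = best_over(refs)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_shuffles):
        shuffled = [
            (nm, ppm[:, rng.permutation(ppm.shape[1])]) for nm, ppm in refs
        ]
        if best_over(shuffled)[0] >= obs_score - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_shuffles)
    return MotifMatch(name, float(obs_score), offset, orient, float(p))
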