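"""Absolute-ranked gene set enrichment analysis with permutation statistics.

Genes are ranked by a two-class differential-expression metric
(signal-to-noise by default).  In *absolute* mode the list is ordered by
the magnitude of the metric, so up- and down-regulated members of a set
both enrich at the top of the list — appropriate when a pathway is
perturbed in both directions.  A weighted Kolmogorov–Smirnov running sum
gives each set an enrichment score (ES); a phenotype-permutation null
yields the normalized score (NES), nominal p, permutation FDR q, and
FWER p; the leading edge (members at or before the running-sum peak)
feeds the downstream frequency scoring.

The running sum walks the ranked list: at a member ("hit") of set S it
rises by |score|^p / N_R (N_R = sum of member weights); at a non-member
("miss") it falls by 1/(N − n_S).  ES is the excursion of maximal
magnitude; with exponent p = 0 this reduces to the classic KS statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .containers import ExpressionMatrix, GeneSetCollection

__all__ = [
    "RankedList",
    "GseaConfig",
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "permutation_statistics",
    "leading_edge_stats",
    "significant_sets",
]

logger = logging.getLogger(__name__)

METRICS = ("s2n", "t_like", "log2_ratio")

# when the positive and negative running-sum extrema tie in magnitude the
# positive one wins; the comparison uses an absolute tolerance so that
# exact ties are not resolved by floating-point summation-order noise
TIE_EPS = 1e-9


@dataclass
class RankedList:
    """Genes ordered by non-increasing score.

    In absolute mode the stored score is the magnitude of the underlying
    metric; ties are broken by gene symbol so the ordering is total.
    """

    genes: tuple[str, ...]
    scores: np.ndarray
    absolute_mode: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be sorted non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaConfig:
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    permutation_mode: str = "phenotype"  # or "gene_set"
    min_set_size: int = 15
    max_set_size: int = 500
    alpha_nom: float = 0.05
    fdr_cut: float = 0.25
    metric: str = "s2n"
    absolute_mode: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (1 <= self.min_set_size <= self.max_set_size):
            raise ValueError("require 1 <= min_set_size <= max_set_size")
        if self.permutation_mode not in ("phenotype", "gene_set"):
            raise ValueError(f"unknown permutation_mode {self.permutation_mode!r}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")


@dataclass
class EnrichmentResult:
    """One row of the per-collection enrichment report."""

    set_name: str
    size: int
    es: float
    nes: float = math.nan
    nom_p: float = math.nan
    fdr_q: float = math.nan
    fwer_p: float = math.nan
    tag_pct: float = math.nan
    gene_pct: float = math.nan
    signal: float = math.nan
    leading_edge: tuple[str, ...] = field(default_factory=tuple)
    peak_rank: int = 0


# ---------------------------------------------------------------------------
# ranking metrics


def _class_stats(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = X[:, mask]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    return mu, sd


def _floor_sigma(sd: np.ndarray, mu: np.ndarray) -> np.ndarray:
    # classical low-variance fix: sigma >= 0.2|mu|, and >= 0.2 when mu = 0
    floor = 0.2 * np.abs(mu)
    floor = np.where(floor == 0, 0.2, floor)
    return np.maximum(sd, floor)


def _metric_scores(X: np.ndarray, disease_mask: np.ndarray, metric: str) -> np.ndarray:
    mu_d, sd_d = _class_stats(X, disease_mask)
    mu_c, sd_c = _class_stats(X, ~disease_mask)
    if metric == "s2n":
        return (mu_d - mu_c) / (_floor_sigma(sd_d, mu_d) + _floor_sigma(sd_c, mu_c))
    if metric == "t_like":
        nd, nc = disease_mask.sum(), (~disease_mask).sum()
        sd_d = _floor_sigma(sd_d, mu_d)
        sd_c = _floor_sigma(sd_c, mu_c)
        return (mu_d - mu_c) / np.sqrt(sd_d**2 / nd + sd_c**2 / nc)
    if metric == "log2_ratio":
        return mu_d - mu_c  # difference of log2 means = log2 ratio
    raise ValueError(metric)


def rank_genes(
    gene_matrix: ExpressionMatrix,
    absolute_mode: bool = True,
    metric: str = "s2n",
) -> RankedList:
    """Rank genes by a two-class differential metric (log2-track input).

    Signal-to-noise: s_g = (mu_D - mu_C) / (sigma_D + sigma_C), each class
    standard deviation floored at 0.2|mu| (0.2 when mu = 0).  In absolute
    mode genes are ordered by |s_g| descending and the stored score is
    |s_g|; ties break by gene symbol.
    """
    dis, ctl = gene_matrix.classes
    for label in (dis, ctl):
        if (gene_matrix.phenotype == label).sum() < 2:
            raise ValueError(f"class {label!r} has < 2 samples; cannot rank")
    X = gene_matrix.values.to_numpy(dtype=float)
    mask = (gene_matrix.phenotype == dis).to_numpy()
    s = _metric_scores(X, mask, metric)
    key = np.abs(s) if absolute_mode else s
    genes = np.asarray(gene_matrix.row_ids, dtype=object)
    order = np.lexsort((genes, -key))
    return RankedList(tuple(genes[order]), key[order], absolute_mode)


# ---------------------------------------------------------------------------
# enrichment score


def enrichment_score(
    ranked: RankedList, members, p: float = 1.0
) -> tuple[float, np.ndarray, int, tuple[str, ...]]:
    """Weighted-KS enrichment score of *members* against the ranked list.

    Returns ``(ES, running_sum, peak_rank, leading_edge)`` where
    ``running_sum[i]`` is the walk value after rank i+1 and ``peak_rank``
    is the 1-based rank of the ES extremum.  For positive ES the leading
    edge is the members at ranks <= peak_rank; for negative ES, at ranks
    >= peak_rank.  When the extrema tie in magnitude the positive one
    wins.
    """
    member_set = set(members)
    genes = ranked.genes
    N = len(genes)
    hit_mask = np.fromiter((g in member_set for g in genes), dtype=bool, count=N)
    n_s = int(hit_mask.sum())
    if n_s == 0 or n_s == N:
        raise ValueError(f"degenerate set: {n_s} of {N} ranked genes are members")

    w = np.abs(ranked.scores) ** p
    w = np.where(hit_mask, w, 0.0)
    n_r = w.sum()
    if n_r == 0:  # all member weights zero (e.g. zero scores); fall back to equal
        w = hit_mask.astype(float)
        n_r = float(n_s)
    miss = 1.0 / (N - n_s)
    steps = w / n_r - np.where(hit_mask, 0.0, miss)
    running = np.cumsum(steps)

    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    hi, lo = running[i_max], running[i_min]
    if hi + lo >= -TIE_EPS:
        es, peak = float(hi), i_max + 1
    else:
        es, peak = float(lo), i_min + 1

    if es > 0:
        leading = tuple(g for i, g in enumerate(genes) if hit_mask[i] and i + 1 <= peak)
    elif es < 0:
        leading = tuple(g for i, g in enumerate(genes) if hit_mask[i] and i + 1 >= peak)
    else:
        leading, peak = (), 0
    return es, running, peak, leading


def _es_sparse(positions: np.ndarray, weights: np.ndarray, N: int) -> float:
    """ES from sorted 0-based member ranks only (permutation fast path).

    The running sum rises only at hits and falls linearly between them,
    so its maximum sits just after some hit and its minimum just before
    some hit (or at the flat ends, where it is 0).
    """
    m = positions.size
    n_r = weights.sum()
    if n_r == 0:
        cw = np.arange(1, m + 1, dtype=float) / m
    else:
        cw = np.cumsum(weights) / n_r
    miss = 1.0 / (N - m)
    drop = (positions - np.arange(m)) * miss  # misses strictly before each hit
    v_after = cw - drop
    v_before = np.concatenate(([0.0], cw[:-1])) - drop
    hi = max(v_after.max(), 0.0)
    lo = min(v_before.min(), 0.0)
    return float(hi) if hi + lo >= -TIE_EPS else float(lo)


# ---------------------------------------------------------------------------
# permutation machinery


def _disease_masks_exhaustive(n: int, n_d: int, observed: np.ndarray):
    """All C(n, n_d) disease-index assignments except the observed one."""
    obs = frozenset(np.flatnonzero(observed))
    masks = []
    for combo in combinations(range(n), n_d):
        if frozenset(combo) == obs:
            continue
        m = np.zeros(n, dtype=bool)
        m[list(combo)] = True
        masks.append(m)
    return masks


def _ranked_positions(key: np.ndarray, genes: np.ndarray) -> np.ndarray:
    """rank (0-based) of each gene index under (key desc, symbol asc)."""
    order = np.lexsort((genes, -key))
    rank_of = np.empty(len(key), dtype=np.intp)
    rank_of[order] = np.arange(len(key))
    return rank_of


def permutation_statistics(
    gene_matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    cfg: GseaConfig | None = None,
) -> list[EnrichmentResult]:
    """Full enrichment analysis of a collection against a two-class cohort.

    Phenotype mode reshuffles class labels and recomputes the ranking per
    permutation; when the requested permutation count reaches the number
    of distinct label splits, the null is enumerated exhaustively
    (observed labeling excluded).  Gene-set mode keeps the observed
    ranking and resamples member positions.  Nominal p uses +1 smoothing
    within the sign class of the observed ES; NES divides ES by the mean
    magnitude of same-sign permutation scores; FDR q follows the pooled
    permutation-NES procedure with a cumulative-minimum monotonicity pass;
    FWER p compares against the per-permutation extreme NES.  Results are
    sorted by nominal p.
    """
    cfg = cfg or GseaConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = np.asarray(gene_matrix.row_ids, dtype=object)
    N = len(genes)
    coll = collection.restrict(genes, cfg.min_set_size, cfg.max_set_size)
    if len(coll) == 0:
        return []

    X = gene_matrix.values.to_numpy(dtype=float)
    dis = gene_matrix.classes[0]
    obs_mask = (gene_matrix.phenotype == dis).to_numpy()
    gene_idx = {g: i for i, g in enumerate(genes)}
    member_idx = [np.array([gene_idx[g] for g in s.members], dtype=np.intp) for s in coll]

    def set_scores(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = _metric_scores(X, mask, cfg.metric)
        key = np.abs(s) if cfg.absolute_mode else s
        return key, np.abs(s)

    # observed ranking and per-set observed ES with full running-sum detail
    key_obs, _ = set_scores(obs_mask)
    order = np.lexsort((genes, -key_obs))
    ranked_obs = RankedList(tuple(genes[order]), key_obs[order], cfg.absolute_mode)
    observed: list[EnrichmentResult] = []
    for s in coll:
        es, _run, peak, leading = enrichment_score(ranked_obs, s.members, cfg.weight_exponent)
        res = EnrichmentResult(s.name, len(s.members), es, leading_edge=leading, peak_rank=peak)
        res.tag_pct, res.gene_pct, res.signal = leading_edge_stats(res, N)
        observed.append(res)

    # permutation ES matrix: sets × permutations
    if cfg.permutation_mode == "phenotype":
        n = len(obs_mask)
        n_d = int(obs_mask.sum())
        total_splits = math.comb(n, n_d)
        if cfg.n_permutations >= total_splits - 1:
            masks = _disease_masks_exhaustive(n, n_d, obs_mask)
            logger.info(
                "exhaustive phenotype enumeration: %d distinct splits (requested %d)",
                len(masks), cfg.n_permutations,
            )
        else:
            masks = []
            for _ in range(cfg.n_permutations):
                m = np.zeros(n, dtype=bool)
                m[rng.choice(n, size=n_d, replace=False)] = True
                masks.append(m)
        n_perm = len(masks)
        es_perm = np.empty((len(coll), n_perm))
        for j, mask in enumerate(masks):
            key, absolute = set_scores(mask)
            rank_of = _ranked_positions(key, genes)
            abs_ranked = absolute[np.lexsort((genes, -key))]
            for k, idx in enumerate(member_idx):
                pos = np.sort(rank_of[idx])
                w = abs_ranked[pos] ** cfg.weight_exponent
                es_perm[k, j] = _es_sparse(pos, w, N)
    else:  # gene_set mode: fixed ranking, resampled member positions
        n_perm = cfg.n_permutations
        abs_ranked = np.abs(ranked_obs.scores)
        es_perm = np.empty((len(coll), n_perm))
        for j in range(n_perm):
            for k, idx in enumerate(member_idx):
                pos = np.sort(rng.choice(N, size=idx.size, replace=False))
                w = abs_ranked[pos] ** cfg.weight_exponent
                es_perm[k, j] = _es_sparse(pos, w, N)

    _attach_permutation_stats(observed, es_perm)
    observed.sort(key=lambda r: (r.nom_p, -abs(r.nes) if np.isfinite(r.nes) else 0, r.set_name))
    return observed


def _attach_permutation_stats(results: list[EnrichmentResult], es_perm: np.ndarray) -> None:
    """Fill nom_p, NES, FDR q and FWER p in place from the null ES matrix."""
    n_sets, _n_perm = es_perm.shape

    pos_mean = np.array([
        es_perm[k][es_perm[k] >= 0].mean() if np.any(es_perm[k] >= 0) else np.nan
        for k in range(n_sets)
    ])
    neg_mean = np.array([
        np.abs(es_perm[k][es_perm[k] < 0]).mean() if np.any(es_perm[k] < 0) else np.nan
        for k in range(n_sets)
    ])

    # per-set nominal p and NES within the observed sign class
    for k, res in enumerate(results):
        perms = es_perm[k]
        if res.es >= 0:
            same = perms[perms >= 0]
            count = int((same >= res.es).sum())
            denom = pos_mean[k]
        else:
            same = perms[perms < 0]
            count = int((np.abs(same) >= abs(res.es)).sum())
            denom = neg_mean[k]
        res.nom_p = (1 + count) / (1 + same.size)
        res.nes = res.es / denom if np.isfinite(denom) and denom > 0 else 0.0

    # normalized null NES, each permutation value scaled by its own set's
    # same-sign mean magnitude
    with np.errstate(invalid="ignore", divide="ignore"):
        nes_perm = np.where(
            es_perm >= 0, es_perm / pos_mean[:, None], es_perm / neg_mean[:, None]
        )
    nes_perm = nes_perm[np.isfinite(nes_perm)]
    pos_null = nes_perm[nes_perm >= 0]
    neg_null = nes_perm[nes_perm < 0]
    obs_nes = np.array([r.nes for r in results])
    pos_obs = obs_nes[obs_nes >= 0]
    neg_obs = obs_nes[obs_nes < 0]

    for res in results:
        if res.nes >= 0:
            num = (pos_null >= res.nes).mean() if pos_null.size else 0.0
            den = (pos_obs >= res.nes).mean()
        else:
            num = (neg_null <= res.nes).mean() if neg_null.size else 0.0
            den = (neg_obs <= res.nes).mean()
        res.fdr_q = min(1.0, num / den) if den > 0 else 1.0

    # monotone coherence: a stronger |NES| never gets a larger q (cumulative
    # minimum from the weakest set upward, per sign class)
    for sign in (1, -1):
        side = [r for r in results if (r.nes >= 0) == (sign == 1)]
        side.sort(key=lambda r: abs(r.nes), reverse=True)  # strongest first
        for i in range(len(side) - 2, -1, -1):
            side[i].fdr_q = min(side[i].fdr_q, side[i + 1].fdr_q)

    # FWER: distribution of the per-permutation extreme normalized score
    with np.errstate(invalid="ignore", divide="ignore"):
        full_nes_perm = np.where(
            es_perm >= 0, es_perm / pos_mean[:, None], es_perm / neg_mean[:, None]
        )
    pos_filled = np.where(full_nes_perm >= 0, full_nes_perm, -np.inf)
    neg_filled = np.where(full_nes_perm < 0, full_nes_perm, np.inf)
    max_pos = pos_filled.max(axis=0)
    min_neg = neg_filled.min(axis=0)
    max_pos = np.where(np.isfinite(max_pos), max_pos, np.nan)
    min_neg = np.where(np.isfinite(min_neg), min_neg, np.nan)
    for res in results:
        if res.nes >= 0:
            valid = max_pos[np.isfinite(max_pos)]
            res.fwer_p = float((valid >= res.nes).mean()) if valid.size else 1.0
        else:
            valid = min_neg[np.isfinite(min_neg)]
            res.fwer_p = float((valid <= res.nes).mean()) if valid.size else 1.0


def leading_edge_stats(result: EnrichmentResult, N: int) -> tuple[float, float, float]:
    """(tag %, gene %, signal) of a scored set within a universe of N genes.

    tag = leading-edge fraction of the set; gene = fractional position of
    the running-sum peak (measured from the relevant end of the list);
    signal = tag · (1 − gene) · N/(N − size).
    """
    if result.es == 0 or not result.leading_edge:
        return 0.0, 0.0, 0.0
    tag = len(result.leading_edge) / result.size
    if result.es > 0:
        gene = result.peak_rank / N
    else:
        gene = (N - result.peak_rank + 1) / N
    signal = tag * (1.0 - gene) * N / (N - result.size)
    return tag, gene, signal


def significant_sets(
    results: list[EnrichmentResult], cfg: GseaConfig | None = None
) -> list[EnrichmentResult]:
    """Sets with nominal p strictly below alpha and FDR q at or below the
    cut, preserving the nominal-p ordering."""
    cfg = cfg or GseaConfig()
    return [r for r in results if r.nom_p < cfg.alpha_nom and r.fdr_q <= cfg.fdr_cut]
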