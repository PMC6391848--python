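"""Pre-ranked gene-set enrichment analysis (GSEA).

Genes are ranked by a per-gene score (default: log2 fold change, stage2 vs
stage1).  For each gene set the classic weighted Kolmogorov–Smirnov running
sum yields an enrichment score ES; significance comes from gene-label
permutations (set membership randomized over the ranked list, sizes
preserved): NES = ES / mean(|null ES| of the same sign), a same-sign nominal
p, and an FDR q from the pooled null-NES distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Gene ids with ranking scores in descending order.

    Ties break deterministically: by score descending, then id ascending.
    """

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate gene ids in ranked list")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class GseaResult:
    name: str
    size: int
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: list[str] = field(default_factory=list)


def rank_genes(de_records, metric: str = "log2fc") -> RankedList:
    """Descending ranked list from DE records by the chosen metric."""
    seen = set()
    for r in de_records:
        if r.id in seen:
            raise ValueError(f"duplicate gene id {r.id!r}")
        seen.add(r.id)
    keyed = [(float(getattr(r, metric)), r.id) for r in de_records]
    if not all(np.isfinite(s) for s, _ in keyed):
        raise ValueError("ranking scores must be finite")
    keyed.sort(key=lambda t: (-t[0], t[1]))
    return RankedList(ids=[i for _, i in keyed], scores=np.array([s for s, _ in keyed]))


def _es_from_hits(scores: np.ndarray, hit: np.ndarray, weight: float):
    """Running sum and signed extreme deviation for one hit-indicator vector."""
    w = np.abs(scores) ** weight
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores zero: fall back to uniform hit weight
        hit_w = hit.astype(float)
        total = hit_w.sum()
    n_miss = len(scores) - int(hit.sum())
    p_hit = np.cumsum(hit_w) / total
    p_miss = np.cumsum(~hit) / n_miss
    running = p_hit - p_miss
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running, idx


def enrichment_score(
    ranked: RankedList,
    gene_set: set[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score of a gene set on a ranked list.

    Hits advance the running sum by |score|^weight (normalized over hits),
    misses retreat by 1/(N - Nh); ES is the extreme deviation, sign
    preserved.  The leading edge contains the set members at or before the
    extremum (at or after it for negative ES).
    """
    hit = np.array([g in gene_set for g in ranked.ids])
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if nh == len(ranked):
        raise ValueError("gene set equals the entire ranked list")
    es, running, idx = _es_from_hits(ranked.scores, hit, weight)
    if es >= 0:
        leading = [g for g, h in zip(ranked.ids[: idx + 1], hit[: idx + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.ids[idx:], hit[idx:]) if h]
    return es, running, leading


def _null_es(scores: np.ndarray, set_size: int, n_perm: int, weight: float,
             rng: np.random.Generator) -> np.ndarray:
    """Null ES distribution from random same-size membership draws, vectorized."""
    N = len(scores)
    w = np.abs(scores) ** weight
    out = np.empty(n_perm)
    # vectorized over permutations: (n_perm, N) hit indicator
    ranks = np.argsort(rng.random((n_perm, N)), axis=1)[:, :set_size]
    hit = np.zeros((n_perm, N), dtype=bool)
    np.put_along_axis(hit, ranks, True, axis=1)
    hit_w = np.where(hit, w, 0.0)
    totals = hit_w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        hit_w[zero] = hit[zero].astype(float)
        totals = hit_w.sum(axis=1, keepdims=True)
    p_hit = np.cumsum(hit_w, axis=1) / totals
    p_miss = np.cumsum(~hit, axis=1) / (N - set_size)
    running = p_hit - p_miss
    idx = np.argmax(np.abs(running), axis=1)
    out[:] = running[np.arange(n_perm), idx]
    return out


def significance(
    ranked: RankedList,
    sets: dict[str, tuple[str, list[str]]] | dict[str, set[str]],
    n_perm: int = 1000,
    rng_seed: int = 0,
    weight: float = 1.0,
    min_perm: int = 100,
) -> list[GseaResult]:
    """Permutation NES, nominal p and FDR q for each gene set.

    Deterministic under a fixed seed.  The FDR follows the standard
    NES-pooling procedure: the null-tail fraction over all sets' normalized
    null ES divided by the observed-tail fraction, clamped to [0, 1] and made
    monotone in |NES| within each sign.
    """
    if n_perm < min_perm:
        raise ValueError(f"n_perm must be >= {min_perm}")
    rng = np.random.default_rng(rng_seed)
    names = sorted(sets)
    observed: dict[str, tuple[float, list[str], int]] = {}
    null_by_set: dict[str, np.ndarray] = {}
    for name in names:
        members = sets[name]
        if isinstance(members, tuple):
            members = members[1]
        members = set(members) & set(ranked.ids)
        if not members:
            logger.warning("set %s does not intersect the ranked list; skipped", name)
            continue
        if len(members) >= len(ranked):
            raise ValueError(f"set {name} is not smaller than the ranked list")
        es, _, leading = enrichment_score(ranked, members, weight=weight)
        observed[name] = (es, leading, len(members))
        null_by_set[name] = _null_es(ranked.scores, len(members), n_perm, weight, rng)

    results: list[GseaResult] = []
    pooled_null_nes: list[np.ndarray] = []
    for name in observed:
        es, leading, size = observed[name]
        null = null_by_set[name]
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        same = null[null >= 0] if es >= 0 else null[null < 0]
        denom = pos_mean if es >= 0 else neg_mean
        nes = 0.0 if not np.isfinite(denom) or denom == 0 else es / denom
        if len(same) == 0:
            p = 1.0
        else:
            p = float((np.abs(same) >= abs(es)).sum() / len(same))
        null_nes = np.where(
            null >= 0,
            null / pos_mean if np.isfinite(pos_mean) and pos_mean > 0 else 0.0,
            null / neg_mean if np.isfinite(neg_mean) and neg_mean > 0 else 0.0,
        )
        pooled_null_nes.append(null_nes)
        results.append(GseaResult(name=name, size=size, es=es, nes=float(nes),
                                  nominal_p=p, fdr_q=1.0, leading_edge=leading))

    if results:
        pool = np.concatenate(pooled_null_nes)
        obs_nes = np.array([r.nes for r in results])
        for r in results:
            if r.nes >= 0:
                null_tail = (pool >= r.nes).mean()
                obs_tail = (obs_nes >= r.nes).mean()
            else:
                null_tail = (pool <= r.nes).mean()
                obs_tail = (obs_nes <= r.nes).mean()
            q = null_tail / obs_tail if obs_tail > 0 else 1.0
            r.fdr_q = float(min(1.0, max(0.0, q)))
        # monotone in |NES| within each sign: more extreme never has larger q
        # (each set takes the min q over less-or-equally extreme sets, as in
        # step-up adjustments)
        for sign in (1, -1):
            side = [r for r in results if (r.nes >= 0) == (sign == 1)]
            side.sort(key=lambda r: abs(r.nes))
            best = np.inf
            for r in side:
                best = min(best, r.fdr_q)
                r.fdr_q = best
    return sorted(results, key=lambda r: (r.nominal_p, -abs(r.nes), r.name))


def write_gsea_results(results: list[GseaResult], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("set\tsize\tes\tnes\tnominal_p\tfdr_q\tleading_edge\n")
        for r in results:
            fh.write(
                f"{r.name}\t{r.size}\t{r.es:.6g}\t{r.nes:.6g}\t{r.nominal_p:.6g}"
                f"\t{r.fdr_q:.6g}\t{';'.join(r.leading_edge)}\n"
            )


def read_ranked_list(path: str | Path) -> RankedList:
    ids, scores = [], []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, score = line.split("\t")[:2]
            if gene == "gene":
                continue
            ids.append(gene)
            scores.append(float(score))
    keyed = sorted(zip(scores, ids), key=lambda t: (-t[0], t[1]))
    return RankedList(ids=[i for _, i in keyed], scores=np.array([s for s, _ in keyed]))
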