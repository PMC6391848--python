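"""Gene-set term enrichment with kappa grouping of enriched terms.

Statistics follow the clique-annotation convention of term-enrichment
plug-ins: a two-sided hypergeometric test per term (doubled smaller tail,
capped at 1), a Bonferroni step-down (Holm) correction over terms, and
grouping of the retained terms into functional groups by connecting term
pairs whose gene-membership agreement (Cohen's kappa over the background
universe) reaches a threshold, 0.4 by default.  lncRNA function is inferred
by annotation transfer through the ceRNA triplets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from scipy.stats import hypergeom

from .triplets import CeRNATriplet

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe.

    Members outside the universe are dropped with a warning; the default
    universe is the union of all set members.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    @classmethod
    def from_sets(
        cls,
        sets: dict[str, tuple[str, list[str]]],
        universe: set[str] | None = None,
    ) -> "GeneSetCollection":
        if universe is None:
            universe = set()
            for _, members in sets.values():
                universe |= set(members)
        clean: dict[str, tuple[str, frozenset[str]]] = {}
        for name, (desc, members) in sets.items():
            kept = frozenset(members) & frozenset(universe)
            dropped = len(set(members)) - len(kept)
            if dropped:
                logger.warning("%d members of set %s outside the universe; dropped", dropped, name)
            if not kept:
                logger.warning("set %s empty after universe restriction; dropped", name)
                continue
            clean[name] = (desc, kept)
        return cls(sets=clean, universe=frozenset(universe))

    @classmethod
    def from_gmt(cls, path: str | Path, universe: set[str] | None = None) -> "GeneSetCollection":
        sets: dict[str, tuple[str, list[str]]] = {}
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
                sets[parts[0]] = (parts[1], parts[2:])
        return cls.from_sets(sets, universe=universe)


@dataclass
class EnrichmentResult:
    term: str
    overlap: list[str]
    k: int  # overlap size
    K: int  # term size
    n: int  # query size
    N: int  # universe size
    p_raw: float
    p_adj: float
    group_id: int | None = None


def hypergeom_two_sided(query_n: int, term_n: int, overlap_k: int, universe_N: int) -> float:
    """Two-sided hypergeometric p: doubled smaller tail, capped at 1.

    Under X ~ Hypergeometric(N, K=term_n, n=query_n), combines the upper tail
    P(X >= k) and the lower tail P(X <= k).
    """
    if not (0 <= overlap_k <= min(query_n, term_n)):
        raise ValueError("overlap must satisfy 0 <= k <= min(query, term)")
    if max(query_n, term_n) > universe_N:
        raise ValueError("query and term must fit in the universe")
    upper = float(hypergeom.sf(overlap_k - 1, universe_N, term_n, query_n))
    lower = float(hypergeom.cdf(overlap_k, universe_N, term_n, query_n))
    return min(1.0, 2.0 * min(upper, lower))


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Bonferroni step-down (Holm) adjustment, returned in the input order."""
    m = len(pvalues)
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * pvalues[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted


def kappa_score(term_a: set[str], term_b: set[str], universe: set[str]) -> float:
    """Cohen's kappa between two terms' membership indicators over the universe."""
    if not term_a or not term_b:
        raise ValueError("terms must be non-empty")
    if not (term_a <= universe and term_b <= universe):
        raise ValueError("terms must be subsets of the universe")
    N = len(universe)
    n11 = len(term_a & term_b)
    n00 = N - len(term_a | term_b)
    p_o = (n11 + n00) / N
    pa, pb = len(term_a) / N, len(term_b) / N
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    p_adj_cutoff: float = 0.05,
    kappa_threshold: float = 0.4,
) -> list[EnrichmentResult]:
    """Two-sided hypergeometric enrichment of a gene query with kappa grouping.

    Query genes outside the universe are dropped (logged).  Terms with
    Holm-adjusted p <= cutoff are retained and linked when their pairwise
    kappa reaches the threshold; ``group_id`` labels the connected components
    of that term–term graph.
    """
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    universe = set(collection.universe)
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside the universe; dropped", len(outside))
    query = query & universe
    N, n = len(universe), len(query)

    names = sorted(collection.sets)
    results = []
    for name in names:
        _, members = collection.sets[name]
        overlap = sorted(query & members)
        p = hypergeom_two_sided(n, len(members), len(overlap), N)
        results.append(
            EnrichmentResult(term=name, overlap=overlap, k=len(overlap), K=len(members),
                             n=n, N=N, p_raw=p, p_adj=1.0)
        )
    adjusted = holm_adjust([r.p_raw for r in results])
    for r, padj in zip(results, adjusted):
        r.p_adj = padj

    retained = [r for r in results if r.p_adj <= p_adj_cutoff]
    g = nx.Graph()
    g.add_nodes_from(r.term for r in retained)
    for i, a in enumerate(retained):
        for b in retained[i + 1:]:
            ka = kappa_score(set(collection.sets[a.term][1]), set(collection.sets[b.term][1]), universe)
            if ka >= kappa_threshold:
                g.add_edge(a.term, b.term)
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    group_of = {term: gid for gid, comp in enumerate(components, start=1) for term in comp}
    for r in retained:
        r.group_id = group_of[r.term]
    return sorted(retained, key=lambda r: (r.p_adj, r.p_raw, r.term))


def annotate_lncrnas(
    triplets: list[CeRNATriplet],
    results: list[EnrichmentResult],
) -> dict[str, list[str]]:
    """Transfer enriched terms to lncRNAs through shared triplet miRNAs.

    A lncRNA inherits every enriched term carried (via the enrichment
    overlap) by an mRNA that shares a miRNA with it in the triplet set.
    """
    terms_of_gene: dict[str, set[str]] = {}
    for r in results:
        for gene in r.overlap:
            terms_of_gene.setdefault(gene, set()).add(r.term)
    lnc_by_mirna: dict[str, set[str]] = {}
    genes_by_mirna: dict[str, set[str]] = {}
    for t in triplets:
        lnc_by_mirna.setdefault(t.mirna_id, set()).add(t.lncrna_id)
        genes_by_mirna.setdefault(t.mirna_id, set()).add(t.mrna_id)
    annotation: dict[str, set[str]] = {}
    for m, lncs in lnc_by_mirna.items():
        terms: set[str] = set()
        for gene in genes_by_mirna.get(m, ()):
            terms |= terms_of_gene.get(gene, set())
        for ln in lncs:
            annotation.setdefault(ln, set()).update(terms)
    return {ln: sorted(terms) for ln, terms in annotation.items()}


def write_enrichment(results: list[EnrichmentResult], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("term\tk\tK\tn\tN\tp_raw\tp_adj\tgroup_id\toverlap\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p_raw:.6g}\t{r.p_adj:.6g}"
                f"\t{r.group_id if r.group_id is not None else ''}\t{';'.join(r.overlap)}\n"
            )


def write_lncrna_annotation(annotation: dict[str, list[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("lncrna_id\tterms\n")
        for ln in sorted(annotation):
            fh.write(f"{ln}\t{';'.join(annotation[ln])}\n")
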