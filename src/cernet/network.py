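"""Tripartite ceRNA network: construction, centralities, degree-distribution
power law and between-class centrality comparison.

Conventions follow the common network-analyzer definitions: raw (unnormalized)
degree, unordered-pair betweenness without normalization, and closeness
restricted to a node's connected component.  The scale-free check is an OLS
line on log10 N(k) vs log10 k over the observed degree histogram, reporting
slope and R^2; a maximum-likelihood exponent is available as a secondary,
clearly labeled estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DERecord
from .triplets import CeRNATriplet

logger = logging.getLogger(__name__)


@dataclass
class PowerLawFit:
    slope: float
    r_squared: float
    n_points: int


@dataclass
class KWResult:
    metric: str
    h_statistic: float
    df: int
    pvalue: float


def build_network(
    triplets: list[CeRNATriplet],
    de_records: list[DERecord],
) -> nx.Graph:
    """Graph with typed nodes (class, regulation direction) and the triplet edges.

    Nodes are the union of triplet members; edges are the lncRNA–miRNA and
    miRNA–mRNA pairs of each triplet, deduplicated.  Every node must have a
    DE record supplying its up/down direction.
    """
    by_id = {r.id: r for r in de_records}
    g = nx.Graph()
    for t in triplets:
        for node, cls in ((t.lncrna_id, "lncRNA"), (t.mirna_id, "miRNA"), (t.mrna_id, "mRNA")):
            if node not in by_id:
                raise ValueError(f"triplet member {node!r} has no DE record")
            g.add_node(node, rna_class=cls, direction=by_id[node].direction)
        g.add_edge(t.lncrna_id, t.mirna_id, interaction="lncRNA-miRNA")
        g.add_edge(t.mirna_id, t.mrna_id, interaction="miRNA-mRNA")
    return g


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Raw edge count per node (unnormalized degree)."""
    return {n: int(d) for n, d in net.degree()}


def betweenness_centrality(net: nx.Graph) -> dict[str, float]:
    """Unnormalized betweenness over unordered node pairs."""
    return nx.betweenness_centrality(net, normalized=False)


def closeness_centrality(net: nx.Graph) -> dict[str, float]:
    """(nodes reachable) / (sum of shortest-path distances), per component."""
    return nx.closeness_centrality(net, wf_improved=False)


def centrality_table(net: nx.Graph) -> pd.DataFrame:
    """DataFrame indexed by node with columns dc, bc, cc, class, direction."""
    dc = degree_centrality(net)
    bc = betweenness_centrality(net)
    cc = closeness_centrality(net)
    rows = {
        n: {
            "rna_class": net.nodes[n].get("rna_class"),
            "direction": net.nodes[n].get("direction"),
            "dc": dc[n],
            "bc": bc[n],
            "cc": cc[n],
        }
        for n in net.nodes
    }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def degree_histogram(net: nx.Graph) -> pd.DataFrame:
    """Columns k, n_k: number of nodes at each observed degree k > 0."""
    degs = np.array([d for _, d in net.degree()], dtype=int)
    ks, counts = np.unique(degs[degs > 0], return_counts=True)
    return pd.DataFrame({"k": ks, "n_k": counts})


def fit_power_law(net_or_hist: nx.Graph | pd.DataFrame) -> PowerLawFit:
    """OLS fit of log10 N(k) on log10 k over the degree histogram.

    N(k) is the number of nodes with degree k (only k with N(k) > 0 enter).
    The slope is the fitted scale-free exponent and R^2 is computed on the
    logarithmized values.  Requires >= 2 distinct degree values.
    """
    hist = net_or_hist if isinstance(net_or_hist, pd.DataFrame) else degree_histogram(net_or_hist)
    hist = hist[hist["n_k"] > 0]
    if len(hist) < 2:
        raise ValueError("power-law fit requires >= 2 distinct degree values")
    x = np.log10(hist["k"].to_numpy(dtype=float))
    y = np.log10(hist["n_k"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid ** 2).sum()) / ss_tot
    return PowerLawFit(slope=float(slope), r_squared=r2, n_points=len(hist))


def power_law_mle_exponent(net: nx.Graph, k_min: int = 1) -> float:
    """Secondary estimate: discrete MLE of the exponent alpha in P(k) ~ k^-alpha."""
    degs = np.array([d for _, d in net.degree() if d >= k_min], dtype=float)
    if len(degs) == 0:
        raise ValueError("no degrees >= k_min")
    return 1.0 + len(degs) / float(np.log(degs / (k_min - 0.5)).sum())


def compare_centrality(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = ("dc", "bc", "cc"),
) -> list[KWResult]:
    """Kruskal–Wallis comparison of each centrality across RNA classes.

    Tie-corrected H with a chi-square p-value at df = (number of classes - 1).
    All-identical values across every group give H = 0, p = 1.
    """
    groups = [g for _, g in table.groupby("rna_class")]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 RNA classes")
    out = []
    for metric in metrics:
        samples = [g[metric].to_numpy(dtype=float) for g in groups]
        flat = np.concatenate(samples)
        if np.all(flat == flat[0]):
            out.append(KWResult(metric=metric, h_statistic=0.0, df=len(groups) - 1, pvalue=1.0))
            continue
        h, p = stats.kruskal(*samples)
        out.append(KWResult(metric=metric, h_statistic=float(h), df=len(groups) - 1, pvalue=float(p)))
    return out


def export_network(
    net: nx.Graph,
    path: str | Path,
    fmt: str,
    table: pd.DataFrame | None = None,
) -> None:
    """Write the network as SIF (tab-delimited), GraphML, or node-attribute TSV.

    GraphML carries class, direction and (when a centrality table is given)
    dc/bc/cc as node attributes and round-trips exactly through
    ``networkx.read_graphml``.
    """
    path = Path(path)
    if fmt == "sif":
        with path.open("w") as fh:
            for u, v, data in sorted(net.edges(data=True)):
                for node in (u, v):
                    if "\t" in node or "\n" in node:
                        raise ValueError(f"node id {node!r} cannot be written to SIF")
                fh.write(f"{u}\t{data.get('interaction', 'interacts')}\t{v}\n")
    elif fmt == "graphml":
        g = net.copy()
        if table is not None:
            for n in g.nodes:
                g.nodes[n]["dc"] = int(table.loc[n, "dc"])
                g.nodes[n]["bc"] = float(table.loc[n, "bc"])
                g.nodes[n]["cc"] = float(table.loc[n, "cc"])
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        if table is None:
            raise ValueError("node-attribute TSV export requires a centrality table")
        table.rename_axis("id").to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
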