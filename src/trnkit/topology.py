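"""Graph statistics of the inferred network and gene-architecture correlations.

Summary statistics (degree means/medians, diameter, clustering, degree
coefficient) are computed with networkx on the directed network and its
undirected projection. The degree coefficient is the Pearson correlation of
the undirected degrees at the two endpoints of each edge (both orientations
counted), which for a near-bipartite TF->target network measures whether
high-degree hubs attach to low-degree partners.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, RegulatoryNetwork, TrnkitError, warn


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_tfs: int
    n_targets: int
    mean_degree: float
    largest_degree: int
    mean_out_degree_tfs: float
    median_out_degree_tfs: float
    mean_in_degree_targets: float
    median_in_degree_targets: float
    diameter: int
    clustering_coefficient: float
    degree_coefficient: float

    def to_dict(self) -> dict:
        return asdict(self)


def _endpoint_degree_pairs(undirected: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    deg = dict(undirected.degree())
    xs, ys = [], []
    for u, v in undirected.edges():
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def degree_coefficient(net: RegulatoryNetwork) -> float:
    """Pearson correlation between the undirected degrees of edge endpoints.

    Undefined (returned as NaN with a warning) when endpoint degrees have zero
    variance, e.g. on a regular graph.
    """
    und = net.graph.to_undirected()
    xs, ys = _endpoint_degree_pairs(und)
    if xs.std() == 0 or ys.std() == 0:
        warn("degree coefficient undefined (zero degree variance); returning NaN")
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def summarize(net: RegulatoryNetwork) -> TopologySummary:
    """All headline statistics of the network in one pass.

    Diameter and clustering are computed on the undirected projection;
    the diameter on its largest connected component.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise TrnkitError("cannot summarize an empty network")
    und = g.to_undirected()
    tfs = sorted(net.tfs)
    targets = sorted(n for n, d in g.in_degree() if d > 0)
    out_deg = np.array([g.out_degree(t) for t in tfs], dtype=float)
    in_deg = np.array([g.in_degree(t) for t in targets], dtype=float)
    comp = max(nx.connected_components(und), key=len)
    diameter = nx.diameter(und.subgraph(comp))
    degrees = np.array([d for _, d in und.degree()], dtype=float)
    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_tfs=len(tfs),
        n_targets=len(targets),
        mean_degree=float(degrees.mean()),
        largest_degree=int(degrees.max()),
        mean_out_degree_tfs=float(out_deg.mean()),
        median_out_degree_tfs=float(np.median(out_deg)),
        mean_in_degree_targets=float(in_deg.mean()),
        median_in_degree_targets=float(np.median(in_deg)),
        diameter=int(diameter),
        clustering_coefficient=float(nx.average_clustering(und)),
        degree_coefficient=degree_coefficient(net),
    )


def degree_distribution(
    net: RegulatoryNetwork, bins: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact per-node degree table plus a log-binned histogram for plotting."""
    g = net.graph
    if g.number_of_edges() == 0:
        raise TrnkitError("empty network")
    table = pd.DataFrame(
        {
            "node": list(g.nodes),
            "in_degree": [g.in_degree(n) for n in g.nodes],
            "out_degree": [g.out_degree(n) for n in g.nodes],
        }
    ).set_index("node")
    degrees = (table["in_degree"] + table["out_degree"]).to_numpy()
    edges = np.unique(np.logspace(0, np.log10(degrees.max() + 1), bins + 1).round()).astype(int)
    counts, edges = np.histogram(degrees, bins=edges)
    hist = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})
    return table, hist


def dispersion_index(expr: ExpressionMatrix) -> pd.Series:
    """Per-gene dispersion std(Y_i)/mean(Y_i) (sample std, ddof=1).

    Genes with nonpositive mean are excluded with a warning: the ratio is not
    a meaningful variability index there.
    """
    vals = expr.values
    means = vals.mean(axis=1)
    ok = means > 0
    if (~ok).any():
        warn(f"{int((~ok).sum())} gene(s) with nonpositive mean excluded from dispersion")
    stds = vals.loc[ok].std(axis=1, ddof=1)
    return (stds / means[ok]).rename("dispersion")


def build_gene_architecture(
    expr: ExpressionMatrix, lengths: pd.Series
) -> pd.DataFrame:
    """Per-gene table of length, mean expression and dispersion."""
    disp = dispersion_index(expr)
    genes = expr.values.index.intersection(lengths.index)
    return pd.DataFrame(
        {
            "length": lengths.loc[genes],
            "mean_expression": expr.values.loc[genes].mean(axis=1),
            "dispersion": disp.reindex(genes),
        }
    )


def architecture_correlations(
    expr: ExpressionMatrix,
    net: RegulatoryNetwork,
    lengths: pd.Series,
) -> pd.DataFrame:
    """Pairwise Pearson correlations among gene length, regulator count
    |in_j|, mean expression, and expression dispersion.

    Restricted to network target genes shared by all three inputs; each row
    reports r, the two-sided p-value, and the n used.
    """
    arch = build_gene_architecture(expr, lengths)
    in_deg = {g: len(net.regulators(g)) for g in net.genes if net.regulators(g)}
    genes = [g for g in arch.index if g in in_deg]
    if len(genes) < 3:
        raise TrnkitError("fewer than 3 genes shared across expression, lengths and network")
    df = arch.loc[genes].copy()
    df["in_degree"] = [in_deg[g] for g in genes]
    variables = ["length", "in_degree", "mean_expression", "dispersion"]
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            sub = df[[a, b]].dropna()
            if sub[a].nunique() < 2 or sub[b].nunique() < 2:
                warn(f"correlation {a} vs {b} undefined (constant input)")
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(sub[a], sub[b])
            rows.append({"x": a, "y": b, "pearson_r": r, "p_value": p, "n": len(sub)})
    return pd.DataFrame(rows)
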