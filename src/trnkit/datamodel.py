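"""Shared domain types for the TRN annotation pipeline.

The pipeline moves through a small number of containers: an expression
matrix (genes x samples) with a designated transcription-factor subset, a
TF x gene lasso coefficient matrix, a weighted directed regulatory network,
a GO corpus (DAG + propagated annotations), and position weight matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

NUCLEOTIDES = "ACGT"

#: Treatment categories used when splitting the compendium into
#: condition-specific networks.
TREATMENT_CATEGORIES = (
    "abiotic stress",
    "biotic stress",
    "development",
    "hormone",
)


class TrnkitError(ValueError):
    """Base error for contract violations."""


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, one row per gene, one column per sample.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. Values are
        treated as given (no transform is applied on load).
    tf_ids
        Ordered subset of the gene index designating the TF feature set T.
    sample_category
        Optional map sample id -> treatment category (e.g. "abiotic stress").
    """

    values: pd.DataFrame
    tf_ids: list[str]
    sample_category: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise TrnkitError(f"duplicate gene ids: {dups[:5]}")
        if cols.duplicated().any():
            raise TrnkitError("duplicate sample ids")
        if len(cols) < 2:
            raise TrnkitError("need at least 2 samples")
        missing = [t for t in self.tf_ids if t not in idx]
        if missing:
            raise TrnkitError(f"tf_ids not in gene index: {missing[:5]}")
        if len(set(self.tf_ids)) != len(self.tf_ids):
            raise TrnkitError("duplicate tf ids")
        if self.values.isna().any().any():
            raise TrnkitError("expression matrix contains missing values")
        if self.sample_category is not None:
            unknown = set(self.sample_category) - set(cols)
            if unknown:
                raise TrnkitError(f"sample_category keys not in samples: {sorted(unknown)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_tf(self) -> int:
        return len(self.tf_ids)

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def tf_design(self) -> np.ndarray:
        """Return X, the (m x n_T) matrix of TF expression levels."""
        return self.values.loc[self.tf_ids].to_numpy().T

    def gene_response(self, gene: str) -> np.ndarray:
        """Return Y_j, the length-m expression vector of one gene."""
        if gene not in self.values.index:
            raise TrnkitError(f"unknown gene: {gene}")
        return self.values.loc[gene].to_numpy()

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        cat = None
        if self.sample_category is not None:
            cat = {s: self.sample_category[s] for s in samples if s in self.sample_category}
        return ExpressionMatrix(self.values[samples].copy(), list(self.tf_ids), cat)


@dataclass
class CoefficientMatrix:
    """The lasso coefficient matrix A (TFs x genes).

    ``values.loc[i, j]`` is a_ij, the fitted coefficient of TF i in the model
    for gene j. Self-entries a_jj are exactly zero by construction (the TF's
    own expression is masked when fitting its model).
    """

    values: pd.DataFrame
    lambda_used: float
    alpha: float | None = None
    r2: pd.Series | None = None

    def __post_init__(self) -> None:
        common = self.values.index.intersection(self.values.columns)
        for tf in common:
            if self.values.at[tf, tf] != 0.0:
                raise TrnkitError(f"self coefficient a_jj must be 0 for TF {tf}")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    def threshold(self, alpha: float) -> "CoefficientMatrix":
        """Return A*: entries kept iff |a_ij| >= alpha, others zeroed."""
        if alpha < 0:
            raise TrnkitError("alpha must be nonnegative")
        kept = self.values.where(self.values.abs() >= alpha, 0.0)
        return CoefficientMatrix(kept, self.lambda_used, alpha=alpha, r2=self.r2)

    def nonzero_edges(self) -> list[tuple[str, str, float]]:
        arr = self.values.to_numpy()
        rows, cols = np.nonzero(arr)
        idx, colnames = self.values.index, self.values.columns
        return [(idx[r], colnames[c], float(arr[r, c])) for r, c in zip(rows, cols)]


class RegulatoryNetwork:
    """Weighted directed TF -> target network G.

    Only nodes that carry at least one edge are members (singleton TFs and
    unregulated genes are excluded). Positive weights denote up-regulation,
    negative weights down-regulation.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]]):
        g = nx.DiGraph()
        for tf, target, w in edges:
            if w == 0:
                raise TrnkitError("zero-weight edge is not allowed")
            if tf == target:
                raise TrnkitError(f"self-loop edge {tf}->{target}")
            g.add_edge(tf, target, weight=float(w))
        self.graph = g

    @property
    def tfs(self) -> set[str]:
        """Nodes with at least one outgoing edge (the TF side)."""
        return {u for u, d in self.graph.out_degree() if d > 0}

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def regulators(self, gene: str) -> dict[str, float]:
        """in_j: TFs with an edge into ``gene``, with weights."""
        if gene not in self.graph:
            return {}
        return {u: d["weight"] for u, _, d in self.graph.in_edges(gene, data=True)}

    def targets(self, tf: str) -> dict[str, float]:
        """out_i: target pool of ``tf``, with weights."""
        if tf not in self.graph:
            return {}
        return {v: d["weight"] for _, v, d in self.graph.out_edges(tf, data=True)}

    def target_pools(self) -> dict[str, set[str]]:
        """Map TF -> out_i for every TF in the network."""
        return {tf: set(self.targets(tf)) for tf in self.tfs}

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        if self.edge_set() != other.edge_set():
            return False
        return all(
            abs(self.graph[u][v]["weight"] - other.graph[u][v]["weight"]) < 1e-12
            for u, v in self.graph.edges()
        )

    def __repr__(self) -> str:
        return (
            f"RegulatoryNetwork({len(self.tfs)} TFs, "
            f"{self.graph.number_of_nodes()} nodes, {self.n_edges} edges)"
        )


# GO relation -> Wang semantic contribution factor
RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class GOCorpus:
    """A GO biological-process corpus: term DAG plus propagated annotations.

    The DAG is stored with child -> parent edges, each carrying a
    ``relation`` attribute (``is_a`` or ``part_of``). Annotations are kept in
    closed (true-path) form: a gene annotated to a term is annotated to all
    of the term's ancestors. The enrichment universe is the set of genes with
    at least one annotation.
    """

    def __init__(self, dag: nx.DiGraph, direct_annotations: Mapping[str, Iterable[str]]):
        if not nx.is_directed_acyclic_graph(dag):
            raise TrnkitError("GO term graph must be acyclic")
        self.dag = dag
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        annotations: dict[str, frozenset[str]] = {}
        for gene, terms in direct_annotations.items():
            closed: set[str] = set()
            for t in terms:
                if t not in dag:
                    raise TrnkitError(f"annotated term {t} not in ontology")
                closed.add(t)
                closed.update(self._ancestors(t))
            if closed:
                annotations[gene] = frozenset(closed)
        self.annotations = annotations
        self.universe = frozenset(annotations)
        genes_for: dict[str, set[str]] = {}
        for gene, terms in annotations.items():
            for t in terms:
                genes_for.setdefault(t, set()).add(gene)
        self._genes_for = {t: frozenset(g) for t, g in genes_for.items()}
        self._matrix: tuple[list[str], list[str], sparse.csr_matrix] | None = None

    def _ancestors(self, term: str) -> frozenset[str]:
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.dag, term))  # edges point child->parent
            self._ancestor_cache[term] = cached
        return cached

    def ancestors(self, term: str) -> frozenset[str]:
        """All (strict) ancestors of a term via is_a/part_of edges."""
        if term not in self.dag:
            raise TrnkitError(f"term {term} not in ontology")
        return self._ancestors(term)

    @property
    def n_universe(self) -> int:
        return len(self.universe)

    def terms(self) -> list[str]:
        return list(self.dag.nodes)

    def genes_for(self, term: str) -> frozenset[str]:
        """Genes annotated (after propagation) to ``term``."""
        return self._genes_for.get(term, frozenset())

    def term_size(self, term: str) -> int:
        return len(self.genes_for(term))

    def presence_matrix(self) -> tuple[list[str], list[str], sparse.csr_matrix]:
        """(genes, terms, G x T boolean CSR) over annotated terms only."""
        if self._matrix is None:
            genes = sorted(self.universe)
            terms = sorted(self._genes_for)
            gene_idx = {g: i for i, g in enumerate(genes)}
            term_idx = {t: i for i, t in enumerate(terms)}
            rows, cols = [], []
            for g, ts in self.annotations.items():
                gi = gene_idx[g]
                for t in ts:
                    rows.append(gi)
                    cols.append(term_idx[t])
            mat = sparse.csr_matrix(
                (np.ones(len(rows), dtype=np.int32), (rows, cols)),
                shape=(len(genes), len(terms)),
            )
            self._matrix = (genes, terms, mat)
        return self._matrix


@dataclass
class PWM:
    """Position weight matrix: 4 x t column-stochastic nucleotide frequencies.

    Rows are ordered A, C, G, T. ``background`` holds the four background
    probabilities b_k (uniform by default).
    """

    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise TrnkitError("PWM matrix must be 4 x t with t >= 1")
        if (self.matrix < 0).any():
            raise TrnkitError("PWM frequencies must be nonnegative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise TrnkitError("PWM columns must sum to 1 (within 1e-6)")
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise TrnkitError("background must be 4 probabilities summing to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(NUCLEOTIDES[k] for k in self.matrix.argmax(axis=0))


@dataclass
class GeneArchitecture:
    """Per-gene structural/expression summary used in correlation analyses."""

    gene_id: str
    length: int
    mean_expression: float = float("nan")
    dispersion: float = float("nan")

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise TrnkitError(f"gene length must be positive ({self.gene_id})")


def warn(msg: str) -> None:
    warnings.warn(msg, UserWarning, stacklevel=3)
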