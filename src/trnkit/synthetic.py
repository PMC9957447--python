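"""Desk-scale synthetic fixtures with the statistical structure the method assumes.

The generator plants a sparse linear regulatory model: TF expression profiles
are i.i.d. standard normal across samples and every target gene is an exact
linear combination of a small random set of TFs plus Gaussian noise. Planted
weights are bounded away from zero (|w| >= 0.2 by default) so a documented
coefficient cutoff separates signal from lasso shrinkage noise. On top of the
expression model, promoters can carry planted binding motifs in the targets of
chosen TFs and a toy GO DAG can concentrate terms in those same target pools,
so that every downstream stage (network inference, enrichment, motif
discovery) has an exactly known ground truth.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import (
    NUCLEOTIDES,
    ExpressionMatrix,
    GOCorpus,
    PWM,
    RegulatoryNetwork,
    TrnkitError,
)


@dataclass
class PlantedModel:
    """Ground truth behind a synthetic dataset.

    ``true_A`` is the planted TF x gene coefficient matrix (self entries are
    zero); ``motif_plants`` maps TF -> (motif string, insertion probability
    pi); ``go_plants`` maps TF -> (term id, annotation probability rho).
    """

    true_A: pd.DataFrame
    noise_sd: float
    seed: int
    motif_plants: dict[str, tuple[str, float]] = field(default_factory=dict)
    go_plants: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        common = self.true_A.index.intersection(self.true_A.columns)
        for tf in common:
            if self.true_A.at[tf, tf] != 0.0:
                raise TrnkitError(f"planted self entry a_jj must be 0 (TF {tf})")
        for tf, (motif, pi) in self.motif_plants.items():
            if set(motif) - set(NUCLEOTIDES):
                raise TrnkitError(f"planted motif for {tf} not over ACGT")
            if not 0 <= pi <= 1:
                raise TrnkitError("insertion probability must be in [0,1]")
        for tf, (_, rho) in self.go_plants.items():
            if not 0 <= rho <= 1:
                raise TrnkitError("annotation probability must be in [0,1]")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.true_A.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.true_A.columns)

    def true_network(self, alpha: float = 0.0) -> RegulatoryNetwork:
        """Planted edge set under the same |a_ij| >= alpha thresholding rule
        the inference stage applies."""
        arr = self.true_A.to_numpy()
        rows, cols = np.nonzero(np.abs(arr) >= max(alpha, np.finfo(float).tiny))
        idx, colnames = self.true_A.index, self.true_A.columns
        return RegulatoryNetwork(
            (idx[r], colnames[c], float(arr[r, c])) for r, c in zip(rows, cols)
        )


def generate_expression(
    n_tf: int,
    n_genes: int,
    m: int,
    density: float,
    noise_sd: float,
    seed: int,
    *,
    weight_range: tuple[float, float] = (0.2, 1.0),
    signed: bool = True,
    tf_tf_density: float = 0.0,
    hub_tail: float | None = 1.5,
) -> tuple[ExpressionMatrix, PlantedModel]:
    """Simulate an expression compendium under a planted sparse linear model.

    Each of the ``n_genes - n_tf`` target genes receives ``ceil(density *
    n_tf)`` regulators chosen without replacement, with coefficients drawn
    from +/- Uniform(*weight_range*); its expression row is the weighted
    TF combination plus Normal(0, noise_sd**2) noise. TF rows are i.i.d.
    standard normal per sample (no TF->TF edges unless ``tf_tf_density`` > 0,
    in which case TF rows are built in index order from earlier TFs).

    Regulator choice is hub-biased by default: per-TF selection propensities
    are drawn from a Pareto(``hub_tail``) mixture, giving the heavy-tailed
    out-degree spectrum (few hub TFs with large target pools, many TFs with
    small ones) that real regulatory networks show. ``hub_tail=None`` selects
    regulators uniformly, making all target pools near-equal in size.
    """
    if not (n_genes >= n_tf >= 1):
        raise TrnkitError("need n_genes >= n_tf >= 1")
    if not (0 < density <= 1):
        raise TrnkitError("density must be in (0, 1]")
    if density * n_tf < 1:
        raise TrnkitError("each target needs >=1 regulator (density * n_tf < 1)")
    rng = np.random.default_rng(seed)
    n_targets = n_genes - n_tf
    k = math.ceil(density * n_tf)
    width = max(4, len(str(n_genes)))
    tf_ids = [f"TF{i:0{width}d}" for i in range(1, n_tf + 1)]
    target_ids = [f"G{i:0{width}d}" for i in range(1, n_targets + 1)]
    gene_ids = tf_ids + target_ids

    A = np.zeros((n_tf, n_genes))
    X = rng.standard_normal((n_tf, m))

    if tf_tf_density > 0:
        # TF j (j >= 1) may be regulated by earlier TFs; built in index order
        # so the planted model stays exactly linear and acyclic.
        for j in range(1, n_tf):
            n_reg = min(j, rng.binomial(j, tf_tf_density))
            if n_reg == 0:
                continue
            regs = rng.choice(j, size=n_reg, replace=False)
            w = rng.uniform(*weight_range, size=n_reg)
            if signed:
                w *= rng.choice([-1.0, 1.0], size=n_reg)
            A[regs, j] = w
            X[j] = w @ X[regs] + rng.normal(0.0, noise_sd, size=m)

    propensity = None
    if hub_tail is not None:
        propensity = 1.0 + rng.pareto(hub_tail, size=n_tf)
        propensity /= propensity.sum()
    for col in range(n_targets):
        regs = rng.choice(n_tf, size=k, replace=False, p=propensity)
        w = rng.uniform(*weight_range, size=k)
        if signed:
            w *= rng.choice([-1.0, 1.0], size=k)
        A[regs, n_tf + col] = w

    targets = A[:, n_tf:].T @ X
    if noise_sd > 0:
        targets = targets + rng.normal(0.0, noise_sd, size=(n_targets, m))
    values = pd.DataFrame(
        np.vstack([X, targets]),
        index=gene_ids,
        columns=[f"S{i:04d}" for i in range(1, m + 1)],
    )
    true_A = pd.DataFrame(A, index=tf_ids, columns=gene_ids)
    expr = ExpressionMatrix(values, tf_ids)
    return expr, PlantedModel(true_A=true_A, noise_sd=noise_sd, seed=seed)


def merge_expressions(parts: dict[str, ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate expression matrices sample-wise, labelling each block with
    its treatment category. Gene ids and TF sets must agree."""
    items = list(parts.items())
    base = items[0][1]
    frames, category = [], {}
    for idx, (cat, expr) in enumerate(items):
        if expr.gene_ids != base.gene_ids or expr.tf_ids != base.tf_ids:
            raise TrnkitError("expression blocks must share gene and TF ids")
        renamed = expr.values.add_suffix(f".{idx}")
        frames.append(renamed)
        category.update({s: cat for s in renamed.columns})
    return ExpressionMatrix(pd.concat(frames, axis=1), list(base.tf_ids), category)


# ---------------------------------------------------------------------------
# Motif and GO planting


def random_motif_plants(
    tf_ids: list[str], k: int = 7, pi: float = 0.5, seed: int = 0
) -> dict[str, tuple[str, float]]:
    """Assign each TF a distinct random k-mer to plant with probability pi."""
    rng = np.random.default_rng(seed)
    plants: dict[str, tuple[str, float]] = {}
    used: set[str] = set()
    for tf in tf_ids:
        while True:
            motif = "".join(NUCLEOTIDES[c] for c in rng.integers(0, 4, size=k))
            if motif not in used:
                used.add(motif)
                break
        plants[tf] = (motif, pi)
    return plants


def assign_go_plants(tf_ids: list[str], rho: float = 0.8) -> dict[str, tuple[str, float]]:
    """Assign each TF a dedicated toy BP term to plant with probability rho."""
    return {tf: (f"GO:P{i:04d}", rho) for i, tf in enumerate(tf_ids, start=1)}


def generate_promoters(
    model: PlantedModel,
    net: RegulatoryNetwork,
    length: int = 1577,
    seed: int = 0,
) -> dict[str, str]:
    """Promoter sequences for every gene in the universe.

    Background is i.i.d. uniform over ACGT; for each TF with a planted motif,
    each gene of its target pool receives one copy at a uniform random
    position with probability pi. The 1577 bp default matches the median
    promoter length of the Arabidopsis set the method was designed around.
    """
    rng = np.random.default_rng(seed)
    for tf, (motif, _) in model.motif_plants.items():
        if len(motif) >= length:
            raise TrnkitError(f"planted motif for {tf} not shorter than promoter length")
    alphabet = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.uint8)
    seqs = {
        g: alphabet[rng.integers(0, 4, size=length)].copy() for g in model.gene_ids
    }
    for tf in sorted(model.motif_plants):
        motif, pi = model.motif_plants[tf]
        planted = np.frombuffer(motif.encode(), dtype=np.uint8)
        for gene in sorted(net.targets(tf)):
            if rng.random() < pi:
                pos = int(rng.integers(0, length - len(motif) + 1))
                seqs[gene][pos : pos + len(motif)] = planted
    return {g: arr.tobytes().decode() for g, arr in seqs.items()}


def generate_go_corpus(
    model: PlantedModel,
    net: RegulatoryNetwork,
    n_terms: int = 120,
    seed: int = 0,
    *,
    background_rate: float = 0.01,
    part_of_every: int = 5,
    heterogeneous: bool = True,
    size_span: float = 400.0,
    program_size: int = 4,
) -> GOCorpus:
    """Toy biological-process corpus concentrated in planted target pools.

    Builds a DAG of one root, three branch terms, and ``n_terms`` leaf terms
    (is_a edges; every ``part_of_every``-th leaf attaches via part_of). Genes
    in out_i are annotated to TF i's planted term with probability rho; every
    gene additionally receives each leaf term independently at a background
    rate. By default the per-term background rates are heavy-tailed (Pareto
    mixture with mean ``background_rate``), mirroring the strongly skewed
    term-size distribution of real GO corpora — most terms annotate few
    genes, a handful are broad. ``heterogeneous=False`` uses the constant
    rate instead.

    A real regulon is enriched in several related processes, not one, and
    larger regulons span more of them. Each planted TF therefore receives a
    functional program: the planted (primary) term annotated across its whole
    target pool with probability rho, plus sibling terms ``<term>.1``,
    ``<term>.2``, ... each covering a dedicated ~``slice_size``-gene slice of
    the pool (at least ``program_size - 1`` slices). Slices are disjoint, so
    sibling terms behave like ordinary small terms for random gene sets —
    they enrich together only in the pool they were carved from. ``n_terms``
    counts the primary planted terms plus background leaves; program siblings
    are added on top. Annotations are propagated to ancestors.
    """
    slice_size = 40
    planted_terms = [term for term, _ in model.go_plants.values()]
    if n_terms < len(planted_terms):
        raise TrnkitError("n_terms smaller than the number of planted terms")
    rng = np.random.default_rng(seed)
    root = "GO:ROOT"
    branches = [f"GO:BR{b}" for b in (1, 2, 3)]
    programs: dict[str, list[str]] = {}
    for tf in sorted(model.go_plants):
        term, _ = model.go_plants[tf]
        pool = len(net.targets(tf))
        n_slices = max(program_size - 1, -(-pool // slice_size)) if pool else 0
        programs[term] = [f"{term}.{j}" for j in range(1, n_slices + 1)]
    leaves = [t for prog in programs.values() for t in prog] + planted_terms
    n_background = n_terms - len(planted_terms)
    for nxt in range(1, n_background + 1):
        leaves.append(f"GO:B{nxt:04d}")

    dag = nx.DiGraph()
    dag.add_node(root, name="biological process (root)")
    for b in branches:
        dag.add_edge(b, root, relation="is_a")
    for i, leaf in enumerate(leaves):
        rel = "part_of" if part_of_every and (i + 1) % part_of_every == 0 else "is_a"
        dag.add_edge(leaf, branches[i % 3], relation=rel)

    genes = model.gene_ids
    direct: dict[str, set[str]] = {g: set() for g in genes}
    if background_rate > 0:
        if heterogeneous:
            # Truncated-Pareto(alpha=1) term sizes (P(L >= x) ~ 1/x over a
            # ``size_span``-fold range), rescaled to mean background_rate and
            # capped at 0.3. Real GO corpora have this strongly skewed
            # spectrum; with an alpha ~ 1 tail the number of terms broad
            # enough to be enrichable grows roughly linearly with pool size,
            # which is the regime the linear null calibration assumes.
            raw = 1.0 / rng.uniform(1.0 / size_span, 1.0, size=len(leaves))
            rates = np.minimum(background_rate * raw / raw.mean(), 0.3)
        else:
            rates = np.full(len(leaves), background_rate)
        hits = rng.random((len(genes), len(leaves))) < rates
        for gi, g in enumerate(genes):
            for ti in np.nonzero(hits[gi])[0]:
                direct[g].add(leaves[ti])
    for tf in sorted(model.go_plants):
        term, rho = model.go_plants[tf]
        targets = sorted(net.targets(tf))
        for gene in targets:
            if rng.random() < rho:
                direct[gene].add(term)
        siblings = programs[term]
        if siblings:
            # round-robin partition of the pool into slices, one per sibling
            for pos, gene in enumerate(targets):
                if rng.random() < rho:
                    direct[gene].add(siblings[pos % len(siblings)])
    direct = {g: ts for g, ts in direct.items() if ts}
    return GOCorpus(dag, direct)


def generate_reference_pwms(
    model: PlantedModel,
    width: int = 11,
    conservation: float = 0.85,
    seed: int = 0,
) -> dict[str, PWM]:
    """Reference PWMs whose conserved core is each TF's planted motif.

    The planted k-mer is embedded at a random offset inside a ``width``-column
    matrix; core columns put ``conservation`` mass on the planted base and the
    remainder uniformly on the other three; flanking columns are uniform.
    """
    rng = np.random.default_rng(seed)
    pwms: dict[str, PWM] = {}
    for tf in sorted(model.motif_plants):
        motif, _ = model.motif_plants[tf]
        if width < len(motif):
            raise TrnkitError("PWM width shorter than planted motif")
        mat = np.full((4, width), 0.25)
        offset = int(rng.integers(0, width - len(motif) + 1))
        for c, base in enumerate(motif):
            col = np.full(4, (1.0 - conservation) / 3.0)
            col[NUCLEOTIDES.index(base)] = conservation
            mat[:, offset + c] = col
        pwms[tf] = PWM(mat, id=tf)
    return pwms


def generate_gene_lengths(
    gene_ids: list[str], seed: int = 0, mean_log: float = 7.8, sd_log: float = 0.6
) -> pd.Series:
    """Log-normal gene lengths (median ~2.4 kb, a plant-like distribution)."""
    rng = np.random.default_rng(seed)
    lengths = np.maximum(200, rng.lognormal(mean_log, sd_log, size=len(gene_ids))).astype(int)
    return pd.Series(lengths, index=gene_ids, name="length")
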