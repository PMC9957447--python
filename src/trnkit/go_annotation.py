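"""Functional annotation of TFs from their inferred target pools.

A TF inherits candidate biological-process functions from GO terms that are
over-represented in its target pool. Significance uses the EASE score, a
conservative variant of the one-sided Fisher / hypergeometric test in which
the observed overlap is penalized by one gene before taking the upper tail.
The number of significant terms per pool is calibrated against random pools
of the same size via linearly interpolated null curves (mu_k, sigma_k),
yielding a z-score per TF. Term specificity (1 / annotated-gene count) and
Wang graph-based semantic similarity support comparison against reference
annotations.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import GOCorpus, RELATION_WEIGHTS, TrnkitError, warn

#: minimum pool genes annotated to a term for the term to be tested
MIN_OVERLAP = 2


def ease_score(overlap: int, pool: int, term_total: int, universe: int) -> float:
    """EASE score: hypergeometric upper tail with the overlap penalized by one.

    Returns P(X >= overlap - 1) for X ~ Hypergeom(universe, term_total, pool);
    overlaps of 0 or 1 score 1 by construction.
    """
    if not (0 <= overlap <= min(pool, term_total) <= universe) or pool > universe:
        raise TrnkitError(
            f"inconsistent counts: overlap={overlap}, pool={pool}, "
            f"term_total={term_total}, universe={universe}"
        )
    if overlap <= 1:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 2, universe, term_total, pool))


def hypergeom_tail(overlap: int, pool: int, term_total: int, universe: int) -> float:
    """Plain upper-tail P(X >= overlap) (no EASE penalty)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, term_total, pool))


def _pool_term_overlaps(
    pool: Iterable[str], corpus: GOCorpus
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Vectorized (overlap, term_size) per annotated term for one pool."""
    genes, terms, mat = corpus.presence_matrix()
    gene_idx = {g: i for i, g in enumerate(genes)}
    rows = [gene_idx[g] for g in pool if g in gene_idx]
    mask = np.zeros(len(genes), dtype=np.int32)
    mask[rows] = 1
    overlaps = np.asarray(mask @ mat).ravel()
    sizes = np.asarray(mat.sum(axis=0)).ravel()
    return overlaps, sizes, terms, len(rows)


def _ease_vector(
    overlaps: np.ndarray, sizes: np.ndarray, pool_size: int, universe: int
) -> np.ndarray:
    p = np.ones(len(overlaps))
    testable = overlaps >= MIN_OVERLAP
    if testable.any():
        p[testable] = stats.hypergeom.sf(
            overlaps[testable] - 2, universe, sizes[testable], pool_size
        )
    return p


def enrich_pool(
    pool: Iterable[str], corpus: GOCorpus, threshold: float = 0.05
) -> pd.DataFrame:
    """EASE enrichment of every testable BP term in one target pool.

    Terms annotated to at least :data:`MIN_OVERLAP` pool genes are tested;
    records with EASE p <= threshold are returned sorted ascending, with
    Benjamini-Hochberg adjusted values (computed over the tested family)
    reported alongside.
    """
    pool = set(pool)
    cols = [
        "term", "overlap", "pool_size", "term_size", "universe",
        "ease_p", "bh_adjusted", "fold_enrichment",
    ]
    if not pool:
        warn("empty pool: no enrichment computed")
        return pd.DataFrame(columns=cols)
    extra = pool - corpus.universe
    if extra and pool <= extra:
        return pd.DataFrame(columns=cols)
    overlaps, sizes, terms, k = _pool_term_overlaps(pool, corpus)
    n = corpus.n_universe
    testable = overlaps >= MIN_OVERLAP
    if not testable.any():
        return pd.DataFrame(columns=cols)
    p = stats.hypergeom.sf(overlaps[testable] - 2, n, sizes[testable], k)
    bh = multipletests(p, method="fdr_bh")[1]
    fold = (overlaps[testable] / k) / (sizes[testable] / n)
    df = pd.DataFrame(
        {
            "term": np.asarray(terms)[testable],
            "overlap": overlaps[testable],
            "pool_size": k,
            "term_size": sizes[testable],
            "universe": n,
            "ease_p": p,
            "bh_adjusted": bh,
            "fold_enrichment": fold,
        }
    )
    df = df[df["ease_p"] <= threshold].sort_values("ease_p", kind="stable")
    return df.reset_index(drop=True)


def count_significant(pool: Iterable[str], corpus: GOCorpus, threshold: float = 0.05) -> int:
    """t(k): number of terms with raw EASE p <= threshold for this pool."""
    pool = set(pool)
    if not pool:
        return 0
    overlaps, sizes, _, k = _pool_term_overlaps(pool, corpus)
    p = _ease_vector(overlaps, sizes, k, corpus.n_universe)
    return int((p <= threshold).sum())


def default_null_sizes() -> list[int]:
    """floor(2^e) for e = 1.5, 2, 2.5, ..., 10 (18 sizes: 2, 4, 5, 8, 11, ...)."""
    return [int(np.floor(2.0**e)) for e in np.arange(1.5, 10.25, 0.5)]


@dataclass
class NullCurves:
    """Random-pool calibration: mean/sd of significant-term counts vs pool size."""

    sizes: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    mu_se: np.ndarray  # standard error of each empirical mean
    mu_slope: float
    mu_intercept: float
    sigma_slope: float
    sigma_intercept: float
    reps: int
    threshold: float

    def predict_mu(self, k: float) -> float:
        return self.mu_intercept + self.mu_slope * k

    def predict_sigma(self, k: float) -> float:
        return self.sigma_intercept + self.sigma_slope * k

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size": self.sizes, "mu": self.mu, "sigma": self.sigma, "mu_se": self.mu_se}
        )


def build_null_curves(
    corpus: GOCorpus,
    sizes: list[int] | None = None,
    reps: int = 100,
    threshold: float = 0.05,
    seed: int = 0,
) -> NullCurves:
    """Fit mu_k and sigma_k of random-pool significant-term counts as linear
    functions of the pool size k.

    For each size, ``reps`` uniform without-replacement gene samples are drawn
    from the universe and the significant-term count recorded; ordinary least
    squares then fits mean and standard deviation against k.
    """
    if sizes is None:
        sizes = default_null_sizes()
    if reps < 2:
        raise TrnkitError("reps must be >= 2")
    genes, _, mat = corpus.presence_matrix()
    n = len(genes)
    for k in sizes:
        if k > n:
            raise TrnkitError(f"sample size {k} exceeds universe {n}")
    rng = np.random.default_rng(seed)
    term_sizes = np.asarray(mat.sum(axis=0)).ravel()
    mus, sds, ses = [], [], []
    for k in sizes:
        counts = np.empty(reps, dtype=int)
        for r in range(reps):
            mask = np.zeros(n, dtype=np.int32)
            mask[rng.choice(n, size=k, replace=False)] = 1
            overlaps = np.asarray(mask @ mat).ravel()
            p = _ease_vector(overlaps, term_sizes, k, n)
            counts[r] = int((p <= threshold).sum())
        mus.append(counts.mean())
        sds.append(counts.std(ddof=1))
        ses.append(counts.std(ddof=1) / np.sqrt(reps))
    sizes_arr = np.asarray(sizes, dtype=float)
    mu_fit = stats.linregress(sizes_arr, mus)
    sigma_fit = stats.linregress(sizes_arr, sds)
    return NullCurves(
        sizes=sizes_arr,
        mu=np.asarray(mus),
        sigma=np.asarray(sds),
        mu_se=np.asarray(ses),
        mu_slope=float(mu_fit.slope),
        mu_intercept=float(mu_fit.intercept),
        sigma_slope=float(sigma_fit.slope),
        sigma_intercept=float(sigma_fit.intercept),
        reps=reps,
        threshold=threshold,
    )


def annotation_zscore(t_observed: int, pool_size: int, curves: NullCurves) -> float:
    """z = (t(k) - mu_hat(k)) / sigma_hat(k) from the fitted null curves.

    NaN (with a warning) when the predicted sigma is nonpositive; a TF is
    called significantly annotated downstream when z >= 2.
    """
    sigma = curves.predict_sigma(pool_size)
    if sigma <= 0:
        warn(f"predicted sigma at k={pool_size} is nonpositive; z undefined")
        return float("nan")
    return float((t_observed - curves.predict_mu(pool_size)) / sigma)


Z_SIGNIFICANT = 2.0


def specificity(terms: str | Iterable[str], corpus: GOCorpus) -> float:
    """Specificity c of a term (1 / annotated-gene count, DAG-propagated) or
    of a term set (max over members)."""
    if isinstance(terms, str):
        size = corpus.term_size(terms)
        if size == 0:
            raise TrnkitError(f"term {terms} has no annotated genes; specificity undefined")
        return 1.0 / size
    terms = list(terms)
    if not terms:
        raise TrnkitError("specificity of an empty term set is undefined")
    return max(specificity(t, corpus) for t in terms)


# ---------------------------------------------------------------------------
# Wang graph-based semantic similarity


def _s_values(term: str, corpus: GOCorpus) -> dict[str, float]:
    """Semantic contributions of ``term``'s ancestors (max over paths of the
    product of edge factors; S(term) = 1)."""
    if term not in corpus.dag:
        raise TrnkitError(f"term {term} not in ontology")
    s = {term: 1.0}
    heap = [(-1.0, term)]
    while heap:
        neg, node = heapq.heappop(heap)
        val = -neg
        if val < s.get(node, 0.0):
            continue
        for _, parent, data in corpus.dag.out_edges(node, data=True):
            w = RELATION_WEIGHTS.get(data.get("relation", "is_a"), 0.8)
            cand = val * w
            if cand > s.get(parent, 0.0):
                s[parent] = cand
                heapq.heappush(heap, (-cand, parent))
    return s


def wang_term_similarity(a: str, b: str, corpus: GOCorpus) -> float:
    """Wang similarity of two terms: shared-ancestor S-values from both sides
    over the two semantic totals."""
    sa, sb = _s_values(a, corpus), _s_values(b, corpus)
    common = set(sa) & set(sb)
    if not common:
        return 0.0
    return sum(sa[t] + sb[t] for t in common) / (sum(sa.values()) + sum(sb.values()))


def wang_similarity(
    terms_a: Iterable[str], terms_b: Iterable[str], corpus: GOCorpus
) -> float:
    """Best-match-average Wang similarity between two term sets."""
    ta, tb = list(dict.fromkeys(terms_a)), list(dict.fromkeys(terms_b))
    if not ta or not tb:
        raise TrnkitError("both term sets must be nonempty")
    sim = np.array([[wang_term_similarity(a, b, corpus) for b in tb] for a in ta])
    return float((sim.max(axis=1).sum() + sim.max(axis=0).sum()) / (len(ta) + len(tb)))


# ---------------------------------------------------------------------------
# Per-network drivers and reference comparison


def annotate_network(
    pools: Mapping[str, set[str]],
    corpus: GOCorpus,
    threshold: float = 0.05,
    curves: NullCurves | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enrich every TF's target pool; returns (records, per-TF summary).

    The summary carries t(k), the z-score against ``curves`` (if given) and
    the specificity of the predicted term set.
    """
    records, summary = [], []
    for tf in sorted(pools):
        df = enrich_pool(pools[tf], corpus, threshold=threshold)
        df.insert(0, "tf", tf)
        records.append(df)
        t_k = len(df)
        k = len(pools[tf])
        z = annotation_zscore(t_k, k, curves) if curves is not None else float("nan")
        spec = specificity(df["term"].tolist(), corpus) if t_k else float("nan")
        summary.append(
            {
                "tf": tf,
                "pool_size": k,
                "n_significant_terms": t_k,
                "z_score": z,
                "z_significant": bool(z >= Z_SIGNIFICANT) if np.isfinite(z) else False,
                "specificity": spec,
            }
        )
    nonempty = [df for df in records if not df.empty]
    rec_df = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=["tf", "term", "overlap", "pool_size", "term_size",
                                   "universe", "ease_p", "bh_adjusted", "fold_enrichment"])
    )
    return rec_df, pd.DataFrame(summary)


def compare_with_reference(
    predicted: Mapping[str, Iterable[str]],
    reference: Mapping[str, Iterable[str]],
    corpus: GOCorpus,
    trivial_terms: set[str] | None = None,
) -> pd.DataFrame:
    """Per-TF comparison of predicted vs reference BP annotations.

    Reports the exact term overlap, Wang set similarity, both specificities,
    and term counts. TFs whose reference annotation consists solely of
    ``trivial_terms`` (e.g. the bare regulation-of-transcription term) are
    flagged ``trivially_annotated``.
    """
    trivial_terms = trivial_terms or set()
    rows = []
    for tf in sorted(set(predicted) | set(reference)):
        pred = set(predicted.get(tf, ()))
        ref = set(reference.get(tf, ()))
        sim = wang_similarity(pred, ref, corpus) if pred and ref else float("nan")
        rows.append(
            {
                "tf": tf,
                "n_predicted": len(pred),
                "n_reference": len(ref),
                "overlap": len(pred & ref),
                "wang_similarity": sim,
                "specificity_predicted": specificity(pred, corpus) if pred else float("nan"),
                "specificity_reference": specificity(ref, corpus) if ref else float("nan"),
                "trivially_annotated": bool(ref) and ref <= trivial_terms,
            }
        )
    return pd.DataFrame(rows)
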