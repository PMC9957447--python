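"""k-mer motif discovery in target-pool promoters and PWM validation.

Candidate binding motifs are exact k-mers (k = 6, 7, 8 by default; 86,016
candidates in total). Presence is binary per promoter. Enrichment of a motif
in a TF's target pool uses the upper-tail hypergeometric test

    p = sum_{x >= l} C(L, x) C(n - L, k_i - x) / C(n, k_i)

with L = genes carrying the motif, l = pool genes carrying it, k_i = pool
size, n = universe size; p-values are Benjamini-Hochberg corrected within
each TF's family of tested motifs. Discovered pair counts are validated
against a size-preserving rewired-network null, and enriched 7-mers are
scored against reference PWMs by a normalized information-content alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import NUCLEOTIDES, PWM, RegulatoryNetwork, TrnkitError, warn

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def enumerate_kmers(ks: Sequence[int]) -> list[str]:
    """All DNA strings of each requested length, lexicographic within length."""
    if not ks or any(k < 1 for k in ks):
        raise TrnkitError("k values must be positive")
    out: list[str] = []
    for k in dict.fromkeys(ks):
        out.extend("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=k))
    return out


@dataclass
class PromoterIndex:
    """Binary promoter presence index over observed k-mers.

    ``matrix`` is an n_genes x n_motifs boolean CSR; multiple occurrences in
    one promoter count once. Motifs never observed (L = 0) are not stored.
    """

    gene_ids: list[str]
    motifs: list[str]
    matrix: sparse.csr_matrix
    ks: tuple[int, ...]
    _motif_pos: dict[str, int] = field(repr=False, default_factory=dict)
    _gene_pos: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._motif_pos = {m: i for i, m in enumerate(self.motifs)}
        self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def L(self, motif: str) -> int:
        """Number of promoters containing ``motif``."""
        i = self._motif_pos.get(motif)
        if i is None:
            return 0
        return int(self.matrix[:, i].sum())

    def genes_with(self, motif: str) -> set[str]:
        i = self._motif_pos.get(motif)
        if i is None:
            return set()
        rows = self.matrix[:, i].nonzero()[0]
        return {self.gene_ids[r] for r in rows}

    def pool_mask(self, pool: Iterable[str]) -> np.ndarray:
        mask = np.zeros(self.n, dtype=np.int32)
        for g in pool:
            i = self._gene_pos.get(g)
            if i is not None:
                mask[i] = 1
        return mask

    def pool_counts(self, pool: Iterable[str]) -> np.ndarray:
        """l per indexed motif: pool promoters containing each motif."""
        return np.asarray(self.pool_mask(pool) @ self.matrix).ravel()

    def motif_totals(self) -> np.ndarray:
        """L per indexed motif."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()


def _kmers_in(seq: str, k: int) -> set[str]:
    valid = set(NUCLEOTIDES)
    found: set[str] = set()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if set(window) <= valid:
            found.add(window)
    return found


def index_promoters(
    promoters: Mapping[str, str],
    ks: Sequence[int] = (6, 7, 8),
    *,
    both_strands: bool = False,
) -> PromoterIndex:
    """Record binary k-mer presence for every promoter.

    Matching is exact and forward-strand by default; ``both_strands`` also
    marks a motif present when its reverse complement occurs. Windows with
    non-ACGT symbols never match.
    """
    gene_ids = list(promoters)
    if len(set(gene_ids)) != len(gene_ids):
        raise TrnkitError("duplicate promoter ids")
    ks = tuple(dict.fromkeys(ks))
    motif_pos: dict[str, int] = {}
    rows, cols = [], []
    for gi, gene in enumerate(gene_ids):
        seq = promoters[gene].upper()
        present: set[str] = set()
        for k in ks:
            found = _kmers_in(seq, k)
            if both_strands:
                found |= {f.translate(_COMPLEMENT)[::-1] for f in found}
            present |= found
        for motif in present:
            pos = motif_pos.setdefault(motif, len(motif_pos))
            rows.append(gi)
            cols.append(pos)
    motifs = sorted(motif_pos, key=lambda m: (len(m), m))
    remap = {motif_pos[m]: i for i, m in enumerate(motifs)}
    cols = [remap[c] for c in cols]
    mat = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(gene_ids), len(motifs)),
    )
    return PromoterIndex(gene_ids=gene_ids, motifs=motifs, matrix=mat, ks=ks)


@dataclass
class MotifHit:
    tf: str
    motif: str
    overlap: int  # l: pool genes containing the motif
    pool_size: int  # k_i
    motif_total: int  # L
    universe: int  # n
    p_value: float
    bh_adjusted: float = float("nan")
    significant: bool = False


def motif_enrichment(pool: Iterable[str], motif: str, index: PromoterIndex, tf: str = "") -> MotifHit:
    """Upper-tail hypergeometric enrichment of one motif in one pool."""
    pool = set(pool)
    known = pool & set(index.gene_ids)
    k_i = len(known)
    L = index.L(motif)
    ell = len(known & index.genes_with(motif))
    n = index.n
    if not (ell <= min(k_i, L) and L <= n and k_i <= n):
        raise TrnkitError("inconsistent counts")
    p = float(stats.hypergeom.sf(ell - 1, n, L, k_i))
    return MotifHit(tf=tf, motif=motif, overlap=ell, pool_size=k_i, motif_total=L, universe=n, p_value=p)


def bh_correct(hits: list[MotifHit], q: float = 0.05) -> list[MotifHit]:
    """Benjamini-Hochberg step-up over the given family of hits."""
    if not (0 < q < 1):
        raise TrnkitError("q must be in (0, 1)")
    if not hits:
        return []
    ps = np.array([h.p_value for h in hits])
    reject, adj, *_ = multipletests(ps, alpha=q, method="fdr_bh")
    out = []
    for h, a, r in zip(hits, adj, reject):
        out.append(
            MotifHit(
                tf=h.tf, motif=h.motif, overlap=h.overlap, pool_size=h.pool_size,
                motif_total=h.motif_total, universe=h.universe, p_value=h.p_value,
                bh_adjusted=float(a), significant=bool(r),
            )
        )
    return out


def _pool_pvalues(
    ells: np.ndarray, totals: np.ndarray, k_i: int, n: int, *, exact_all: bool = False
) -> np.ndarray:
    """Vectorized upper-tail hypergeometric p-values for one pool.

    Unless ``exact_all``, motifs whose overlap is below mean + 0.5 sd are
    assigned p = 1 without the exact tail computation: their true p-value
    exceeds any usable significance threshold by a wide margin, so BH flags
    (and the adjusted values of flagged hits) are unchanged. Exact tails are
    evaluated once per distinct (l, L) pair.
    """
    ps = np.ones(len(ells))
    if exact_all:
        cand = ells >= 1
    else:
        frac = totals / n
        mean = k_i * frac
        sd = np.sqrt(np.maximum(k_i * frac * (1 - frac) * (n - k_i) / max(n - 1, 1), 0.0))
        cand = (ells >= 1) & (ells >= mean + 0.5 * sd)
    if cand.any():
        codes = ells[cand].astype(np.int64) * (n + 1) + totals[cand].astype(np.int64)
        uniq, inverse = np.unique(codes, return_inverse=True)
        u_ell, u_L = uniq // (n + 1), uniq % (n + 1)
        ps[cand] = stats.hypergeom.sf(u_ell - 1, n, u_L, k_i)[inverse]
    return ps


def _significant_counts_for_pools(
    pools: Mapping[str, set[str]],
    index: PromoterIndex,
    q: float,
    collect: bool = False,
    exact_all: bool = False,
) -> tuple[int, pd.DataFrame | None]:
    """Count BH-significant TF-motif pairs (per-TF family), vectorized."""
    totals = index.motif_totals()
    n = index.n
    count = 0
    frames = []
    for tf in sorted(pools):
        mask = index.pool_mask(pools[tf])
        k_i = int(mask.sum())
        if k_i == 0:
            continue
        ells = np.asarray(mask @ index.matrix).ravel()
        ps = _pool_pvalues(ells, totals, k_i, n, exact_all=exact_all)
        reject, adj, *_ = multipletests(ps, alpha=q, method="fdr_bh")
        count += int(reject.sum())
        if collect and reject.any():
            sel = np.nonzero(reject)[0]
            frames.append(
                pd.DataFrame(
                    {
                        "tf": tf,
                        "motif": np.asarray(index.motifs)[sel],
                        "overlap": ells[sel],
                        "pool_size": k_i,
                        "motif_total": totals[sel],
                        "universe": n,
                        "p_value": ps[sel],
                        "bh_adjusted": adj[sel],
                    }
                )
            )
    if not collect:
        return count, None
    df = (
        pd.concat(frames, ignore_index=True).sort_values(["tf", "p_value"], kind="stable")
        if frames
        else pd.DataFrame(
            columns=["tf", "motif", "overlap", "pool_size", "motif_total",
                     "universe", "p_value", "bh_adjusted"]
        )
    )
    return count, df.reset_index(drop=True)


def discover_motifs(
    net: RegulatoryNetwork, index: PromoterIndex, q: float = 0.05
) -> pd.DataFrame:
    """All BH-significant TF-motif pairs of the network (per-TF FDR family)."""
    _, df = _significant_counts_for_pools(net.target_pools(), index, q, collect=True)
    return df


@dataclass
class RewireNullResult:
    observed: int
    null_counts: np.ndarray
    empirical_p: float  # fraction of null reps with count >= observed
    frac_observed_exceeds: float  # fraction of null reps strictly below observed

    @property
    def n_null_zero(self) -> int:
        return int((self.null_counts == 0).sum())


def rewire_null(
    net: RegulatoryNetwork,
    index: PromoterIndex,
    reps: int = 100,
    seed: int = 0,
    q: float = 0.05,
    *,
    mode: str = "redraw",
) -> RewireNullResult:
    """Significant-pair counts under size-preserving random rewiring.

    Each rep replaces every TF's target pool with a random gene set of the
    same cardinality (``mode="redraw"``: independent uniform draws from the
    universe; ``mode="permute"``: a permutation of the pooled target
    multiset), then reruns enrichment + BH correction.
    """
    if reps < 1:
        raise TrnkitError("reps must be >= 1")
    if mode not in ("redraw", "permute"):
        raise TrnkitError("mode must be 'redraw' or 'permute'")
    pools = net.target_pools()
    observed, _ = _significant_counts_for_pools(pools, index, q)
    rng = np.random.default_rng(seed)
    genes = index.gene_ids
    counts = np.empty(reps, dtype=int)
    tf_order = sorted(pools)
    for r in range(reps):
        if mode == "redraw":
            shuffled = {
                tf: set(rng.choice(genes, size=len(pools[tf]), replace=False))
                for tf in tf_order
            }
        else:
            multiset = [g for tf in tf_order for g in sorted(pools[tf])]
            perm = rng.permutation(multiset)
            shuffled, at = {}, 0
            for tf in tf_order:
                k = len(pools[tf])
                shuffled[tf] = set(perm[at : at + k])
                at += k
        counts[r], _ = _significant_counts_for_pools(shuffled, index, q)
    return RewireNullResult(
        observed=observed,
        null_counts=counts,
        empirical_p=float((counts >= observed).mean()),
        frac_observed_exceeds=float((counts < observed).mean()),
    )


# ---------------------------------------------------------------------------
# Information-content alignment against reference PWMs


@dataclass
class ICAlignment:
    pwm_id: str
    motif: str
    best_start: int  # 0-based column of the best window
    window_score: float  # masked score of the best window
    s_max: float  # best unmasked window score
    ic_score: float


def _column_contributions(pwm: PWM, sign: str) -> np.ndarray:
    """Per-(column, symbol) contribution p*log2(p/b), zero where p = 0."""
    p = pwm.matrix
    b = pwm.background[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / b), 0.0)
    if sign == "literal":
        contrib = -contrib
    return contrib.T  # t x 4


def ic_score(pwm: PWM, motif: str, *, sign: str = "positive") -> ICAlignment:
    """Normalized best-window information-content alignment of a k-mer to a PWM.

    Column score s(p_c) is the max over symbols of p_ck * log2(p_ck / b_k)
    (conserved over-background symbols score highest; ``sign="literal"``
    negates the contributions). The motif-masked window score sums the
    contribution of the motif's symbol over len(motif) consecutive columns;
    the result is the best masked window divided by s_max, the best unmasked
    window. Ties break to the smallest start.
    """
    w = len(motif)
    if set(motif) - set(NUCLEOTIDES):
        raise TrnkitError(f"motif {motif!r} not over ACGT")
    if pwm.length < w:
        raise TrnkitError(
            f"PWM shorter than motif (t={pwm.length} < {w})"
        )
    contrib = _column_contributions(pwm, sign)  # t x 4
    col_best = contrib.max(axis=1)
    sym = np.array([NUCLEOTIDES.index(c) for c in motif])
    n_windows = pwm.length - w + 1
    unmasked = np.array([col_best[c : c + w].sum() for c in range(n_windows)])
    masked = np.array(
        [contrib[np.arange(c, c + w), sym].sum() for c in range(n_windows)]
    )
    s_max = float(unmasked.max())
    best = int(masked.argmax())
    if s_max <= 0:
        warn(f"PWM {pwm.id or '?'} has no informative window; ic score undefined")
        score = float("nan")
    else:
        score = float(masked[best] / s_max)
    return ICAlignment(
        pwm_id=pwm.id, motif=motif, best_start=best,
        window_score=float(masked[best]), s_max=s_max, ic_score=score,
    )


def score_assignments(
    assignments: Mapping[str, Iterable[str]],
    pwms: Mapping[str, PWM],
    *,
    sign: str = "positive",
) -> pd.DataFrame:
    """ic_score for every (TF, enriched motif) pair with an available PWM.

    PWMs shorter than a motif are skipped with a warning.
    """
    rows = []
    for tf in sorted(assignments):
        pwm = pwms.get(tf)
        if pwm is None:
            continue
        for motif in assignments[tf]:
            if pwm.length < len(motif):
                warn(f"PWM for {tf} shorter than motif {motif}; skipped")
                continue
            aln = ic_score(pwm, motif, sign=sign)
            rows.append(
                {
                    "tf": tf, "motif": motif, "best_start": aln.best_start,
                    "window_score": aln.window_score, "s_max": aln.s_max,
                    "ic_score": aln.ic_score,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ShuffleBaselineResult:
    true_scores: np.ndarray
    shuffled_scores: np.ndarray
    t_statistic: float
    p_value: float


def score_shuffle_baseline(
    assignments: Mapping[str, Iterable[str]],
    pwms: Mapping[str, PWM],
    seed: int = 0,
    *,
    sign: str = "positive",
) -> ShuffleBaselineResult:
    """Compare true TF-motif ic scores with scores after permuting motif sets
    across TFs (independent two-sample t-test)."""
    tfs = sorted(tf for tf in assignments if tf in pwms)
    if len(tfs) < 2:
        raise TrnkitError("need at least 2 TFs with PWMs")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(tfs))
    shuffled = {tfs[i]: list(assignments[tfs[perm[i]]]) for i in range(len(tfs))}
    true_df = score_assignments({tf: assignments[tf] for tf in tfs}, pwms, sign=sign)
    shuf_df = score_assignments(shuffled, pwms, sign=sign)
    a = true_df["ic_score"].dropna().to_numpy()
    b = shuf_df["ic_score"].dropna().to_numpy()
    t, p = stats.ttest_ind(a, b)
    return ShuffleBaselineResult(
        true_scores=a, shuffled_scores=b, t_statistic=float(t), p_value=float(p)
    )
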