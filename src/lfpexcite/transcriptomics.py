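"""Downstream differential-expression analysis.

Operates on per-gene DE result tables (gene, logFC, pvalue) for two brain
tissues: Benjamini-Hochberg adjustment, significant-set extraction,
cross-tissue intersection, predicted-miRNA-target overlap filtering,
rank-rank hypergeometric overlap (RRHO) with a permutation p value, and
Kolmogorov-Smirnov disease-term enrichment.  Count modelling (the upstream
DESeq2 stage) is out of scope; DE tables are consumed as inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "RrhoResult",
    "bh_adjust",
    "add_padj",
    "significant_set",
    "cross_tissue_intersection",
    "candidate_targets",
    "rrho",
    "rrho_permutation_p",
    "ks_term_enrichment",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_padj(table: pd.DataFrame) -> pd.DataFrame:
    """Copy of a DE table with a BH-adjusted ``padj`` column."""
    out = table.copy()
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def significant_set(table: pd.DataFrame, alpha: float = 0.05,
                    direction: str = "any") -> set[str]:
    """Genes with padj <= alpha, optionally restricted by logFC sign."""
    t = table if "padj" in table.columns else add_padj(table)
    mask = t["padj"] <= alpha
    if direction == "up":
        mask &= t["logFC"] > 0
    elif direction == "down":
        mask &= t["logFC"] < 0
    elif direction != "any":
        raise ValueError(f"unknown direction {direction!r}")
    return set(t.loc[mask, "gene"])


def cross_tissue_intersection(set_a: Iterable[str], set_b: Iterable[str]) -> set[str]:
    """Genes differentially expressed in both tissues."""
    return set(set_a) & set(set_b)


def candidate_targets(shared_up: Iterable[str],
                      target_sets: Mapping[str, Iterable[str]]) -> set[str]:
    """Shared upregulated genes that are predicted targets of either miRNA arm."""
    union: set[str] = set()
    for genes in target_sets.values():
        union |= set(genes)
    return set(shared_up) & union


@dataclass
class RrhoResult:
    """Rank-rank hypergeometric overlap map.

    ``matrix[i, j]`` is -log10 of the hypergeometric upper-tail probability
    of the overlap between the top ``thresholds[i]`` genes of list A and the
    top ``thresholds[j]`` genes of list B (both ranked by descending logFC).
    ``summary_stat`` is the sum of the map; ``perm_p`` the permutation p
    value when computed.
    """

    step: int
    thresholds: np.ndarray
    matrix: np.ndarray
    summary_stat: float
    perm_p: float | None = None


def _inner_join(table_a: pd.DataFrame, table_b: pd.DataFrame):
    a = table_a.drop_duplicates("gene").set_index("gene")
    b = table_b.drop_duplicates("gene").set_index("gene")
    common = a.index.intersection(b.index)
    dropped = (len(a) - len(common)) + (len(b) - len(common))
    if dropped:
        logger.info("rrho: inner join dropped %d non-shared gene rows", dropped)
    return a.loc[common], b.loc[common]


def _grid(n: int, step: int) -> np.ndarray:
    thresholds = np.arange(step, n + step, step)
    thresholds = thresholds[thresholds <= n]
    if len(thresholds) == 0 or thresholds[-1] != n:
        thresholds = np.append(thresholds, n)
    return thresholds


def _overlap_counts(rank_a: np.ndarray, rank_b: np.ndarray,
                    thresholds: np.ndarray) -> np.ndarray:
    """|top-i(A) ∩ top-j(B)| for every grid cell, via a cumulative 2-D
    histogram of the joint rank distribution."""
    m = len(thresholds)
    cell_a = np.searchsorted(thresholds, rank_a, side="right")
    cell_b = np.searchsorted(thresholds, rank_b, side="right")
    hist = np.zeros((m, m))
    np.add.at(hist, (cell_a, cell_b), 1.0)
    return hist.cumsum(axis=0).cumsum(axis=1)


def _neglog_tails(overlap: np.ndarray, n: int, thresholds: np.ndarray,
                  cache: dict | None = None) -> np.ndarray:
    """-log10 P[X >= o], X ~ Hypergeom(N=n, K=i, n=j), per grid cell.

    scipy evaluates the tail exactly (log-space internally).  ``cache`` maps
    (cell, overlap) to previously computed values — across permutations the
    overlap counts concentrate near their null means, so hits dominate.
    """
    m = len(thresholds)
    ii = np.broadcast_to(thresholds[:, None], (m, m))
    jj = np.broadcast_to(thresholds[None, :], (m, m))
    o = overlap.astype(np.int64).ravel()
    if cache is None:
        tail = _stats.hypergeom.sf(o - 1, n, ii.ravel(), jj.ravel())
        with np.errstate(divide="ignore"):
            vals = -np.log10(np.maximum(tail, np.finfo(float).tiny))
        return vals.reshape(m, m)
    keys = np.arange(m * m, dtype=np.int64) * (n + 1) + o
    vals = np.fromiter((cache.get(k, np.nan) for k in keys.tolist()),
                       dtype=float, count=m * m)
    miss = np.isnan(vals)
    if miss.any():
        tail = _stats.hypergeom.sf(o[miss] - 1, n, ii.ravel()[miss], jj.ravel()[miss])
        with np.errstate(divide="ignore"):
            new = -np.log10(np.maximum(tail, np.finfo(float).tiny))
        vals[miss] = new
        cache.update(zip(keys[miss].tolist(), new.tolist()))
    return vals.reshape(m, m)


def _rrho_matrix(rank_a: np.ndarray, rank_b: np.ndarray, step: int,
                 cache: dict | None = None):
    n = len(rank_a)
    thresholds = _grid(n, step)
    overlap = _overlap_counts(rank_a, rank_b, thresholds)
    return thresholds, _neglog_tails(overlap, n, thresholds, cache)


def rrho(table_a: pd.DataFrame, table_b: pd.DataFrame, step: int | None = None) -> RrhoResult:
    """Rank-rank hypergeometric overlap of two DE tables on descending logFC.

    One-sided enrichment map over the concordant (both-upregulated) corner;
    the summary statistic is the sum of all -log10 p entries.  Tables with
    different gene universes are inner-joined (logged).  ``step`` defaults to
    round(N/100), at least 1.
    """
    a, b = _inner_join(table_a, table_b)
    n = len(a)
    if n == 0:
        raise ValueError("no shared genes between the two tables")
    if step is None:
        step = max(1, round(n / 100))
    if step > n:
        raise ValueError("step exceeds the number of shared genes")
    order_a = np.argsort(-a["logFC"].to_numpy(), kind="stable")
    order_b = np.argsort(-b["logFC"].to_numpy(), kind="stable")
    rank_a = np.empty(n, dtype=int)
    rank_b = np.empty(n, dtype=int)
    rank_a[order_a] = np.arange(n)
    rank_b[order_b] = np.arange(n)
    thresholds, mat = _rrho_matrix(rank_a, rank_b, step)
    return RrhoResult(step=int(step), thresholds=thresholds, matrix=mat,
                      summary_stat=float(mat.sum()))


def rrho_permutation_p(table_a: pd.DataFrame, table_b: pd.DataFrame,
                       step: int | None = None, n_perm: int = 999,
                       seed: int | None = None) -> RrhoResult:
    """RRHO with a permutation p value on the summary statistic.

    The gene-to-logFC assignment of table B is permuted ``n_perm`` times
    (an exchangeable null on gene labels), which is equivalent to drawing a
    uniform random ranking for list B; the add-one estimate
    (1 + #{perm >= observed}) / (n_perm + 1) can never be zero and is
    reproducible under ``seed``.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    a, b = _inner_join(table_a, table_b)
    n = len(a)
    if n == 0:
        raise ValueError("no shared genes between the two tables")
    if step is None:
        step = max(1, round(n / 100))
    if step > n:
        raise ValueError("step exceeds the number of shared genes")
    rng = np.random.default_rng(seed)
    observed = rrho(a.reset_index(), b.reset_index(), step=step)
    cache: dict = {}
    exceed = 0
    for _ in range(n_perm):
        rank_a = rng.permutation(n)  # relabelling one list permutes both ranks
        rank_b = np.arange(n)
        _, mat = _rrho_matrix(rank_a, rank_b, step, cache=cache)
        if float(mat.sum()) >= observed.summary_stat:
            exceed += 1
    observed.perm_p = (1 + exceed) / (n_perm + 1)
    return observed


def ks_term_enrichment(gene_stat: pd.Series,
                       term_sets: Mapping[str, Iterable[str]],
                       min_size: int = 2) -> pd.DataFrame:
    """Per-term Kolmogorov-Smirnov enrichment of a per-gene score.

    For each term, the scores of member genes are compared against the
    scores of all non-members with a two-sample KS test.  The default score
    in this pipeline is the per-gene DE p value, so a term whose genes are
    preferentially differentially expressed is detected regardless of effect
    direction.  Terms smaller than ``min_size`` (or with fewer than
    ``min_size`` non-members) are skipped with a warning.  Returns a table
    (term, n_genes, p, neg_log10_p).
    """
    scores = gene_stat.astype(float)
    universe = set(scores.index)
    rows = []
    for term, genes in term_sets.items():
        members = set(genes) & universe
        missing = set(genes) - universe
        if missing:
            logger.warning("term %s: %d genes outside the scored universe",
                           term, len(missing))
        rest = universe - members
        if len(members) < min_size or len(rest) < min_size:
            logger.warning("term %s skipped: too few members (%d) or "
                           "non-members (%d)", term, len(members), len(rest))
            continue
        res = _stats.ks_2samp(scores.loc[sorted(members)].to_numpy(),
                              scores.loc[sorted(rest)].to_numpy())
        p = float(res.pvalue)
        rows.append({"term": term, "n_genes": len(members), "p": p,
                     "neg_log10_p": -np.log10(max(p, np.finfo(float).tiny))})
    return pd.DataFrame(rows, columns=["term", "n_genes", "p", "neg_log10_p"])
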