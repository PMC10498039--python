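"""Rank-based gene-set enrichment and protein-type contribution tests.

:func:`gsea` implements the weighted Kolmogorov–Smirnov running-sum
statistic over a ranked protein list (here: t-statistics from the
high−low diet contrast), with a gene-label permutation null, normalized
enrichment scores, and Benjamini–Hochberg control across sets.  Gene
sets arrive as plain ID collections or GMT files; no ontology structure
is assumed.

:func:`contribution_enrichment` regresses per-protein PC contributions
on a binary protein-type indicator, the standard test for whether one
protein class is over-represented among a component's drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "TypeEnrichment",
    "rank_by_statistic",
    "enrichment_score",
    "gsea",
    "contribution_enrichment",
]


def rank_by_statistic(stat: pd.Series) -> pd.Series:
    """Sort a gene → statistic map into a strictly ordered ranking.

    Descending by statistic; ties broken by gene ID (ascending) so the
    ranking is deterministic.  Duplicate gene IDs are an error.
    """
    if stat.index.duplicated().any():
        raise ValueError("ranking statistic has duplicate gene IDs")
    frame = stat.rename("stat").rename_axis("gene").reset_index()
    frame = frame.sort_values(["stat", "gene"], ascending=[False, True])
    return frame.set_index("gene")["stat"]


def enrichment_score(
    ranked: pd.Series, gene_set: set[str], weight: float = 1.0
) -> tuple[float, int]:
    """Running-sum enrichment score of one set against a ranked list.

    Hits advance the sum by their |statistic|^weight (normalized to sum
    to one; uniform if all hit weights are zero), misses retreat by
    1/(N − n_set).  Returns the signed maximum deviation and the 0-based
    rank position where it is attained.
    """
    hit = np.fromiter((g in gene_set for g in ranked.index), bool, len(ranked))
    n_hit = int(hit.sum())
    N = len(ranked)
    if n_hit == 0 or n_hit == N:
        raise ValueError("gene set must hit a strict subset of the ranking")
    w = np.abs(ranked.to_numpy()) ** weight * hit
    total = w.sum()
    if total <= 0:
        w = hit / n_hit
    else:
        w = w / total
    step = w - (~hit) / (N - n_hit)
    running = np.cumsum(step)
    pos = int(np.abs(running).argmax())
    return float(running[pos]), pos


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set enrichment table and bookkeeping of skipped sets."""

    table: pd.DataFrame     # es, nes, size, p, q, leading_edge
    skipped: tuple[str, ...]
    n_perm: int


def _null_es(
    abs_w: np.ndarray, n_hit: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Permutation null: ES of ``n_hit`` random positions, vectorized."""
    N = len(abs_w)
    null = np.empty(n_perm)
    miss_pen = 1.0 / (N - n_hit)
    for b in range(n_perm):
        pos = np.sort(rng.choice(N, size=n_hit, replace=False))
        w = abs_w[pos]
        tot = w.sum()
        w = w / tot if tot > 0 else np.full(n_hit, 1.0 / n_hit)
        cum_hit = np.cumsum(w)
        k = np.arange(1, n_hit + 1)
        # running sum right after each hit, and just before each hit
        after = cum_hit - (pos + 1 - k) * miss_pen
        before = after - w
        lo = before.min()  # valleys sit just before a hit; the sum ends at 0
        hi = after.max()
        null[b] = hi if hi >= -lo else lo
    return null


def gsea(
    ranked: pd.Series,
    gene_sets: dict[str, set[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> EnrichmentResult:
    """Gene set enrichment analysis over a ranked list.

    ``ranked`` maps gene IDs to the ranking statistic (will be strictly
    ordered via :func:`rank_by_statistic`).  For each set with between
    ``min_size`` and ``max_size`` members present in the ranking, the
    signed running-sum ES is computed; the null is a gene-label
    permutation (random hit positions) with ``n_perm`` draws.  The
    nominal p-value compares |ES| with same-signed null scores and is
    floored at ``1/(n_perm+1)``; NES divides ES by the mean |null ES| of
    matching sign; q is Benjamini–Hochberg across scored sets, so both
    enrichment directions (high-diet and low-diet leading) are reported
    on one scale.
    """
    ranked = rank_by_statistic(ranked)
    universe = set(ranked.index)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x65EA]))
    abs_w = np.abs(ranked.to_numpy()) ** weight

    rows, skipped = [], []
    null_cache: dict[int, np.ndarray] = {}
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        if not (min_size <= len(members) <= min(max_size, len(universe) - 1)):
            skipped.append(name)
            continue
        es, pos = enrichment_score(ranked, members, weight)
        n_hit = len(members)
        if n_hit not in null_cache:
            null_cache[n_hit] = _null_es(abs_w, n_hit, n_perm, rng)
        null = null_cache[n_hit]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same):
            p = max(float((np.abs(same) >= abs(es)).mean()), 1.0 / (n_perm + 1))
            nes = es / float(np.abs(same).mean())
        else:
            p, nes = 1.0 / (n_perm + 1), np.nan
        hits_mask = ranked.index.isin(members)
        idx = np.flatnonzero(hits_mask)
        leading = tuple(
            ranked.index[i] for i in (idx[idx <= pos] if es >= 0 else idx[idx >= pos])
        )
        rows.append((name, es, nes, n_hit, p, leading))

    table = pd.DataFrame(
        rows, columns=["set", "es", "nes", "size", "p", "leading_edge"]
    ).set_index("set")
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table["q"] = pd.Series(dtype=float)
    table = table[["es", "nes", "size", "p", "q", "leading_edge"]]
    return EnrichmentResult(table=table, skipped=tuple(skipped), n_perm=n_perm)


@dataclass(frozen=True)
class TypeEnrichment:
    """OLS slope of contribution on a binary protein-type indicator."""

    beta: float
    se: float
    t: float
    df: int
    p: float
    n: int


def contribution_enrichment(
    contributions: pd.Series, type_indicator: pd.Series
) -> TypeEnrichment:
    """Test whether one protein type dominates a component's contributions.

    Least-squares regression of per-protein contribution on a 0/1 type
    indicator; the slope equals the group mean difference, with the
    usual t test on n − 2 degrees of freedom.
    """
    ind = type_indicator.reindex(contributions.index)
    if ind.isna().any():
        raise ValueError("type indicator does not cover all proteins")
    x = ind.to_numpy(dtype=float)
    if len(np.unique(x)) != 2:
        raise ValueError("type indicator must have exactly two non-empty groups")
    y = contributions.to_numpy(dtype=float)
    n = len(y)
    xc = x - x.mean()
    beta = float((xc @ y) / (xc @ xc))
    alpha = y.mean() - beta * x.mean()
    resid = y - alpha - beta * x
    s2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(s2 / (xc @ xc)))
    if se == 0:
        t = 0.0 if beta == 0 else np.inf
    else:
        t = beta / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return TypeEnrichment(beta=beta, se=se, t=float(t), df=n - 2, p=float(p), n=n)
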