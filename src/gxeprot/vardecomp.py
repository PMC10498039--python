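"""Variance decomposition of the normalized proteome.

PCA of the sample × protein matrix, type-III ANOVA of principal
component scores on diet, isoline and their interaction, partial ε²
effect sizes with noncentral-F confidence intervals, per-protein PC
contributions, and Ward hierarchical clustering orders (both the
unsquared- and squared-dissimilarity recursions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "PCAResult",
    "EffectSize",
    "WardResult",
    "run_pca",
    "typeIII_anova",
    "one_way_anova",
    "partial_epsilon_squared",
    "pc_contributions",
    "ward_order",
]


@dataclass(frozen=True)
class PCAResult:
    """Scores (samples × PCs), loadings (proteins × PCs), variance %."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray  # percent of total variance, non-increasing


def run_pca(
    norm_matrix: pd.DataFrame, center: bool = True, scale: bool = False
) -> PCAResult:
    """PCA of samples over proteins via SVD (prcomp conventions).

    ``norm_matrix`` is proteins × samples; samples are the observations.
    Protein columns are mean-centered (and optionally unit-scaled); the
    variance fraction of a component is its squared singular value over
    the total.  Component signs are fixed so the largest-magnitude
    loading of each component is positive.
    """
    X = norm_matrix.to_numpy(dtype=float).T  # samples × proteins
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least two samples")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError("cannot scale constant proteins")
        X = X / sd
    total = float((X ** 2).sum())
    if total <= 0:
        raise ValueError("matrix has no variance")

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: dominant loading of each PC is positive
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    U, Vt = U * signs, Vt * signs[:, None]

    comps = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(U * S, index=norm_matrix.columns, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=norm_matrix.index, columns=comps),
        variance_fraction=100.0 * S ** 2 / total,
    )


def typeIII_anova(pc_scores: pd.Series, design: pd.DataFrame) -> pd.DataFrame:
    """Type-III ANOVA of a PC score on diet × isoline (sum-to-zero coding).

    Returns a table indexed by ``diet, isoline, diet:isoline, residual``
    with columns ``SS, df, F, p``.
    """
    dsn = design.loc[pc_scores.index]
    cells = dsn.groupby(["diet", "isoline"], observed=True).size()
    expected_cells = dsn["diet"].nunique() * dsn["isoline"].nunique()
    if len(cells) < expected_cells or (cells < 1).any():
        raise ValueError("empty diet × isoline cells: interaction inestimable")

    frame = pd.DataFrame(
        {"score": pc_scores.to_numpy(), "diet": dsn["diet"].to_numpy(),
         "isoline": dsn["isoline"].to_numpy()}
    )
    model = smf.ols("score ~ C(diet, Sum) * C(isoline, Sum)", data=frame).fit()
    raw = sm.stats.anova_lm(model, typ=3)
    rename = {
        "C(diet, Sum)": "diet",
        "C(isoline, Sum)": "isoline",
        "C(diet, Sum):C(isoline, Sum)": "diet:isoline",
        "Residual": "residual",
    }
    tab = raw.loc[list(rename)].rename(index=rename)
    tab = tab.rename(columns={"sum_sq": "SS", "PR(>F)": "p"})
    return tab[["SS", "df", "F", "p"]]


def one_way_anova(scores: pd.Series, labels: pd.Series) -> tuple[float, int, int]:
    """One-way ANOVA F for scores across groups; returns (F, df1, df2)."""
    groups = [scores[labels == g].to_numpy() for g in labels.unique()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    F = float(stats.f_oneway(*groups).statistic)
    df1 = len(groups) - 1
    df2 = len(scores) - len(groups)
    return F, df1, df2


@dataclass(frozen=True)
class EffectSize:
    """Partial ε² with a noncentral-F confidence interval."""

    epsilon2: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    F: float | None = None
    df1: int | None = None
    df2: int | None = None


def _ncf_cdf(F: float, df1: int, df2: int, lam: float) -> float:
    v = special.ncfdtr(df1, df2, lam, F)
    return 0.0 if np.isnan(v) else float(v)


def _ncp_root(F: float, df1: int, df2: int, target: float) -> float:
    """Largest λ with ncf_cdf(F; λ) = target (cdf decreases in λ)."""
    if _ncf_cdf(F, df1, df2, 0.0) <= target:
        return 0.0
    hi = 1.0
    while _ncf_cdf(F, df1, df2, hi) > target:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("noncentrality bracket exhausted")
    return float(optimize.brentq(
        lambda lam: _ncf_cdf(F, df1, df2, lam) - target, 0.0, hi, xtol=1e-8
    ))


def partial_epsilon_squared(
    F: float, df1: int, df2: int, conf_level: float = 0.95
) -> EffectSize:
    """Partial ε² from an ANOVA F statistic, with a two-sided CI.

    The point estimate is ``df1 (F − 1) / (df1 F + df2)``, floored at 0.
    The interval inverts the noncentral-F CDF at the two tails to bound
    the noncentrality λ, then maps ``λ / (λ + df1 + df2 + 1)``; the
    lower bound is floored at 0.
    """
    if not np.isfinite(F):
        raise ValueError("F must be finite")
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("require F >= 0 and dfs >= 1")
    if not (0 < conf_level < 1):
        raise ValueError("conf_level must be in (0, 1)")

    est = max(0.0, df1 * (F - 1.0) / (df1 * F + df2))
    alpha = 1.0 - conf_level
    lam_lo = _ncp_root(F, df1, df2, 1.0 - alpha / 2.0)
    lam_hi = _ncp_root(F, df1, df2, alpha / 2.0)
    N = df1 + df2 + 1
    return EffectSize(
        epsilon2=est,
        ci_low=max(0.0, lam_lo / (lam_lo + N)),
        ci_high=lam_hi / (lam_hi + N),
        conf_level=conf_level,
        F=F, df1=df1, df2=df2,
    )


def pc_contributions(pca: PCAResult, component: str | int) -> pd.DataFrame:
    """Percent contribution of each protein to one component.

    ``contribution = 100 · loading² / Σ loading²``; a protein is
    ``above_average`` when its contribution strictly exceeds the uniform
    share ``100 / n_proteins``.
    """
    comp = f"PC{component}" if isinstance(component, int) else component
    if comp not in pca.loadings.columns:
        raise ValueError(f"component {comp!r} out of range")
    lo = pca.loadings[comp].to_numpy()
    contrib = 100.0 * lo ** 2 / float((lo ** 2).sum())
    return pd.DataFrame(
        {
            "contribution": contrib,
            "above_average": contrib > 100.0 / len(lo),
        },
        index=pca.loadings.index,
    )


@dataclass(frozen=True)
class WardResult:
    """Agglomerative merge sequence and the dendrogram leaf order.

    ``merges`` rows are (cluster_a, cluster_b, height, size) with
    original items 0..n−1 and merged clusters numbered n, n+1, …  —
    the scipy linkage convention.
    """

    merges: np.ndarray
    order: tuple[int, ...]
    labels: tuple[str, ...]


def ward_order(
    matrix: pd.DataFrame, axis: int = 0, linkage_variant: str = "ward.D2"
) -> WardResult:
    """Ward hierarchical clustering via the Lance–Williams recursion.

    ``axis=0`` clusters rows, ``axis=1`` columns, on Euclidean
    distances.  ``"ward.D2"`` feeds squared distances into the recursion
    and reports square-root heights (the usual Ward criterion);
    ``"ward.D"`` feeds raw distances, as in the historical variant.
    Ties are broken toward the lowest cluster-index pair, so the merge
    sequence is deterministic.
    """
    if linkage_variant not in ("ward.D", "ward.D2"):
        raise ValueError("linkage_variant must be 'ward.D' or 'ward.D2'")
    X = matrix.to_numpy(dtype=float)
    if axis == 1:
        X = X.T
        labels = tuple(str(c) for c in matrix.columns)
    else:
        labels = tuple(str(i) for i in matrix.index)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two items to cluster")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in clustering input")

    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    S = d ** 2 if linkage_variant == "ward.D2" else d.copy()
    np.fill_diagonal(S, np.inf)

    size = np.ones(n)
    cluster_id = np.arange(n)
    active = np.ones(n, dtype=bool)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], S, np.inf)
        i, j = np.unravel_index(int(np.argmin(masked)), masked.shape)
        if i > j:
            i, j = j, i
        s_ij = S[i, j]
        height = np.sqrt(s_ij) if linkage_variant == "ward.D2" else s_ij
        a, b = cluster_id[i], cluster_id[j]
        if a > b:
            a, b = b, a
        merges[step] = (a, b, height, size[i] + size[j])
        # Lance–Williams Ward update onto slot i
        ni, nj = size[i], size[j]
        for k in np.flatnonzero(active):
            if k in (i, j):
                continue
            nk = size[k]
            s_new = ((ni + nk) * S[i, k] + (nj + nk) * S[j, k] - nk * s_ij) / (
                ni + nj + nk
            )
            S[i, k] = S[k, i] = s_new
        size[i] += size[j]
        active[j] = False
        members[next_id] = members.pop(a) + members.pop(b)
        cluster_id[i] = next_id
        next_id += 1

    order = tuple(members[next_id - 1])
    return WardResult(merges=merges, order=order, labels=labels)
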