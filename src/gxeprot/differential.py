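"""Per-protein diet contrasts from a mixed model, with FDR control.

Each protein's normalized log2 abundance is modelled as

    abundance ~ diet + isoline + (1 | replicate)

with diet coded ±1/2 so the diet coefficient is directly the high−low
log2 fold change, isoline sum-coded, and the biological replicate batch
as a random intercept.  Because the design matrix is identical for every
protein, the random-intercept model is fitted by profiling the REML
criterion over the single variance ratio θ = σ²_replicate / σ²_residual
after a one-off eigendecomposition of the replicate incidence structure;
θ̂ = 0 recovers ordinary least squares exactly, which doubles as the
degenerate-fit fallback.  The Wald t for the contrast uses residual
degrees of freedom.

Optional empirical-Bayes variance moderation (off by default) shrinks
per-protein residual variances toward a common prior fitted by moment
matching on log variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .synth import DIET_HIGH, DIET_LOW

__all__ = [
    "ContrastResult",
    "DirectionalBias",
    "fit_contrasts",
    "directional_bias",
    "class_mean_logfc",
]


@dataclass(frozen=True)
class ContrastResult:
    """Per-protein contrast table plus fit diagnostics.

    ``table`` columns: ``logFC`` (high−low, log2), ``se``, ``t``, ``df``,
    ``p``, ``q`` (Benjamini–Hochberg) and, when class labels were given,
    ``protein_class``.  ``theta`` is the fitted replicate-to-residual
    variance ratio; ``ols_fallback_ids`` lists proteins whose random
    effect collapsed to zero, ``constant_ids`` proteins with no variance.
    """

    table: pd.DataFrame
    ols_fallback_ids: tuple[str, ...]
    constant_ids: tuple[str, ...]


class _ReplicateContrastSolver:
    """Profiled-REML solver for one shared design across many proteins."""

    def __init__(self, design: pd.DataFrame):
        diets = set(design["diet"].unique())
        if diets != {DIET_HIGH, DIET_LOW}:
            raise ValueError(f"expected diets {{'high','low'}}, got {sorted(diets)}")
        isolines = sorted(design["isoline"].unique())
        if len(isolines) < 2:
            raise ValueError("need at least two isolines")

        n = len(design)
        x_diet = np.where(design["diet"].to_numpy() == DIET_HIGH, 0.5, -0.5)
        iso = pd.Categorical(design["isoline"], categories=isolines)
        iso_dummies = np.zeros((n, len(isolines) - 1))
        codes = np.asarray(iso.codes)
        for j in range(len(isolines) - 1):
            iso_dummies[:, j] = (codes == j).astype(float)
        iso_dummies[codes == len(isolines) - 1, :] = -1.0  # sum-to-zero coding

        X = np.column_stack([np.ones(n), x_diet, iso_dummies])
        groups = pd.Categorical(design["replicate"]).codes
        Zzt = (groups[:, None] == groups[None, :]).astype(float)
        lam, Q = np.linalg.eigh(Zzt)
        self.n, self.p = X.shape
        self.lam = np.clip(lam, 0.0, None)
        self.Xt = Q.T @ X
        self.Q = Q
        self.c_index = 1  # diet column

    def _profile(self, theta: float, yt: np.ndarray):
        w = 1.0 / (1.0 + theta * self.lam)
        Xw = self.Xt * w[:, None]
        A = Xw.T @ self.Xt
        beta = np.linalg.solve(A, Xw.T @ yt)
        resid = yt - self.Xt @ beta
        rss = float(np.sum(w * resid ** 2))
        return w, A, beta, rss

    def _reml(self, theta: float, yt: np.ndarray) -> float:
        _, A, _, rss = self._profile(theta, yt)
        dfres = self.n - self.p
        sigma2 = rss / dfres
        if sigma2 <= 0:
            return np.inf
        return (
            dfres * np.log(sigma2)
            + float(np.sum(np.log1p(theta * self.lam)))
            + float(np.linalg.slogdet(A)[1])
        )

    def fit(self, y: np.ndarray):
        """Return (logfc, se, t, df, p, theta, is_constant) for one protein."""
        yt = self.Q.T @ y
        dfres = self.n - self.p
        if np.ptp(y) < 1e-12:
            return 0.0, 0.0, 0.0, dfres, 1.0, 0.0, True
        res = optimize.minimize_scalar(
            self._reml, args=(yt,), bounds=(0.0, 200.0),
            method="bounded", options={"xatol": 1e-8},
        )
        theta = float(res.x) if res.fun <= self._reml(0.0, yt) else 0.0
        w, A, beta, rss = self._profile(theta, yt)
        sigma2 = rss / dfres
        Ainv = np.linalg.inv(A)
        logfc = float(beta[self.c_index])
        var_c = sigma2 * Ainv[self.c_index, self.c_index]
        if var_c <= 0:
            return logfc, 0.0, 0.0, dfres, 1.0, theta, True
        se = float(np.sqrt(var_c))
        t = logfc / se
        p = 2.0 * stats.t.sf(abs(t), dfres)
        return logfc, se, t, dfres, p, theta, False


def _moderate(table: pd.DataFrame, dfres: int) -> pd.DataFrame:
    """Limma-style empirical-Bayes shrinkage of residual variances."""
    ok = table["se"] > 0
    # se^2 = sigma2 * h with h shared across proteins; shrinkage is invariant
    # to the common factor h, so shrink se^2 directly.
    s2 = table.loc[ok, "se"].to_numpy() ** 2
    z = np.log(s2)
    e = z - special.digamma(dfres / 2) + np.log(dfres / 2)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, dfres / 2))
    if evar <= 0:
        d0, s02 = np.inf, float(np.exp(np.mean(e)))
    else:
        d0 = 2 * optimize.brentq(
            lambda x: float(special.polygamma(1, x)) - evar, 1e-6, 1e8
        )
        s02 = float(np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2)))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_post = np.inf
    else:
        s2_post = (d0 * s02 + dfres * s2) / (d0 + dfres)
        df_post = dfres + d0
    out = table.copy()
    out["df"] = out["df"].astype(float)
    out.loc[ok, "se"] = np.sqrt(s2_post)
    out.loc[ok, "t"] = out.loc[ok, "logFC"] / out.loc[ok, "se"]
    out.loc[ok, "df"] = df_post
    out.loc[ok, "p"] = 2.0 * stats.t.sf(np.abs(out.loc[ok, "t"]), df_post)
    return out


def fit_contrasts(
    norm_matrix: pd.DataFrame,
    design: pd.DataFrame,
    classes: pd.Series | None = None,
    moderate: bool = False,
) -> ContrastResult:
    """Fit the high−low diet contrast for every protein.

    ``norm_matrix`` is proteins × samples on the log2 scale with no
    missing values; ``design`` must contain diet, isoline and replicate
    columns; ``classes`` optionally maps protein IDs to class labels.
    p-values are BH-adjusted across all fitted proteins.
    """
    if norm_matrix.isna().to_numpy().any():
        raise ValueError("fit_contrasts requires a complete matrix")
    dsn = design.loc[norm_matrix.columns]
    solver = _ReplicateContrastSolver(dsn)

    rows, fallback, constant = [], [], []
    Y = norm_matrix.to_numpy(dtype=float)
    for pid, y in zip(norm_matrix.index, Y):
        logfc, se, t, df, p, theta, is_const = solver.fit(y)
        rows.append((pid, logfc, se, t, df, p, theta))
        if is_const:
            constant.append(pid)
        elif theta == 0.0:
            fallback.append(pid)
    table = pd.DataFrame(
        rows, columns=["protein_id", "logFC", "se", "t", "df", "p", "theta"]
    ).set_index("protein_id")
    if moderate:
        table = _moderate(table, solver.n - solver.p)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    if classes is not None:
        table["protein_class"] = classes.reindex(table.index)
    return ContrastResult(
        table=table,
        ols_fallback_ids=tuple(fallback),
        constant_ids=tuple(constant),
    )


@dataclass(frozen=True)
class DirectionalBias:
    """2×2 class × fold-change-sign table and its Pearson chi-square."""

    classes: tuple[str, str]
    counts: np.ndarray        # rows: classes; cols: (down, up)
    chi2: float
    df: int
    p: float
    n_zero_excluded: int


def directional_bias(
    contrasts: pd.DataFrame | ContrastResult,
    classes: tuple[str, str] = ("SFP", "SpP"),
) -> DirectionalBias:
    """Test whether two protein classes differ in fold-change direction.

    Builds the 2×2 table of class × sign(logFC) (zero-logFC proteins are
    excluded and counted) and applies Pearson's chi-square without
    continuity correction.
    """
    table = contrasts.table if isinstance(contrasts, ContrastResult) else contrasts
    if "protein_class" not in table.columns:
        raise ValueError("contrast table lacks a 'protein_class' column")
    counts = np.zeros((2, 2), dtype=int)
    n_zero = 0
    for i, cls in enumerate(classes):
        sub = table.loc[table["protein_class"] == cls, "logFC"]
        if sub.empty:
            raise ValueError(f"class {cls!r} is empty")
        n_zero += int((sub == 0).sum())
        counts[i, 0] = int((sub < 0).sum())
        counts[i, 1] = int((sub > 0).sum())
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return DirectionalBias(
        classes=classes, counts=counts, chi2=float(chi2), df=int(df),
        p=float(p), n_zero_excluded=n_zero,
    )


def class_mean_logfc(contrasts: pd.DataFrame | ContrastResult, cls: str) -> float:
    """Arithmetic mean log2 fold change over the members of one class."""
    table = contrasts.table if isinstance(contrasts, ContrastResult) else contrasts
    if "protein_class" not in table.columns:
        raise ValueError("contrast table lacks a 'protein_class' column")
    sub = table.loc[table["protein_class"] == cls, "logFC"]
    if sub.empty:
        raise ValueError(f"class {cls!r} is empty")
    return float(sub.mean())
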