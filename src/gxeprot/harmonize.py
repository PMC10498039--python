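"""Cross-plex harmonization of multi-plex TMT reporter intensities.

The stack mirrors the standard practice for isobaric-label proteomics
run across several plexes:

1. :func:`impute_and_filter` — a protein missing in exactly one plex is
   filled with the mean diet-specific abundance of the remaining plexes;
   proteins missing in more than one plex are excluded.
2. :func:`sample_loading_normalize` — equalize column totals within each
   plex (channels of a plex received nominally equal material).
3. :func:`tmm_factors` — trimmed-mean-of-M-values scale factors between
   columns, computed on intensity proportions.
4. log2 transform.
5. :func:`combat_adjust` — parametric empirical-Bayes location/scale
   batch adjustment across plexes, retaining diet and isoline as
   covariates.

:func:`normalize_pipeline` chains the five steps and records provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImputationReport",
    "TMMParams",
    "BatchModel",
    "NormalizedMatrix",
    "impute_and_filter",
    "sample_loading_normalize",
    "tmm_factors",
    "combat_adjust",
    "normalize_pipeline",
]


@dataclass(frozen=True)
class ImputationReport:
    n_detected: int
    n_imputed: int
    n_excluded: int
    n_retained: int
    imputed_ids: tuple[str, ...]
    #: proteins where a diet level was unobservable outside the missing plex
    fallback_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_retained != self.n_detected - self.n_excluded:
            raise ValueError("inconsistent report: retained != detected - excluded")


def _plex_missingness(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Proteins × plexes boolean table of whole-plex missingness.

    Raises if any protein is partially observed within a plex — the
    quantification contract is that identification is a plex-level event.
    """
    isna = matrix.isna()
    plex = design.loc[matrix.columns, "plex"]
    all_missing = isna.T.groupby(plex.values).all().T
    any_missing = isna.T.groupby(plex.values).any().T
    partial = any_missing & ~all_missing
    if partial.to_numpy().any():
        bad = partial.index[partial.any(axis=1)][:5].tolist()
        raise ValueError(f"partial within-plex missingness (e.g. {bad})")
    return all_missing


def impute_and_filter(
    matrix: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, ImputationReport]:
    """Apply the single-missing-plex imputation and multi-missing exclusion.

    For a protein missing in exactly one plex, every missing cell is
    filled with the mean abundance of the same-diet samples of that
    protein in the other plexes.  Proteins missing in more than one plex
    (including all) are removed.  Observed cells are never altered.
    """
    plex = design.loc[matrix.columns, "plex"]
    if plex.nunique() < 2:
        raise ValueError("imputation requires at least two plexes")
    all_missing = _plex_missingness(matrix, design)
    n_miss = all_missing.sum(axis=1)

    keep = n_miss <= 1
    out = matrix.loc[keep].copy()
    to_impute = n_miss.index[n_miss == 1]
    diet = design.loc[matrix.columns, "diet"]

    fallback: list[str] = []
    for k in all_missing.columns:
        rows = to_impute[all_missing.loc[to_impute, k]]
        if len(rows) == 0:
            continue
        donor_mask = (plex != k).to_numpy()
        for lvl in diet.unique():
            lvl_mask = (diet == lvl).to_numpy()
            target_cols = matrix.columns[lvl_mask & ~donor_mask]
            if len(target_cols) == 0:
                continue
            donor_cols = matrix.columns[lvl_mask & donor_mask]
            if len(donor_cols) == 0:
                # diet level exists only inside the missing plex
                donor_cols = matrix.columns[donor_mask]
                fallback.extend(rows)
            fill = out.loc[rows, donor_cols].mean(axis=1)
            out.loc[rows, target_cols] = np.broadcast_to(
                fill.to_numpy()[:, None], (len(rows), len(target_cols))
            )

    report = ImputationReport(
        n_detected=len(matrix),
        n_imputed=len(to_impute),
        n_excluded=int((~keep).sum()),
        n_retained=len(out),
        imputed_ids=tuple(to_impute),
        fallback_ids=tuple(dict.fromkeys(fallback)),
    )
    return out, report


def sample_loading_normalize(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Equalize column totals within each plex (sample-loading correction).

    Each column is rescaled so its total matches the mean column total of
    its plex; the grand total of a plex is therefore conserved.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("sample_loading_normalize requires a complete matrix")
    out = matrix.copy()
    plex = design.loc[matrix.columns, "plex"]
    for k, cols in matrix.columns.groupby(plex).items():
        totals = matrix[list(cols)].sum(axis=0)
        zero = totals.index[totals <= 0]
        if len(zero):
            raise ValueError(f"zero-total sample(s): {list(zero)}")
        out[list(cols)] = matrix[list(cols)] * (totals.mean() / totals)
    return out


@dataclass(frozen=True)
class TMMParams:
    """Trimmed-mean-of-M-values tuning constants."""

    m_trim: float = 0.30
    a_trim: float = 0.05
    #: explicit reference column; default picks the column whose
    #: upper-quartile proportion is closest to the mean upper-quartile
    reference: str | None = None

    def validate(self) -> None:
        if not (0 <= self.m_trim < 0.5 and 0 <= self.a_trim < 0.5):
            raise ValueError("trim fractions must lie in [0, 0.5)")


def tmm_factors(matrix: pd.DataFrame, params: TMMParams | None = None) -> pd.Series:
    """Per-column TMM scale factors on intensity proportions.

    For column *j* against reference *r*, with proportions
    ``p = y / total``: ``M = log2(p_j / p_r)`` and
    ``A = 0.5 * log2(p_j * p_r)``.  Proteins in the upper/lower
    ``m_trim`` tail of M or ``a_trim`` tail of A are discarded and the
    factor is ``2 ** weighted_mean(M)`` with inverse asymptotic-variance
    weights, finally rescaled so the factors have geometric mean 1.
    """
    params = params or TMMParams()
    params.validate()
    if matrix.shape[1] < 2:
        raise ValueError("TMM requires at least two columns")
    if (matrix.to_numpy() <= 0).any() or matrix.isna().to_numpy().any():
        raise ValueError("TMM requires strictly positive, complete intensities")

    totals = matrix.sum(axis=0)
    props = matrix / totals

    if params.reference is None:
        uq = props.quantile(0.75, axis=0)
        ref = (uq - uq.mean()).abs().idxmin()
    else:
        ref = params.reference
        if ref not in matrix.columns:
            raise ValueError(f"reference column {ref!r} not in matrix")

    p_r = props[ref].to_numpy()
    t_r = float(totals[ref])
    log_factors = {}
    for col in matrix.columns:
        if col == ref:
            log_factors[col] = 0.0
            continue
        p_j = props[col].to_numpy()
        M = np.log2(p_j / p_r)
        A = 0.5 * np.log2(p_j * p_r)
        finite = np.isfinite(M) & np.isfinite(A)
        M, A, p_jf, p_rf = M[finite], A[finite], p_j[finite], p_r[finite]
        n = len(M)
        if n < 2:
            warnings.warn(f"column {col!r}: <2 usable proteins; factor set to 1")
            log_factors[col] = 0.0
            continue
        # doubly trimmed keep-set via ranks, as in the published method
        rank_m = pd.Series(M).rank().to_numpy()
        rank_a = pd.Series(A).rank().to_numpy()
        lo_m = np.floor(n * params.m_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * params.a_trim) + 1
        hi_a = n + 1 - lo_a
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() < 2:
            warnings.warn(f"column {col!r}: <2 proteins survive trimming; factor 1")
            log_factors[col] = 0.0
            continue
        t_j = float(totals[col])
        w = (1 - p_jf[keep]) / (t_j * p_jf[keep]) + (1 - p_rf[keep]) / (t_r * p_rf[keep])
        log_factors[col] = float(np.sum(M[keep] / w) / np.sum(1.0 / w))

    f = pd.Series(log_factors).reindex(matrix.columns)
    f -= f.mean()  # geometric mean 1 on the linear scale
    return np.exp2(f)


@dataclass(frozen=True)
class BatchModel:
    """Per-batch location/scale estimates and their EB-shrunken versions."""

    batches: tuple
    gamma_hat: pd.DataFrame     # proteins × batches, raw locations
    delta2_hat: pd.DataFrame    # proteins × batches, raw scales
    gamma_star: pd.DataFrame    # shrunken locations
    delta2_star: pd.DataFrame   # shrunken scales
    #: per-batch normal prior (mean, var) for locations and inverse-gamma
    #: (shape, scale) for scales, estimated by method of moments
    hyper: dict = field(default_factory=dict)


def _combat_it_sol(
    sdat: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
    g_bar: float, t2: float, a: float, b: float, conv: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint EB fixed-point for one batch (parametric priors)."""
    n = sdat.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
        change = max(
            np.abs(g_new - g_old).max() / (np.abs(g_old).max() + 1e-30),
            np.abs(d_new - d_old).max() / (np.abs(d_old).max() + 1e-30),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(
    log_matrix: pd.DataFrame,
    batch_labels: pd.Series,
    design_covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, BatchModel | None]:
    """Parametric empirical-Bayes batch adjustment (ComBat) on log2 data.

    Per protein the model retains the covariates, standardizes to pooled
    variance, estimates per-batch location and scale, shrinks them with
    a normal / inverse-gamma prior whose hyperparameters come from
    moments across proteins, then removes the shrunken batch effects and
    restores the grand mean and covariate fit.

    ``batch_labels`` is indexed by sample; ``design_covariates`` holds
    categorical columns (e.g. diet, isoline) to protect from removal.
    With a single batch the input is returned unchanged.
    """
    batch = batch_labels.loc[log_matrix.columns]
    batches = tuple(sorted(batch.unique()))
    if len(batches) == 1:
        return log_matrix.copy(), None
    counts = batch.value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs at least two samples")

    Y = log_matrix.to_numpy(dtype=float)       # proteins × samples
    n_array = Y.shape[1]
    B = np.stack([(batch == b).to_numpy(float) for b in batches], axis=1)
    if design_covariates is not None and len(design_covariates.columns):
        C = pd.get_dummies(
            design_covariates.loc[log_matrix.columns].astype("category"),
            drop_first=True,
        ).to_numpy(float)
    else:
        C = np.empty((n_array, 0))
    X = np.hstack([B, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariates are confounded with batch")

    # per-protein OLS with batch means + covariates
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)      # (K+q) × proteins
    nk = counts.reindex(list(batches)).to_numpy(float)
    grand = (nk / n_array) @ beta[: len(batches)]        # per-protein grand mean
    stand_mean = grand[:, None] + (C @ beta[len(batches):]).T
    resid = Y - (X @ beta).T
    var_pooled = (resid ** 2).mean(axis=1)
    if (var_pooled <= 0).any():
        var_pooled = np.maximum(var_pooled, 1e-12)
    Z = (Y - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.empty((Y.shape[0], len(batches)))
    delta2_hat = np.empty_like(gamma_hat)
    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(gamma_hat)
    hyper: dict = {}
    Zadj = Z.copy()
    for j, b in enumerate(batches):
        cols = (batch == b).to_numpy()
        sdat = Z[:, cols]
        g_hat = sdat.mean(axis=1)
        d_hat = sdat.var(axis=1, ddof=1)
        g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        m, s2 = float(d_hat.mean()), float(d_hat.var(ddof=1))
        a_prior = (2 * s2 + m ** 2) / s2
        b_prior = (m * s2 + m ** 3) / s2
        g_star, d_star = _combat_it_sol(sdat, g_hat, d_hat, g_bar, t2, a_prior, b_prior)
        gamma_hat[:, j], delta2_hat[:, j] = g_hat, d_hat
        gamma_star[:, j], delta2_star[:, j] = g_star, d_star
        hyper[b] = {"gamma_bar": g_bar, "tau2": t2, "a": a_prior, "b": b_prior}
        Zadj[:, cols] = (sdat - g_star[:, None]) / np.sqrt(d_star)[:, None]

    adjusted = Zadj * np.sqrt(var_pooled)[:, None] + stand_mean
    out = pd.DataFrame(adjusted, index=log_matrix.index, columns=log_matrix.columns)
    model = BatchModel(
        batches=batches,
        gamma_hat=pd.DataFrame(gamma_hat, index=log_matrix.index, columns=list(batches)),
        delta2_hat=pd.DataFrame(delta2_hat, index=log_matrix.index, columns=list(batches)),
        gamma_star=pd.DataFrame(gamma_star, index=log_matrix.index, columns=list(batches)),
        delta2_star=pd.DataFrame(delta2_star, index=log_matrix.index, columns=list(batches)),
        hyper=hyper,
    )
    return out, model


@dataclass(frozen=True)
class NormalizedMatrix:
    """Log2-scale normalized abundances plus a provenance trail."""

    data: pd.DataFrame
    provenance: tuple[str, ...]
    tmm_factors: pd.Series | None = None
    batch_model: BatchModel | None = None


def normalize_pipeline(
    raw_matrix: pd.DataFrame,
    design: pd.DataFrame,
    tmm_params: TMMParams | None = None,
    batch_correct: bool = True,
) -> tuple[NormalizedMatrix, ImputationReport]:
    """Impute/exclude, then SL → TMM → log2 → empirical-Bayes batch adjust.

    Returns the normalized matrix (finite everywhere, labels preserved)
    and the imputation report.  With a single plex the batch-adjustment
    stage is a no-op.
    """
    imputed, report = impute_and_filter(raw_matrix, design)
    provenance = ["impute_and_filter"]

    sl = sample_loading_normalize(imputed, design)
    provenance.append("sample_loading_normalize")

    factors = tmm_factors(sl, tmm_params)
    scaled = sl / factors
    provenance.append("tmm_scale")

    logm = np.log2(scaled)
    provenance.append("log2")

    model = None
    if batch_correct and design.loc[logm.columns, "plex"].nunique() > 1:
        logm, model = combat_adjust(
            logm, design["plex"], design[["diet", "isoline"]]
        )
        provenance.append("combat_adjust")

    if not np.isfinite(logm.to_numpy()).all():
        raise ValueError("normalization produced non-finite values")
    return (
        NormalizedMatrix(
            data=logm, provenance=tuple(provenance),
            tmm_factors=factors, batch_model=model,
        ),
        report,
    )
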