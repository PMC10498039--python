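"""Imputation/exclusion, loading and TMM normalization, batch adjustment."""

import numpy as np
import pandas as pd
import pytest

from gxeprot import (
    TMMParams, TruthParams, combat_adjust, generate_design, impute_and_filter,
    normalize_pipeline, sample_loading_normalize, simulate_intensities,
    tmm_factors,
)
from gxeprot.vardecomp import one_way_anova, partial_epsilon_squared, run_pca


# ---------------------------------------------------------------------------
# impute_and_filter
# ---------------------------------------------------------------------------

class TestImputeAndFilter:
    def test_single_missing_plex_filled_with_diet_means(self, design72):
        params = TruthParams(n_proteins=6, dropout=(6, 0, 0))
        m, _ = simulate_intensities(design72, params, seed=0)
        plex3 = design72.index[design72["plex"] == 3]
        m.loc["P00002", plex3] = np.nan
        out, rep = impute_and_filter(m, design72)
        assert rep.n_imputed == 1 and rep.imputed_ids == ("P00002",)
        for diet in ("high", "low"):
            donors = design72.index[(design72["plex"] != 3)
                                    & (design72["diet"] == diet)]
            targets = design72.index[(design72["plex"] == 3)
                                     & (design72["diet"] == diet)]
            expected = m.loc["P00002", donors].mean()
            assert np.allclose(out.loc["P00002", targets], expected)

    def test_fully_observed_protein_bit_identical(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams(n_proteins=10, dropout=(8, 1, 1)), seed=1
        )
        out, rep = impute_and_filter(m, design72)
        untouched = [p for p in out.index if p not in rep.imputed_ids]
        pd.testing.assert_frame_equal(out.loc[untouched], m.loc[untouched])

    def test_study_marginals_report(self, design72):
        m, _ = simulate_intensities(design72, TruthParams(), seed=2)
        _, rep = impute_and_filter(m, design72)
        assert (rep.n_detected, rep.n_imputed, rep.n_excluded, rep.n_retained) \
            == (4328, 445, 1336, 2992)

    def test_conservation_and_observed_cells_unaltered(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams(n_proteins=40, dropout=(20, 12, 8)), seed=3
        )
        out, rep = impute_and_filter(m, design72)
        assert rep.n_detected == rep.n_retained + rep.n_excluded
        obs = m.loc[out.index].notna()
        assert np.allclose(out.to_numpy()[obs.to_numpy()],
                           m.loc[out.index].to_numpy()[obs.to_numpy()])

    def test_partial_within_plex_missingness_rejected(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams(n_proteins=4, dropout=(4, 0, 0)), seed=4
        )
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="partial"):
            impute_and_filter(m, design72)


# ---------------------------------------------------------------------------
# sample loading normalization
# ---------------------------------------------------------------------------

class TestSampleLoading:
    def test_two_columns_meet_at_mean_total(self):
        design = generate_design(1, 2, 1, 2, seed=0)
        m = pd.DataFrame(
            {design.index[0]: [60.0, 40.0], design.index[1]: [200.0, 100.0]},
            index=["p1", "p2"],
        )
        out = sample_loading_normalize(m, design)
        assert np.allclose(out.sum(axis=0), [200.0, 200.0])

    def test_equal_totals_unchanged(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams(n_proteins=30, dropout=(30, 0, 0),
                                  isoline_sd=0.0, diet_sd=0.0,
                                  interaction_sd=0.0, loading_sd=0.0,
                                  batch_sd=0.0, sigma=0.0),
            seed=5,
        )
        out = sample_loading_normalize(m, design72)
        assert np.allclose(out.to_numpy(), m.to_numpy(), rtol=1e-12)

    def test_per_plex_grand_sum_conserved(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams(n_proteins=50, dropout=(50, 0, 0)), seed=6
        )
        out = sample_loading_normalize(m, design72)
        for k, cols in m.columns.groupby(design72["plex"]).items():
            assert np.isclose(out[list(cols)].sum().sum(),
                              m[list(cols)].sum().sum())

    def test_zero_total_column_named_in_error(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams(n_proteins=5, dropout=(5, 0, 0)), seed=7
        )
        m[m.columns[3]] = 0.0
        with pytest.raises(ValueError, match=str(m.columns[3])):
            sample_loading_normalize(m, design72)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _naive_tmm(matrix: pd.DataFrame, m_trim: float, a_trim: float,
               ref: str) -> pd.Series:
    """Independent loop-based evaluation of the trim-and-weight formula."""
    totals = matrix.sum(axis=0)
    props = matrix / totals
    logf = {}
    for col in matrix.columns:
        if col == ref:
            logf[col] = 0.0
            continue
        rows = []
        for gene in matrix.index:
            pj, pr = props.at[gene, col], props.at[gene, ref]
            M = np.log2(pj / pr)
            A = 0.5 * np.log2(pj * pr)
            w = (1 - pj) / (totals[col] * pj) + (1 - pr) / (totals[ref] * pr)
            rows.append((gene, M, A, w))
        n = len(rows)
        by_m = sorted(rows, key=lambda r: r[1])
        by_a = sorted(rows, key=lambda r: r[2])
        lo_m, lo_a = int(np.floor(n * m_trim)) + 1, int(np.floor(n * a_trim)) + 1
        keep_m = {r[0] for r in by_m[lo_m - 1: n + 1 - lo_m]}
        keep_a = {r[0] for r in by_a[lo_a - 1: n + 1 - lo_a]}
        kept = [r for r in rows if r[0] in keep_m and r[0] in keep_a]
        num = sum(M / w for _, M, _, w in kept)
        den = sum(1 / w for _, _, _, w in kept)
        logf[col] = num / den
    f = pd.Series(logf).reindex(matrix.columns)
    return np.exp2(f - f.mean())


class TestTMM:
    def test_identical_columns_all_factors_one(self):
        m = pd.DataFrame(np.tile([[5.0], [9.0], [2.0], [14.0]], (1, 4)),
                         columns=list("abcd"))
        assert np.allclose(tmm_factors(m), 1.0)

    def test_scaled_column_absorbed_by_proportions(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(5, 50, 30)
        m = pd.DataFrame({"r": base, "j": 3.0 * base})
        f = tmm_factors(m, TMMParams(reference="r"))
        assert np.allclose(f, 1.0)

    def test_matches_naive_formula_on_toy(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(
            rng.uniform(10, 1000, (10, 4)),
            index=[f"g{i}" for i in range(10)], columns=list("abcd"),
        )
        params = TMMParams(m_trim=0.2, a_trim=0.1, reference="a")
        got = tmm_factors(m, params)
        expected = _naive_tmm(m, 0.2, 0.1, "a")
        assert np.allclose(got.to_numpy(), expected.to_numpy(), rtol=1e-10)

    def test_geometric_mean_one(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams(n_proteins=80, dropout=(80, 0, 0)), seed=8
        )
        f = tmm_factors(m)
        assert np.isclose(np.log(f).mean(), 0.0, atol=1e-9)

    def test_invalid_trims_rejected(self):
        with pytest.raises(ValueError):
            TMMParams(m_trim=0.6).validate()


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------

class TestCombat:
    def test_single_batch_returns_input(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams(n_proteins=10, dropout=(10, 0, 0)), seed=9
        )
        logm = np.log2(m)
        batch = pd.Series(1, index=logm.columns)
        out, model = combat_adjust(logm, batch)
        pd.testing.assert_frame_equal(out, logm)
        assert model is None

    def test_pure_location_shift_removed(self):
        rng = np.random.default_rng(10)
        n_per, P = 60, 200
        cols = [f"s{i}" for i in range(2 * n_per)]
        batch = pd.Series([1] * n_per + [2] * n_per, index=cols)
        data = rng.normal(0.0, 1.0, (P, 2 * n_per))
        data[:, n_per:] += 1.5  # constant location offset in batch 2
        logm = pd.DataFrame(data, columns=cols)
        out, _ = combat_adjust(logm, batch)
        diff = (out.iloc[:, n_per:].mean(axis=1)
                - out.iloc[:, :n_per].mean(axis=1))
        se = np.sqrt(2.0 / n_per)
        assert abs(diff.mean()) < 3 * se / np.sqrt(P)

    def test_batch_f_statistic_reduced(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams.batch_only(n_proteins=500), seed=11
        )
        logm = np.log2(m)
        out, _ = combat_adjust(logm, design72["plex"],
                               design72[["diet", "isoline"]])
        plex = design72["plex"]

        def mean_batch_f(df):
            fs = []
            for _, row in df.iterrows():
                groups = [row[plex[plex == k].index].to_numpy()
                          for k in plex.unique()]
                fs.append(one_way_anova(row, plex)[0])
            return np.mean(fs)

        assert mean_batch_f(out) < mean_batch_f(logm)

    def test_shrunken_locations_between_raw_and_prior(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams.batch_only(n_proteins=200), seed=12
        )
        _, model = combat_adjust(np.log2(m), design72["plex"],
                                 design72[["diet", "isoline"]])
        for b in model.batches:
            g_bar = model.hyper[b]["gamma_bar"]
            raw = model.gamma_hat[b].to_numpy()
            star = model.gamma_star[b].to_numpy()
            lo, hi = np.minimum(raw, g_bar), np.maximum(raw, g_bar)
            assert ((star >= lo - 1e-9) & (star <= hi + 1e-9)).all()
            assert (model.delta2_star[b] > 0).all()

    def test_confounded_design_rejected(self):
        cols = [f"s{i}" for i in range(8)]
        logm = pd.DataFrame(np.random.default_rng(1).normal(size=(5, 8)),
                            columns=cols)
        batch = pd.Series([1] * 4 + [2] * 4, index=cols)
        cov = pd.DataFrame({"diet": ["high"] * 4 + ["low"] * 4}, index=cols)
        with pytest.raises(ValueError, match="confounded"):
            combat_adjust(logm, batch, cov)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

class TestNormalizePipeline:
    def test_zero_effect_equal_loading_constant_output(self, design72):
        params = TruthParams(
            n_proteins=12, dropout=(12, 0, 0), isoline_sd=0.0, diet_sd=0.0,
            interaction_sd=0.0, batch_sd=0.0, loading_sd=0.0, sigma=0.0,
        )
        m, _ = simulate_intensities(design72, params, seed=13)
        norm, _ = normalize_pipeline(m, design72)
        assert np.allclose(norm.data.to_numpy().std(axis=1), 0.0, atol=1e-9)

    def test_batch_only_pc1_no_longer_separates_plexes(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams.batch_only(n_proteins=300), seed=14
        )
        norm, _ = normalize_pipeline(m, design72)
        pca = run_pca(norm.data)
        F, df1, df2 = one_way_anova(pca.scores["PC1"], design72["plex"])
        assert partial_epsilon_squared(F, df1, df2).epsilon2 < 0.06

    def test_output_finite_and_labels_preserved(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams(n_proteins=60, dropout=(40, 12, 8)), seed=15
        )
        norm, rep = normalize_pipeline(m, design72)
        assert np.isfinite(norm.data.to_numpy()).all()
        assert list(norm.data.columns) == list(m.columns)
        assert set(norm.data.index) <= set(m.index)
        assert len(norm.data) == rep.n_retained
        assert norm.provenance == (
            "impute_and_filter", "sample_loading_normalize", "tmm_scale",
            "log2", "combat_adjust",
        )

    def test_deterministic(self, design72):
        m, _ = simulate_intensities(
            design72, TruthParams(n_proteins=40, dropout=(40, 0, 0)), seed=16
        )
        a, _ = normalize_pipeline(m, design72)
        b, _ = normalize_pipeline(m, design72)
        pd.testing.assert_frame_equal(a.data, b.data)
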