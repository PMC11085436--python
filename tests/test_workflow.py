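"""Split, discretization, parameter trends and the selection pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crownlma as cl
from crownlma.data_model import Dataset
from crownlma.synthetic_data import GeneratorConfig, generate_dataset
from crownlma.workflow import (
    GroupedFit,
    PipelineConfig,
    discretize,
    grouped_fits,
    parameter_trend,
    run_pipeline,
    split_data,
)
from crownlma.metrics import FitReport


def _toy_dataset(n, rng=None, doys=None):
    rng = rng or np.random.default_rng(0)
    doys = doys if doys is not None else np.arange(150, 241, 15)
    df = pd.DataFrame({
        "plot_id": "P1",
        "tree_id": [f"T{i % 5}" for i in range(n)],
        "rdinc": rng.uniform(0.08, 0.99, n),
        "doy": rng.choice(doys, n),
        "lma_g_m2": rng.uniform(40, 100, n),
        "ldmc_g_g": rng.uniform(0.1, 0.6, n),
    })
    return Dataset(df)


class TestSplit:
    def test_study_scale_ceiling_split(self):
        fit_, val = split_data(_toy_dataset(779), fraction=0.75, seed=0)
        assert (len(fit_), len(val)) == (585, 194)

    def test_minimal_ceiling_split(self):
        fit_, val = split_data(_toy_dataset(4), fraction=0.75, seed=0)
        assert (len(fit_), len(val)) == (3, 1)

    def test_deterministic_at_fixed_seed(self):
        ds = _toy_dataset(100)
        a1, b1 = split_data(ds, seed=7)
        a2, b2 = split_data(ds, seed=7)
        pd.testing.assert_frame_equal(a1.df, a2.df)
        pd.testing.assert_frame_equal(b1.df, b2.df)

    @given(n=st.integers(2, 300), frac=st.floats(0.1, 0.9),
           seed=st.integers(0, 100))
    @settings(max_examples=40, deadline=None)
    def test_disjoint_and_exhaustive(self, n, frac, seed):
        import math
        if not (1 <= math.ceil(frac * n) <= n - 1):
            return
        ds = _toy_dataset(n)
        ds.df["uid"] = np.arange(n)
        fit_, val = split_data(ds, fraction=frac, seed=seed)
        ids = np.concatenate([fit_.df["uid"], val.df["uid"]])
        assert len(set(ids)) == n
        assert len(fit_) == math.ceil(frac * n)

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="degenerate|fraction"):
            split_data(_toy_dataset(3), fraction=0.95)

    def test_stratified_split_covers_every_tree(self):
        ds = _toy_dataset(100)
        fit_, val = split_data(ds, fraction=0.75, seed=3, stratify_by_tree=True)
        assert set(fit_.df["tree_id"]) == set(ds.df["tree_id"])
        assert len(fit_) + len(val) == 100


class TestDiscretize:
    def test_biweekly_doy_grid_yields_six_groups(self):
        ds = _toy_dataset(600)
        bins = discretize(ds, "doy", min_n=1)
        assert [b[0] for b in bins] == [150.0, 165.0, 180.0, 195.0, 210.0, 225.0]

    def test_rdinc_width_tenth_yields_ten_raw_bins(self, rng):
        n = 2000
        df = pd.DataFrame({
            "rdinc": rng.uniform(0.08, 0.99, n), "doy": 200,
            "lma_g_m2": 70.0, "ldmc_g_g": 0.3})
        bins = discretize(Dataset(df), "rdinc", min_n=1)
        assert len(bins) == 10
        assert bins[0][0] == 0.0 and bins[-1][0] == pytest.approx(0.9)

    def test_single_record_single_group(self):
        df = pd.DataFrame({"rdinc": [0.5], "doy": [200],
                           "lma_g_m2": [70.0], "ldmc_g_g": [0.3]})
        bins = discretize(Dataset(df), "rdinc", min_n=1)
        assert len(bins) == 1

    def test_small_bins_merge_into_nearest_neighbour(self):
        df = pd.DataFrame({
            "rdinc": [0.05] * 20 + [0.15] * 2 + [0.35] * 20,
            "doy": 200, "lma_g_m2": 70.0, "ldmc_g_g": 0.3})
        bins = discretize(Dataset(df), "rdinc", min_n=10)
        assert len(bins) == 2
        sizes = {start: len(idx) for start, idx in bins}
        assert sizes[0.0] == 22  # the n=2 bin merged downward (nearest)

    def test_partition_is_exhaustive(self, default_dataset):
        bins = discretize(default_dataset, "doy", min_n=1)
        total = sum(len(idx) for _, idx in bins)
        assert total == len(default_dataset)

    def test_unknown_covariate_rejected(self, default_dataset):
        with pytest.raises(ValueError, match="covariate"):
            discretize(default_dataset, "height")


class TestParameterTrend:
    def _grouped(self, midpoints, coef_fn):
        return [
            GroupedFit(group_key=m, midpoint=m, n=50,
                       coefficients=np.atleast_1d(coef_fn(m)),
                       fit_report=FitReport())
            for m in midpoints
        ]

    def test_exact_linear_trend_is_perfect_at_degree_one(self):
        grouped = self._grouped(np.linspace(0.1, 0.9, 6), lambda m: 3.0 * m + 1.0)
        trends = parameter_trend(grouped)
        best = trends[0][0]
        assert best.degree == 1
        assert best.r2 == pytest.approx(1.0, abs=1e-12)

    def test_exact_quadratic_beats_linear_by_adjusted_r2(self):
        grouped = self._grouped(np.linspace(30, 120, 7),
                                lambda m: 0.01 * m**2 - m + 4.0)
        trends = parameter_trend(grouped)
        assert trends[0][0].degree == 2

    def test_trend_coefficients_match_vandermonde_oracle(self, rng):
        mids = np.linspace(0.1, 0.9, 8)
        vals = rng.normal(0, 1, 8)
        grouped = self._grouped(mids, lambda m: vals[np.argmin(np.abs(mids - m))])
        trends = parameter_trend(grouped, degrees=(2,))
        V = np.vander(mids, 3)  # columns x^2, x, 1 (numpy convention)
        oracle = np.linalg.solve(V.T @ V, V.T @ vals)
        np.testing.assert_allclose(trends[0][0].coefficients, oracle, rtol=1e-8)

    def test_underdetermined_degrees_skipped(self):
        grouped = self._grouped([0.2, 0.5, 0.8], lambda m: m)
        trends = parameter_trend(grouped)
        assert {t.degree for t in trends[0]} == {1, 2}  # cubic skipped at 3 groups

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="3 groups"):
            parameter_trend(self._grouped([0.2, 0.5], lambda m: m))


class TestGroupedFits:
    def test_per_bin_fits_cover_partition(self, default_dataset):
        gf = grouped_fits(default_dataset, 1, "doy", min_n=10)
        assert sum(g.n for g in gf) == len(default_dataset)
        for g in gf:
            assert g.coefficients.size == 2


class TestPipeline:
    def test_generating_form_is_selected(self, default_dataset):
        """On data generated from the dynamic bivariate surface, the pipeline
        selects that surface among all 13 candidates."""
        result = run_pipeline(default_dataset, PipelineConfig(seed=1))
        assert result.best_id == 13

    def test_bivariate_models_outperform_univariate_parents(self, default_dataset):
        result = run_pipeline(default_dataset, PipelineConfig(seed=1))
        from crownlma.model_library import PARENT_MODEL
        for child, parent in PARENT_MODEL.items():
            r_child = result.candidates[child].fit_report.r2_adjusted
            r_parent = result.candidates[parent].fit_report.r2_adjusted
            assert r_child >= r_parent - 0.01

    def test_noiseless_limit_perfect_validation(self):
        ds = generate_dataset(GeneratorConfig(seed=2, sigma_lma=0.0))
        result = run_pipeline(ds, PipelineConfig(seed=2))
        assert result.best_id == 13
        assert result.validation_report.fi == pytest.approx(1.0, abs=1e-10)

    def test_deterministic_serialization(self, default_dataset):
        a = run_pipeline(default_dataset, PipelineConfig(seed=4)).to_json()
        b = run_pipeline(default_dataset, PipelineConfig(seed=4)).to_json()
        assert a == b

    def test_selection_tiebreak_order(self, default_dataset):
        result = run_pipeline(default_dataset, PipelineConfig(seed=1))
        best = result.candidates[result.best_id].fit_report
        for mid, m in result.candidates.items():
            assert (-best.r2_adjusted, best.rmse, best.aic) <= (
                -m.fit_report.r2_adjusted, m.fit_report.rmse, m.fit_report.aic)

    def test_stage_name_attached_to_errors(self):
        df = pd.DataFrame({"rdinc": [0.5] * 10, "doy": [200] * 10,
                           "lma_g_m2": np.linspace(60, 80, 10),
                           "ldmc_g_g": np.linspace(0.2, 0.4, 10)})
        with pytest.raises(ValueError, match="pipeline stage"):
            run_pipeline(Dataset(df), PipelineConfig(seed=0))

    def test_parameter_recovery_coverage(self):
        """Across replicates at study scale, the fitted RDINC coefficient is
        unbiased and its +/-2 SE interval covers the generating value at the
        nominal rate."""
        from crownlma.model_library import fit, get_form
        form = get_form(13)
        est, cover = [], 0
        n_rep = 120
        for rep in range(n_rep):
            ds = generate_dataset(GeneratorConfig(seed=10_000 + rep))
            m = fit(13, ds)
            df = ds.df
            data = {"rdinc": df["rdinc"].to_numpy(), "d": df["doy"].to_numpy() - 120.0}
            data["lead"] = data["rdinc"]
            X = form.basis(data)
            resid = df["lma_g_m2"].to_numpy() - X @ m.coefficients
            s2 = resid @ resid / (len(df) - 5)
            se0 = np.sqrt(s2 * np.linalg.inv(X.T @ X)[0, 0])
            est.append(m.coefficients[0])
            cover += abs(m.coefficients[0] + 37.08) < 2 * se0
        est = np.asarray(est)
        assert abs(est.mean() + 37.08) < 2 * est.std(ddof=1) / np.sqrt(n_rep)
        assert 0.88 <= cover / n_rep <= 1.0  # nominal ~0.95
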