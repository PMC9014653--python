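import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabsex.preprocess import (
    BELOW_QUANT_TAG,
    CleanMetaboliteData,
    QCReport,
    RawMetaboliteData,
    collapse_replicates,
    crossplate_normalize,
    filter_by_missingness,
    filter_participants_by_flags,
    impute_left_censored,
    mahalanobis_screen,
    replicate_quality,
    residualize_medications,
    run_qc,
    transform_concentrations,
)


def make_raw(values, plate=None, group=None, lod=None, platform="targeted", **kw):
    """Small-fixture helper: one record per row of ``values``."""
    values = pd.DataFrame(values)
    values.index = [f"r{i}" for i in range(len(values))]
    values.columns = [f"met{j}" for j in range(values.shape[1])]
    plate = pd.Series(plate if plate is not None else ["p0"] * len(values), index=values.index)
    group = pd.Series(group if group is not None else list(values.index), index=values.index)
    if lod is None and platform == "targeted":
        lod = pd.DataFrame(0.0, index=values.columns, columns=sorted(plate.unique()))
    return RawMetaboliteData(values=values, plate_of=plate, replicate_group=group,
                             lod=lod, platform=platform, **kw)


class TestMissingness:
    def test_boundary_inclusive_for_metabolites(self):
        # 2/10 missing at threshold 0.20 -> removed ("20% or more")
        vals = np.ones((10, 2))
        vals[:2, 0] = np.nan
        data = make_raw(vals)
        out, report = filter_by_missingness(data, 0.20, 0.40)
        assert list(out.values.columns) == ["met1"]
        assert report.removed_metabolites == [("met0", "missingness")]

    def test_below_boundary_retained(self):
        vals = np.ones((10, 2))
        vals[0, 0] = np.nan
        out, _ = filter_by_missingness(make_raw(vals), 0.20, 0.40)
        assert list(out.values.columns) == ["met0", "met1"]

    def test_participant_boundary_exclusive(self):
        # exactly 40% missing is retained ("greater than 40%")
        vals = np.ones((4, 5))
        vals[0, :2] = np.nan  # 40%
        vals[1, :3] = np.nan  # 60%
        out, report = filter_by_missingness(make_raw(vals), 0.99, 0.40)
        assert "r0" in out.values.index and "r1" not in out.values.index
        assert report.removed_participants == [("r1", "missingness")]

    def test_constructed_counts(self):
        # 3 metabolites over threshold, then 1 participant over 0.40
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 2, size=(10, 10))
        vals[:2, 0] = np.nan
        vals[:3, 1] = np.nan
        vals[:9, 2] = np.nan
        vals[5, 3:7] = np.nan  # 4/7 = 57% after the 3 bad metabolites are gone
        out, report = filter_by_missingness(make_raw(vals), 0.20, 0.40)
        assert len(report.metabolites_removed_for("missingness")) == 3
        assert len(report.participants_removed_for("missingness")) == 1
        assert out.values.shape == (9, 7)

    def test_metabolites_removed_before_participants(self):
        # participant exceeds 40% only if the bad metabolite is kept
        vals = np.ones((10, 5))
        vals[:, 0] = np.nan  # fully missing metabolite
        vals[0, 1] = np.nan  # 2/5 = 40% with met0; 1/4 = 25% without
        out, report = filter_by_missingness(make_raw(vals), 0.20, 0.30)
        assert "r0" in out.values.index

    def test_empty_result_errors(self):
        vals = np.full((3, 2), np.nan)
        with pytest.raises(ValueError, match="empty"):
            filter_by_missingness(make_raw(vals), 0.20, 0.40)

    @pytest.mark.parametrize("bad", [0.0, 1.5, -0.1])
    def test_threshold_validation(self, bad):
        with pytest.raises(ValueError):
            filter_by_missingness(make_raw(np.ones((3, 2))), bad, 0.4)


class TestCrossplateNormalize:
    def test_hand_computed_scaling(self):
        # plate means 10 and 20 -> grand mean 15 -> factors 1.5 and 0.75
        vals = np.array([[8.0], [12.0], [18.0], [22.0]])
        data = make_raw(vals, plate=["p0", "p0", "p1", "p1"])
        out = crossplate_normalize(data)
        np.testing.assert_allclose(out.values.iloc[:2, 0], [12.0, 18.0])
        np.testing.assert_allclose(out.values.iloc[2:, 0], [13.5, 16.5])
        assert out.values.iloc[:2, 0].mean() == pytest.approx(15.0)
        assert out.values.iloc[2:, 0].mean() == pytest.approx(15.0)

    def test_single_plate_identity(self):
        data = make_raw(np.array([[1.0], [2.0]]))
        out = crossplate_normalize(data)
        pd.testing.assert_frame_equal(out.values, data.values)

    def test_equal_means_fixed_point(self):
        vals = np.array([[10.0], [20.0], [12.0], [18.0]])
        data = make_raw(vals, plate=["p0", "p0", "p1", "p1"])
        out = crossplate_normalize(data)
        pd.testing.assert_frame_equal(out.values, data.values)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 10, size=(20, 4))
        data = make_raw(vals, plate=["p0", "p1"] * 10)
        once = crossplate_normalize(data)
        twice = crossplate_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_missing_plate_warns_and_skips(self):
        vals = np.array([[1.0, 1.0], [2.0, 1.0], [np.nan, 2.0], [np.nan, 4.0]])
        data = make_raw(vals, plate=["p0", "p0", "p1", "p1"])
        with pytest.warns(UserWarning, match="all-missing"):
            out = crossplate_normalize(data)
        assert out.values["met0"].isna().sum() == 2


class TestReplicateQuality:
    def test_pair_cv_closed_form(self):
        # sd(90, 110) = 200**0.5 * ... = 14.142; cv = 0.14142 -> retained
        vals = np.array([[90.0], [110.0]])
        data = make_raw(vals, group=["a", "a"])
        out, cv, icc, _ = replicate_quality(data, cv_max=0.20, icc_min=0.0)
        assert cv["met0"] == pytest.approx(np.sqrt(200.0) / 100.0, rel=1e-12)
        assert "met0" in out.values.columns

    def test_identical_pairs_perfect(self):
        vals = np.array([[1.0], [1.0], [5.0], [5.0], [9.0], [9.0]])
        data = make_raw(vals, group=["a", "a", "b", "b", "c", "c"])
        out, cv, icc, _ = replicate_quality(data)
        assert cv["met0"] == 0.0
        assert icc["met0"] == pytest.approx(1.0)
        assert "met0" in out.values.columns

    def test_pure_noise_low_icc_removed(self):
        # no between-participant variance -> ICC ~ 0 -> removed at 0.65
        rng = np.random.default_rng(2)
        n_pairs = 200
        vals = rng.normal(100, 10, size=(2 * n_pairs, 1))
        groups = np.repeat([f"g{i}" for i in range(n_pairs)], 2)
        data = make_raw(vals, group=list(groups))
        out, cv, icc, report = replicate_quality(data, cv_max=1.0, icc_min=0.65)
        assert abs(icc["met0"]) < 0.2
        assert "met0" not in out.values.columns
        assert report.removed_metabolites == [("met0", "icc")]

    def test_high_cv_removed(self):
        vals = np.array([[50.0], [150.0], [60.0], [140.0]])
        data = make_raw(vals, group=["a", "a", "b", "b"])
        out, cv, icc, report = replicate_quality(data, cv_max=0.20, icc_min=0.0)
        assert cv["met0"] > 0.20
        assert "met0" not in out.values.columns
        assert ("met0", "cv") in report.removed_metabolites

    def test_no_replicates_warns(self):
        data = make_raw(np.ones((3, 1)) * [[1.0], [2.0], [3.0]])
        with pytest.warns(UserWarning, match="skipped"):
            out, cv, icc, _ = replicate_quality(data)
        assert cv.isna().all()
        assert out.values.shape == data.values.shape


class TestCollapseReplicates:
    def test_pair_mean(self):
        data = make_raw(np.array([[4.0], [6.0]]), group=["a", "a"])
        out = collapse_replicates(data)
        assert out.values.loc["a", "met0"] == 5.0

    def test_pair_with_missing(self):
        data = make_raw(np.array([[4.0], [np.nan]]), group=["a", "a"])
        out = collapse_replicates(data)
        assert out.values.loc["a", "met0"] == 4.0

    def test_triplicate(self):
        data = make_raw(np.array([[1.0], [2.0], [9.0]]), group=["a", "a", "a"])
        out = collapse_replicates(data)
        assert out.values.loc["a", "met0"] == 4.0

    def test_all_missing_stays_missing(self):
        data = make_raw(np.array([[np.nan], [np.nan]]), group=["a", "a"])
        out = collapse_replicates(data)
        assert np.isnan(out.values.loc["a", "met0"])

    def test_one_row_per_participant(self):
        data = make_raw(np.arange(8.0).reshape(4, 2), group=["a", "a", "b", "c"])
        out = collapse_replicates(data)
        assert sorted(out.values.index) == ["a", "b", "c"]


class TestFlagFilters:
    def test_nonfasting_removed(self):
        fasting = pd.Series({"r0": False, "r1": True})
        data = make_raw(np.ones((2, 2)), fasting=fasting)
        out, report = filter_participants_by_flags(data)
        assert list(out.values.index) == ["r1"]
        assert report.removed_participants == [("r0", "non-fasting")]

    def test_nmr_contamination_tag_removed(self):
        vals = np.array([[np.nan, 1.0], [np.nan, 2.0], [1.0, 3.0]])
        tags = pd.DataFrame(
            [["low ethanol", None], [BELOW_QUANT_TAG, None], [None, None]],
            index=["r0", "r1", "r2"], columns=["met0", "met1"],
        )
        data = make_raw(vals, platform="nmr", qc_tags=tags)
        out, report = filter_participants_by_flags(data)
        assert list(out.values.index) == ["r1", "r2"]
        assert ("r0", "qc-tag") in report.removed_participants

    def test_below_quantification_retained(self):
        vals = np.array([[np.nan], [2.0]])
        tags = pd.DataFrame([[BELOW_QUANT_TAG], [None]], index=["r0", "r1"], columns=["met0"])
        data = make_raw(vals, platform="nmr", qc_tags=tags)
        out, _ = filter_participants_by_flags(data)
        assert list(out.values.index) == ["r0", "r1"]

    def test_targeted_ignores_tags(self):
        vals = np.array([[np.nan], [2.0]])
        tags = pd.DataFrame([["low ethanol"], [None]], index=["r0", "r1"], columns=["met0"])
        data = make_raw(vals, qc_tags=tags)
        out, _ = filter_participants_by_flags(data)
        assert len(out.values) == 2


class TestImputation:
    def test_half_lod(self):
        vals = np.array([[np.nan], [1.0]])
        lod = pd.DataFrame({"p0": [0.4]}, index=["met0"])
        data = make_raw(vals, lod=lod)
        out, report = impute_left_censored(data)
        assert out.values.loc["r0", "met0"] == pytest.approx(0.2)
        assert report.imputation_log == [("r0", "met0", 0.2, "half-lod")]

    def test_half_min_nmr(self):
        vals = np.array([[np.nan], [0.06], [0.5]])
        data = make_raw(vals, platform="nmr")
        out, report = impute_left_censored(data)
        assert out.values.loc["r0", "met0"] == pytest.approx(0.03)
        assert report.imputation_log == [("r0", "met0", 0.03, "half-min")]

    def test_missing_lod_entry_errors(self):
        vals = np.array([[np.nan], [1.0]])
        lod = pd.DataFrame({"p0": [np.nan]}, index=["met0"])
        data = make_raw(vals, lod=lod)
        with pytest.raises(ValueError, match="LOD"):
            impute_left_censored(data)

    def test_278_censored_cells_logged(self):
        # fixture constructed with exactly 278 censored cells across 26 metabolites
        rng = np.random.default_rng(7)
        n, p = 300, 30
        vals = rng.uniform(1, 5, size=(n, p))
        cells = []
        for j in range(26):
            k = 278 // 26 + (1 if j < 278 % 26 else 0)
            rows = rng.choice(n, size=k, replace=False)
            for i in rows:
                cells.append((i, j))
        for i, j in cells:
            vals[i, j] = np.nan
        assert len(cells) == 278
        lod = pd.DataFrame(0.5, index=[f"met{j}" for j in range(p)], columns=["p0"])
        data = make_raw(vals, lod=lod)
        out, report = impute_left_censored(data)
        assert len(report.imputation_log) == 278
        assert out.values.notna().all().all()
        imputed_mets = {m for _, m, _, _ in report.imputation_log}
        assert len(imputed_mets) == 26


class TestTransform:
    def test_hand_computed_column(self):
        # (0,1,3) -> log2+1 -> (0,1,2) -> z with population SD 0.8165
        vals = np.array([[0.0, 1.0], [1.0, 2.0], [3.0, 4.0]])
        clean = transform_concentrations(make_raw(vals))
        expect = np.array([-1.224744871, 0.0, 1.224744871])
        np.testing.assert_allclose(clean.matrix["met0"], expect, rtol=1e-9)

    def test_winsor_clamps(self):
        rng = np.random.default_rng(3)
        vals = np.exp(rng.normal(size=(200, 1)))
        vals[0, 0] = 1e6  # extreme z-score
        clean = transform_concentrations(make_raw(vals), winsor_limit=3.0)
        assert clean.matrix.iloc[0, 0] == pytest.approx(3.0)
        assert clean.matrix.to_numpy().min() >= -3.0
        assert clean.matrix.to_numpy().max() <= 3.0

    def test_zscore_before_winsor(self):
        rng = np.random.default_rng(4)
        vals = np.exp(rng.normal(size=(500, 3)))
        clean = transform_concentrations(make_raw(vals), winsor_limit=None)
        assert np.all(np.abs(clean.matrix.mean(axis=0)) < 1e-8)
        assert np.all(np.abs(clean.matrix.std(axis=0, ddof=0) - 1) < 1e-8)

    def test_constant_column_errors(self):
        vals = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="met0"):
            transform_concentrations(make_raw(vals))

    def test_missing_values_rejected(self):
        vals = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="complete"):
            transform_concentrations(make_raw(vals))

    def test_provenance_records_order(self):
        vals = np.abs(np.random.default_rng(5).normal(size=(50, 2))) + 0.1
        clean = transform_concentrations(make_raw(vals))
        assert [s["step"] for s in clean.provenance] == [
            "add_constant", "log2", "zscore", "winsorize",
        ]


class TestMahalanobis:
    def test_planted_point_chi2_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(500, 2))
        X[0] = [5.0, 5.0]  # D2 ~ 50; chi2.sf(50, 2) ~ 1.4e-11
        flags = mahalanobis_screen(X, alpha=0.001)
        assert flags[0]
        assert stats.chi2.sf(50.0, 2) < 1e-10

    def test_singular_covariance_errors(self):
        X = np.ones((10, 3)) + 1e-15 * np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="singular"):
            mahalanobis_screen(X)

    def test_matches_bruteforce_quadratic_form(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 3))
        mu = X.mean(axis=0)
        S = np.cov(X, rowvar=False, ddof=1)
        Sinv = np.linalg.inv(S)
        d2_brute = np.array([(x - mu) @ Sinv @ (x - mu) for x in X])
        for alpha in (0.5, 0.1, 0.01):
            expect = stats.chi2.sf(d2_brute, 3) < alpha
            got = mahalanobis_screen(X, alpha=alpha)
            np.testing.assert_array_equal(got, expect)

    def test_needs_more_rows_than_columns(self):
        with pytest.raises(ValueError, match="rows"):
            mahalanobis_screen(np.random.default_rng(0).normal(size=(5, 5)))

    def test_null_flag_rate_near_nominal(self):
        # estimated covariance makes the rate approximate; tolerance doubled
        rng = np.random.default_rng(9)
        total, flagged = 0, 0
        for _ in range(10):
            X = rng.normal(size=(2000, 5))
            flagged += int(mahalanobis_screen(X, alpha=0.001).sum())
            total += 2000
        rate = flagged / total
        half_width = 2 * 1.96 * np.sqrt(0.001 * 0.999 / total)
        assert abs(rate - 0.001) < half_width


class TestResidualizeMedications:
    def _clean(self, n, p, seed):
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(
            rng.normal(size=(n, p)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"met{j}" for j in range(p)],
        )
        return CleanMetaboliteData(mat), rng

    def test_zero_medications_identity(self):
        clean, _ = self._clean(50, 3, 0)
        meds = pd.DataFrame(index=clean.matrix.index)
        out = residualize_medications(clean, meds)
        pd.testing.assert_frame_equal(out.matrix, clean.matrix)

    def test_null_effects_mostly_pass_through(self):
        clean, rng = self._clean(500, 40, 1)
        meds = pd.DataFrame(
            (rng.random((500, 3)) < 0.3).astype(int),
            index=clean.matrix.index, columns=["a", "b", "c"],
        )
        out = residualize_medications(clean, meds, alpha_keep=0.05)
        unchanged = (out.matrix == clean.matrix).all(axis=0)
        # per column, P(no predictor survives backward selection) ~ (1-alpha)^3
        assert unchanged.mean() > 0.70

    def test_injected_effect_recovered(self):
        clean, rng = self._clean(500, 5, 2)
        med = (rng.random(500) < 0.4).astype(float)
        clean.matrix["met0"] = clean.matrix["met0"] + 1.0 * med
        meds = pd.DataFrame({"m": med}, index=clean.matrix.index)
        out = residualize_medications(clean, meds, alpha_keep=0.05)
        r = np.corrcoef(out.matrix["met0"], med)[0, 1]
        assert abs(r) < 0.05
        assert not out.matrix["met0"].equals(clean.matrix["met0"])

    def test_duplicate_columns_dropped(self):
        clean, rng = self._clean(100, 2, 3)
        med = (rng.random(100) < 0.5).astype(int)
        meds = pd.DataFrame({"a": med, "b": med}, index=clean.matrix.index)
        with pytest.warns(UserWarning, match="collinear"):
            residualize_medications(clean, meds)


class TestRunQC:
    def test_pipeline_trajectory_and_bounds(self, small_cohort):
        clean, report = run_qc(small_cohort.raw)
        assert clean.matrix.notna().all().all()
        assert clean.matrix.to_numpy().min() >= -3.0
        assert clean.matrix.to_numpy().max() <= 3.0
        steps = [s["step"] for s in report.steps]
        assert steps.index("filter_by_missingness") < steps.index("collapse_replicates")
        assert steps.index("collapse_replicates") < steps.index("impute_left_censored")
        assert steps.index("impute_left_censored") < steps.index("transform_concentrations")
        # counts reconcile with dimension trajectory
        n_removed_mets = len(report.removed_metabolites)
        assert report.steps[0]["n_metabolites"] - n_removed_mets == clean.matrix.shape[1]

    def test_manual_exclusions(self, small_cohort):
        clean, report = run_qc(small_cohort.raw, manual_exclusions=("M0000",))
        assert "M0000" not in clean.matrix.columns
        assert ("M0000", "manual") in report.removed_metabolites
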