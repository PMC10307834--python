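"""Filtering rules, per-probe tests, Bonferroni and pipeline behaviour."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hlameth.dmp_pipeline import (
    AssociationConfig,
    apply_blocklist,
    bonferroni,
    compare_cell_types,
    dmp_regression,
    dmp_ttest,
    filter_detection_p,
    run_dmp,
    subset_region,
)
from hlameth.errors import DataError
from hlameth.io_formats import RegionDefinition

from conftest import make_cohort, make_probe, matrix_from_array


# ------------------------------------------------------------ detection-P

def _detp_fixture(n_failures: int):
    betas = matrix_from_array(np.full((1, 10), 0.5))
    detp_vals = np.zeros((1, 10))
    detp_vals[0, :n_failures] = 0.5
    detp = matrix_from_array(detp_vals)
    return betas, detp


def test_detection_p_exactly_ten_percent_kept():
    betas, detp = _detp_fixture(1)  # 10% failures: "more than 10%" is strict
    kept, dropped = filter_detection_p(betas, detp)
    assert kept.shape == (1, 10) and dropped == []


def test_detection_p_twenty_percent_dropped():
    betas, detp = _detp_fixture(2)
    kept, dropped = filter_detection_p(betas, detp)
    assert kept.shape == (0, 10) and dropped == ["p0"]


def test_detection_p_all_zero_nothing_dropped():
    betas, detp = _detp_fixture(0)
    kept, dropped = filter_detection_p(betas, detp)
    assert dropped == []


def test_detection_p_boundary_cut_is_failure():
    # detP exactly 0.01 counts as a failed measurement (>= cut)
    betas = matrix_from_array(np.full((1, 10), 0.5))
    detp = matrix_from_array(np.full((1, 10), 0.01))
    _, dropped = filter_detection_p(betas, detp)
    assert dropped == ["p0"]


def test_detection_p_axis_mismatch():
    betas = matrix_from_array(np.full((2, 3), 0.5))
    detp = matrix_from_array(np.zeros((2, 4)))
    with pytest.raises(DataError):
        filter_detection_p(betas, detp)


# -------------------------------------------------------------- blocklist

def test_blocklist_removes_rows():
    betas = matrix_from_array(np.full((3, 2), 0.5), probe_ids=["a", "b", "c"])
    kept, n = apply_blocklist(betas, {"b"})
    assert kept.probe_ids == ["a", "c"] and n == 1


def test_blocklist_empty_is_identity():
    betas = matrix_from_array(np.full((3, 2), 0.5))
    kept, n = apply_blocklist(betas, set())
    assert kept.probe_ids == betas.probe_ids and n == 0


def test_blocklist_absent_probe_noop():
    betas = matrix_from_array(np.full((2, 2), 0.5), probe_ids=["a", "b"])
    kept, n = apply_blocklist(betas, {"zzz"})
    assert kept.probe_ids == ["a", "b"] and n == 0


# ----------------------------------------------------------------- region

def test_subset_region_inclusive_bounds():
    region = RegionDefinition("r", "6", 26_000_000, 35_000_000)
    manifest = [
        make_probe("at_start", binding_pos=26_000_000),
        make_probe("before", binding_pos=25_999_999),
        make_probe("chr7", chromosome="7", binding_pos=30_000_000),
    ]
    betas = matrix_from_array(
        np.full((3, 2), 0.5), probe_ids=["at_start", "before", "chr7"]
    )
    kept = subset_region(betas, manifest, region)
    assert kept.probe_ids == ["at_start"]


def test_subset_region_missing_manifest_entry():
    region = RegionDefinition("r", "6", 1, 10)
    betas = matrix_from_array(np.full((1, 2), 0.5), probe_ids=["unknown"])
    with pytest.raises(DataError, match="unknown"):
        subset_region(betas, [], region)


# ----------------------------------------------------------------- t-test

def test_ttest_zero_variance_flagged(cohort):
    betas = matrix_from_array(
        np.full((1, 84), 0.5), sample_ids=[s.sample_id for s in cohort]
    )
    res = dmp_ttest(betas, cohort)
    row = res.iloc[0]
    assert row["difference"] == 0.0
    assert np.isnan(row["p_ttest"])
    assert row["ttest_flag"] == "zero_variance"


def test_ttest_printed_mean_difference(cohort):
    """Group means of (0.8049, 0.7651) reproduce a -0.0398 difference."""
    sample_ids = [s.sample_id for s in cohort]
    case_vals = 0.7651 + 0.01 * np.tile([1, -1], 21)
    ctrl_vals = 0.8049 + 0.01 * np.tile([1, -1], 21)
    betas = matrix_from_array(
        np.concatenate([case_vals, ctrl_vals])[None, :], sample_ids=sample_ids
    )
    res = dmp_ttest(betas, cohort)
    assert res.iloc[0]["mean_beta_case"] == pytest.approx(0.7651, abs=1e-12)
    assert res.iloc[0]["mean_beta_control"] == pytest.approx(0.8049, abs=1e-12)
    assert res.iloc[0]["difference"] == pytest.approx(-0.0398, abs=1e-12)


def test_ttest_matches_scipy_per_probe(cohort, rng):
    sample_ids = [s.sample_id for s in cohort]
    vals = rng.uniform(0.2, 0.8, size=(5, 84))
    betas = matrix_from_array(vals, sample_ids=sample_ids)
    res = dmp_ttest(betas, cohort)
    for i in range(5):
        expected = stats.ttest_ind(vals[i, :42], vals[i, 42:], equal_var=True)
        assert res.iloc[i]["p_ttest"] == pytest.approx(expected.pvalue)


def test_ttest_insufficient_group(cohort):
    sample_ids = [s.sample_id for s in cohort]
    vals = np.full((1, 84), np.nan)
    vals[0, :1] = 0.5       # one case value
    vals[0, 42:] = 0.5      # all controls
    betas = matrix_from_array(vals, sample_ids=sample_ids)
    res = dmp_ttest(betas, cohort)
    assert res.iloc[0]["ttest_flag"] == "insufficient"
    assert np.isnan(res.iloc[0]["p_ttest"])


def test_ttest_missing_excluded_pairwise(cohort):
    sample_ids = [s.sample_id for s in cohort]
    vals = np.concatenate([np.full(42, 0.4), np.full(42, 0.6)])[None, :].copy()
    vals[0, 0] = np.nan
    vals = vals + np.tile([0.01, -0.01], 42)[None, :]
    betas = matrix_from_array(vals, sample_ids=sample_ids)
    res = dmp_ttest(betas, cohort)
    assert res.iloc[0]["n_case"] == 41 and res.iloc[0]["n_control"] == 42


def test_ttest_detects_planted_shift_small_mc():
    """Shift -0.05 at sd 0.03, n=42/42: overwhelmingly significant."""
    cohort = make_cohort()
    sample_ids = [s.sample_id for s in cohort]
    rng = np.random.default_rng(7)
    hits = 0
    reps = 25
    for _ in range(reps):
        case = rng.normal(0.45, 0.03, 42)
        ctrl = rng.normal(0.50, 0.03, 42)
        betas = matrix_from_array(
            np.concatenate([case, ctrl])[None, :], sample_ids=sample_ids
        )
        if dmp_ttest(betas, cohort).iloc[0]["p_ttest"] < 1e-6:
            hits += 1
    assert hits >= int(0.95 * reps)


# ------------------------------------------------------------- regression

def _carrier_vector(cohort):
    return np.array([s.dqb1_0602_carrier for s in cohort], float)


def test_regression_noiseless_orthogonal_covariate_equals_ttest_difference():
    # carrier status balanced within groups -> orthogonal to case status
    cohort = make_cohort(carriers_case=21, carriers_ctrl=21)
    sample_ids = [s.sample_id for s in cohort]
    is_case = np.array([s.group == "case" for s in cohort], float)
    beta_row = 0.4 + 0.05 * is_case  # exact, noiseless
    betas = matrix_from_array(beta_row[None, :], sample_ids=sample_ids)
    tt = dmp_ttest(betas, cohort)
    reg = dmp_regression(betas, cohort)
    assert abs(reg.iloc[0]["coef_regression"] - tt.iloc[0]["difference"]) < 1e-10
    assert reg.iloc[0]["regression_flag"] == "zero_residual"


def test_regression_collinear_design_flagged():
    # every sample a carrier: carrier column collinear with the intercept
    cohort = make_cohort(carriers_case=42, carriers_ctrl=42)
    sample_ids = [s.sample_id for s in cohort]
    betas = matrix_from_array(
        np.random.default_rng(0).uniform(0.3, 0.7, (3, 84)), sample_ids=sample_ids
    )
    reg = dmp_regression(betas, cohort)
    assert (reg["regression_flag"] == "collinear").all()
    assert reg["p_regression"].isna().all()


def test_regression_matches_reference_ols(cohort, rng):
    """Cross-check the vectorized fit against an independent lstsq solve."""
    sample_ids = [s.sample_id for s in cohort]
    vals = rng.uniform(0.2, 0.8, size=(4, 84))
    betas = matrix_from_array(vals, sample_ids=sample_ids)
    reg = dmp_regression(betas, cohort)
    X = np.column_stack(
        [
            np.ones(84),
            np.array([s.group == "case" for s in cohort], float),
            _carrier_vector(cohort),
        ]
    )
    for i in range(4):
        coef, res_ss, *_ = np.linalg.lstsq(X, vals[i], rcond=None)
        dof = 84 - 3
        sigma2 = res_ss[0] / dof
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = coef[1] / se
        p = 2 * stats.t.sf(abs(t), dof)
        assert reg.iloc[i]["coef_regression"] == pytest.approx(coef[1], rel=1e-10)
        assert reg.iloc[i]["p_regression"] == pytest.approx(p, rel=1e-8)


def test_regression_missing_cells_refit(cohort, rng):
    sample_ids = [s.sample_id for s in cohort]
    vals = rng.uniform(0.2, 0.8, size=(2, 84))
    vals[1, 5] = np.nan
    betas = matrix_from_array(vals, sample_ids=sample_ids)
    reg = dmp_regression(betas, cohort)
    assert reg["regression_flag"].tolist() == ["ok", "ok"]
    assert reg["p_regression"].notna().all()


def test_regression_carrier_mediated_vs_direct_small_mc():
    """Carrier-driven effects lose p_case after adjustment; direct ones keep it."""
    cohort = make_cohort()  # 42/42 carriers vs 8/42
    sample_ids = [s.sample_id for s in cohort]
    is_case = np.array([s.group == "case" for s in cohort], float)
    carrier = _carrier_vector(cohort)
    rng = np.random.default_rng(11)
    reps = 30
    carrier_ok = direct_ok = 0
    for _ in range(reps):
        noise = rng.normal(0, 0.03, (2, 84))
        y_carrier = 0.5 - 0.19 * carrier + noise[0]
        y_direct = 0.5 - 0.05 * is_case + noise[1]
        betas = matrix_from_array(
            np.vstack([y_carrier, y_direct]), sample_ids=sample_ids
        )
        tt = dmp_ttest(betas, cohort)
        reg = dmp_regression(betas, cohort)
        if (
            tt.iloc[0]["p_ttest"] < 0.05
            and reg.iloc[0]["p_regression"] > 0.05
            and reg.iloc[0]["p_covariate"] < 0.01
        ):
            carrier_ok += 1
        if reg.iloc[1]["p_regression"] < 0.05:
            direct_ok += 1
    assert carrier_ok >= int(0.8 * reps)
    assert direct_ok >= int(0.9 * reps)


def test_adjustment_rank_consistency():
    """Carrier independent of case: t-test and adjusted P agree in rank."""
    cohort = make_cohort(carriers_case=21, carriers_ctrl=21)
    sample_ids = [s.sample_id for s in cohort]
    rng = np.random.default_rng(3)
    vals = rng.beta(5, 5, size=(300, 84))
    betas = matrix_from_array(vals, sample_ids=sample_ids)
    tt = dmp_ttest(betas, cohort)
    reg = dmp_regression(betas, cohort)
    rho = stats.spearmanr(tt["p_ttest"], reg["p_regression"]).statistic
    assert rho > 0.95


# ------------------------------------------------------------- bonferroni

def test_bonferroni_threshold():
    flags, thr = bonferroni([0.004, 0.006], alpha_family=0.05, n_tests=10)
    assert thr == pytest.approx(0.005)
    assert flags.tolist() == [True, False]


def test_bonferroni_exact_threshold_not_significant():
    flags, thr = bonferroni([0.005], alpha_family=0.05, n_tests=10)
    assert flags.tolist() == [False]


def test_bonferroni_single_test():
    flags, thr = bonferroni([0.04], alpha_family=0.05, n_tests=1)
    assert thr == pytest.approx(0.05) and flags.tolist() == [True]


def test_bonferroni_is_computed_not_hardcoded():
    # alpha/n for n=12181 is ~4.105e-6, not the rounded 4.06e-6
    _, thr = bonferroni(np.full(12181, 0.5), alpha_family=0.05)
    assert thr == pytest.approx(0.05 / 12181)
    assert abs(thr - 4.06e-6) > 1e-8


def test_bonferroni_nan_never_significant():
    flags, _ = bonferroni([np.nan, 1e-9], alpha_family=0.05, n_tests=2)
    assert flags.tolist() == [False, True]


# -------------------------------------------------------------- cell types

def _results(sig_probes, all_probes, diff_sign=-1.0):
    p = pd.Series(
        [0.01 if pid in sig_probes else 0.5 for pid in all_probes], index=all_probes
    )
    return pd.DataFrame(
        {"p_ttest": p, "difference": diff_sign * 0.05 * np.ones(len(all_probes))}
    )


def test_compare_cell_types_disjoint():
    universe = [f"p{i}" for i in range(10)]
    out = compare_cell_types(
        _results({"p0", "p1"}, universe), _results({"p5"}, universe)
    )
    assert (out.n_significant_a, out.n_significant_b, out.n_common) == (2, 1, 0)


def test_compare_cell_types_identical():
    universe = [f"p{i}" for i in range(6)]
    res = _results({"p0", "p1", "p2"}, universe)
    out = compare_cell_types(res, res.copy())
    assert out.n_common == 3 == out.n_significant_a == out.n_significant_b


def test_compare_cell_types_partial_overlap_and_fractions():
    universe = [f"p{i}" for i in range(10)]
    a = _results({"p0", "p1", "p2", "p3", "p4"}, universe, diff_sign=-1.0)
    b = _results({"p2", "p3", "p4", "p5"}, universe, diff_sign=+1.0)
    out = compare_cell_types(a, b)
    assert (out.n_significant_a, out.n_significant_b, out.n_common) == (5, 4, 3)
    assert out.hypo_fraction_a == 1.0
    assert out.hypo_fraction_b == 0.0 and out.hyper_fraction_b == 1.0


def test_compare_cell_types_universe_mismatch():
    with pytest.raises(DataError):
        compare_cell_types(_results(set(), ["a"]), _results(set(), ["b"]))


# ---------------------------------------------------------------- pipeline

def test_run_dmp_order_and_counts(cohort, rng):
    region = RegionDefinition("r", "6", 1_000, 2_000)
    manifest = [
        make_probe("in1", binding_pos=1_500),
        make_probe("in2", binding_pos=1_600),
        make_probe("out1", binding_pos=5_000),
        make_probe("blocked", binding_pos=1_700),
        make_probe("faildet", binding_pos=1_800),
    ]
    ids = [p.probe_id for p in manifest]
    sample_ids = [s.sample_id for s in cohort]
    betas = matrix_from_array(
        rng.uniform(0.3, 0.7, (5, 84)), probe_ids=ids, sample_ids=sample_ids
    )
    detp_vals = np.zeros((5, 84))
    detp_vals[4, :20] = 0.5  # >10% failures
    detp = matrix_from_array(detp_vals, probe_ids=ids, sample_ids=sample_ids)
    result, meta = run_dmp(
        betas, detp, manifest, cohort, region, blocklist={"blocked"}
    )
    assert meta["probes_in"] == 5
    assert meta["dropped_detection_p"] == 1
    assert meta["dropped_blocklist"] == 1
    assert meta["probes_in_region"] == 2 == meta["probes_tested"]
    assert sorted(result.index) == ["in1", "in2"]
    assert meta["alpha_threshold"] == pytest.approx(0.05 / 2)
    assert {"coef_regression", "p_regression", "p_covariate"} <= set(result.columns)


def test_run_dmp_deterministic(cohort, rng):
    region = RegionDefinition("r", "6", 1, 10_000)
    manifest = [make_probe(f"p{i}", binding_pos=100 + i) for i in range(4)]
    sample_ids = [s.sample_id for s in cohort]
    betas = matrix_from_array(
        rng.uniform(0.3, 0.7, (4, 84)),
        probe_ids=[p.probe_id for p in manifest],
        sample_ids=sample_ids,
    )
    r1, _ = run_dmp(betas, None, manifest, cohort, region)
    r2, _ = run_dmp(betas, None, manifest, cohort, region)
    pd.testing.assert_frame_equal(r1, r2)


def test_association_config_validates_alpha():
    with pytest.raises(ValueError):
        AssociationConfig(alpha_family=1.5)


def test_null_pvalues_uniform_small():
    """No planted effects: nominal rejection near 5% (scaled-down check)."""
    cohort = make_cohort()
    sample_ids = [s.sample_id for s in cohort]
    rng = np.random.default_rng(42)
    vals = rng.beta(0.5 * 250, 0.5 * 250, size=(800, 84))
    betas = matrix_from_array(vals, sample_ids=sample_ids)
    res = dmp_ttest(betas, cohort)
    rate = (res["p_ttest"] < 0.05).mean()
    assert 0.02 <= rate <= 0.08
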