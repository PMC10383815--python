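"""Monte-Carlo failure-probability maps against closed-form normal tails."""

import numpy as np
import pytest
from scipy import stats

from dtsq import datasets
from dtsq.design_space import (
    MCSettings,
    MODRBox,
    OPERATING_POINT,
    VERIFICATION_POINTS,
    DesignSpaceError,
    SpecLimits,
    extract_design_space,
    failure_probability_map,
    verify_points,
)
from dtsq.modeling import FittedModel, parse_term


def toy_model(response, coefficients, cov_scale=0.0, resid_var=0.0):
    names = ["NS", "TD", "Tl"]
    terms = [parse_term(t, names) for t in ["b0", "NS", "Tl"]]
    p = len(terms)
    return FittedModel(
        response=response, terms=terms, factor_names=names,
        coefficients=np.asarray(coefficients, dtype=float),
        cov=np.eye(p) * cov_scale, resid_var=resid_var, df_resid=10,
        r2=1.0, r2_adj=1.0, conf_int=np.zeros((p, 2)),
        column_sd=np.ones(p), factor_sd=np.ones(3),
    )


def toy_models(acc=0.5, snr=2000.0, tq=10.0, **kw):
    return {
        "accuracy": toy_model("accuracy", [acc, 0, 0], **kw),
        "snr": toy_model("snr", [snr, 0, 0], **kw),
        "tq": toy_model("tq", [tq, 0, 0], **kw),
    }


SMOKE = MCSettings(grid_resolution=4, n_sim=2000, seed=11)


def test_zero_variance_models_inside_limits_never_fail(ccd):
    grid = failure_probability_map(toy_models(), SpecLimits(), SMOKE, ccd.factors)
    assert np.all(grid.combined == 0)
    for arr in grid.per_response.values():
        assert np.all(arr == 0)


def test_mean_sitting_on_the_limit_fails_half_the_time(ccd):
    models = toy_models(acc=3.0, resid_var=0.04)
    grid = failure_probability_map(models, SpecLimits(), SMOKE, ccd.factors,
                                   td_values=(65536,))
    se = np.sqrt(0.5 * 0.5 / SMOKE.n_sim)
    assert grid.per_response["accuracy"] == pytest.approx(0.5, abs=4 * se)


def test_mc_probability_matches_analytic_normal_tail(ccd):
    """Coefficient + residual draws reproduce Phi((limit - mean)/sd)."""
    models = toy_models(acc=2.5, cov_scale=0.01, resid_var=0.04)
    mc = MCSettings(grid_resolution=2, n_sim=10_000, seed=5)
    grid = failure_probability_map(models, SpecLimits(), mc, ccd.factors,
                                   td_values=(65536,))
    m = models["accuracy"]
    for i, tl in enumerate(grid.tl_axis):
        for j, ns in enumerate(grid.ns_axis):
            from dtsq.doe import code

            x = np.array([1.0, code(float(ns), ccd.factors[0]),
                          code(float(tl), ccd.factors[2])])
            sd = np.sqrt(x @ m.cov @ x + m.resid_var)
            p_exact = stats.norm.sf((3.0 - x @ m.coefficients) / sd)
            se = max(np.sqrt(p_exact * (1 - p_exact) / mc.n_sim), 1e-4)
            assert grid.per_response["accuracy"][0, i, j] == pytest.approx(
                p_exact, abs=3 * se)


def test_combined_probability_dominates_each_response(rsm_models, ccd):
    grid = failure_probability_map(rsm_models, SpecLimits(), SMOKE, ccd.factors,
                                   td_values=(65536,))
    for arr in grid.per_response.values():
        assert np.all(grid.combined >= arr - 1e-12)


def test_tightening_a_limit_never_lowers_failure_probability(rsm_models, ccd):
    loose = failure_probability_map(rsm_models, SpecLimits(), SMOKE, ccd.factors)
    tight = failure_probability_map(
        rsm_models, SpecLimits(accuracy_max=1.5, snr_min=1400, time_max=20),
        SMOKE, ccd.factors)
    assert np.all(tight.combined >= loose.combined - 1e-12)


def test_same_seed_reproduces_grid_bit_for_bit(rsm_models, ccd):
    a = failure_probability_map(rsm_models, SpecLimits(), SMOKE, ccd.factors)
    b = failure_probability_map(rsm_models, SpecLimits(), SMOKE, ccd.factors)
    assert np.array_equal(a.combined, b.combined)


def test_independent_seeds_agree_within_mc_error(rsm_models, ccd):
    mc2 = MCSettings(grid_resolution=4, n_sim=2000, seed=99)
    a = failure_probability_map(rsm_models, SpecLimits(), SMOKE, ccd.factors,
                                td_values=(65536,))
    b = failure_probability_map(rsm_models, SpecLimits(), mc2, ccd.factors,
                                td_values=(65536,))
    p = (a.combined + b.combined) / 2
    se = np.sqrt(np.maximum(p * (1 - p), 1e-5) * 2 / 2000)
    assert np.all(np.abs(a.combined - b.combined) <= 4 * se)


def test_mc_standard_error_shrinks_as_root_n(ccd):
    """Empirical spread of the failure estimate falls ~sqrt(100) when n_sim
    rises from 100 to 10,000."""
    models = toy_models(acc=2.8, resid_var=0.04)

    def spread(n_sim, reps=20):
        est = []
        for s in range(reps):
            mc = MCSettings(grid_resolution=2, n_sim=n_sim, seed=1000 + s)
            g = failure_probability_map(models, SpecLimits(), mc, ccd.factors,
                                        td_values=(65536,))
            est.append(g.per_response["accuracy"][0, 0, 0])
        return np.std(est, ddof=1)

    ratio = spread(100) / spread(10_000)
    assert 4 < ratio < 25


def test_extreme_thresholds_select_everything_or_zero_failures(rsm_models, ccd):
    grid = failure_probability_map(rsm_models, SpecLimits(), SMOKE, ccd.factors)
    all_mask, _ = extract_design_space(grid, threshold=1.0)
    assert all_mask.all()
    zero_mask, _ = extract_design_space(grid, threshold=0.0)
    assert np.array_equal(zero_mask, grid.combined == 0)


def test_modr_box_lies_inside_the_one_percent_design_space(rsm_models, ccd):
    mc = MCSettings(grid_resolution=21, n_sim=4000, seed=7)
    grid = failure_probability_map(rsm_models, SpecLimits(), mc, ccd.factors,
                                   td_values=(65536, 98304))
    mask, contours = extract_design_space(grid, threshold=0.01)
    box = MODRBox()
    for it in range(len(grid.td_values)):
        for ns in box.ns_values:
            for tl in box.tl_range:
                i = int(np.argmin(np.abs(grid.tl_axis - tl)))
                j = int(np.argmin(np.abs(grid.ns_axis - ns)))
                assert mask[it, i, j]
    assert isinstance(contours, dict)


def test_published_verification_points_pass_mean_model_limits(rsm_models, ccd):
    pts = list(VERIFICATION_POINTS) + [OPERATING_POINT]
    report = verify_points(rsm_models, SpecLimits(), pts, ccd.factors)
    assert report["pass_all"].all()
    assert (report["pred_accuracy"] <= 3).all()
    assert (report["pred_snr"] >= 1000).all()
    assert (report["pred_tq"] <= 25).all()


def test_out_of_region_point_flagged_for_time(rsm_models, ccd):
    # NS 96 with a ~33.4 s time lag: far past the 25-minute budget
    from dtsq.doe import acquisition_time

    d1 = 33.4 - acquisition_time(65536, 12.016, 500.13)
    report = verify_points(rsm_models, SpecLimits(), [(96, 65536, d1)], ccd.factors)
    assert not report.loc[0, "pass_tq"]
    assert not report.loc[0, "pass_all"]


def test_missing_covariance_instructs_refit(ccd):
    broken = toy_models()
    broken["snr"].cov = None
    with pytest.raises(DesignSpaceError, match="refit"):
        failure_probability_map(broken, SpecLimits(), SMOKE, ccd.factors)


@pytest.mark.parametrize("bad", [dict(grid_resolution=1), dict(n_sim=10),
                                 dict(failure_threshold=0.0)])
def test_invalid_mc_settings_rejected(bad):
    with pytest.raises(DesignSpaceError):
        MCSettings(**bad)


def test_grid_long_format_export_has_one_row_per_point(rsm_models, ccd):
    grid = failure_probability_map(rsm_models, SpecLimits(), SMOKE, ccd.factors,
                                   td_values=(65536,))
    df = grid.to_frame()
    assert len(df) == 16
    assert {"TD", "Tl", "NS", "combined", "p_fail_snr"} <= set(df.columns)
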