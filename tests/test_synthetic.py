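"""Generator contracts: determinism, noise scale, effect injection."""

import numpy as np
import pandas as pd
import pytest

import respfanova as rf
from respfanova.errors import ConfigError

from conftest import make_single_var_config


def test_fixed_seed_is_bit_identical(single_var_config):
    cfg = single_var_config(seed=1, grid_step_s=20.0)
    a = rf.generate_dataset(cfg)
    b = rf.generate_dataset(cfg)
    pd.testing.assert_frame_equal(a.to_long(), b.to_long())
    c = rf.generate_dataset(single_var_config(seed=2, grid_step_s=20.0))
    assert not np.array_equal(
        a.series[("S01", "FB", "Tin")], c.series[("S01", "FB", "Tin")]
    )


def test_zero_effect_vanishing_noise_limit(single_var_config):
    cfg = single_var_config(
        effect=rf.EffectCurve("zero"), sigma=1e-12, grid_step_s=20.0
    )
    ds = rf.generate_dataset(cfg)
    diff = ds.values_matrix("Tin", "FB") - ds.values_matrix("Tin", "ONB")
    assert np.abs(diff).max() < 1e-10


def test_mean_condition_difference_matches_planted_effect(single_var_config):
    # CLT bound: pooled mean of FB-ONB over 18 x 121 cells, noise SD 0.2 per
    # condition, lies within 3 * (0.2*sqrt(2)) / sqrt(18*121) of the true 0.4
    cfg = single_var_config(
        effect=rf.EffectCurve("constant", 0.4), sigma=0.2, seed=7
    )
    ds = rf.generate_dataset(cfg)
    diff = ds.values_matrix("Tin", "FB") - ds.values_matrix("Tin", "ONB")
    assert diff.shape == (18, 121)
    bound = 3.0 * (0.2 * np.sqrt(2.0)) / np.sqrt(18 * 121)
    assert abs(diff.mean() - 0.4) < bound


def test_ground_truth_curves(single_var_config):
    const = single_var_config(effect=rf.EffectCurve("constant", 0.3))
    gt = rf.ground_truth(const)["Tin"]
    assert np.allclose(gt["delta"], 0.3)
    assert gt["mu"].shape == gt["delta"].shape == const.grid.shape

    bump = single_var_config(effect=rf.EffectCurve("bump", 1.0, width_s=90.0))
    gtb = rf.ground_truth(bump)["Tin"]
    assert np.isclose(gtb["delta"].max(), 1.0)


def test_residual_sd_converges_to_sigma(single_var_config):
    cfg = single_var_config(sigma=0.5, n_subjects=200, grid_step_s=20.0, seed=3)
    ds = rf.generate_dataset(cfg)
    gt = rf.ground_truth(cfg)["Tin"]
    resid = np.concatenate(
        [
            (ds.values_matrix("Tin", "ONB") - gt["mu"]).ravel(),
            (ds.values_matrix("Tin", "FB") - gt["mu"] - gt["delta"]).ravel(),
        ]
    )
    assert abs(resid.std(ddof=1) - 0.5) / 0.5 < 0.05


@pytest.mark.parametrize("sigma_subject,expect_corr", [(0.0, False), (0.5, True)])
def test_subject_intercept_induces_cross_condition_correlation(
    single_var_config, sigma_subject, expect_corr
):
    cfg = single_var_config(
        sigma=0.5,
        n_subjects=200,
        grid_step_s=20.0,
        sigma_subject=sigma_subject,
        seed=5,
        effect=rf.EffectCurve("zero"),
    )
    ds = rf.generate_dataset(cfg)
    gt = rf.ground_truth(cfg)["Tin"]
    onb = (ds.values_matrix("Tin", "ONB") - gt["mu"]).mean(axis=1)
    fb = (ds.values_matrix("Tin", "FB") - gt["mu"]).mean(axis=1)
    r = np.corrcoef(onb, fb)[0, 1]
    if expect_corr:
        assert r > 0.5
    else:
        assert abs(r) < 0.1


def test_log_variable_round_trip_through_transform(single_var_config):
    cfg = rf.SimConfig(
        variables=[rf.VARIABLES["VO2"]],
        mean_curves={"VO2": rf.MeanCurve(baseline=7.0, amplitude=0.1)},
        effect_curves={"VO2": rf.EffectCurve("constant", 0.02)},
        sigma_noise={"VO2": 0.05},
        n_subjects=5,
        grid_step_s=60.0,
        seed=2,
    )
    ds = rf.generate_dataset(cfg)
    assert all(np.all(v > 0) for v in ds.series.values())
    logged = rf.apply_transforms(ds, {"VO2": rf.VARIABLES["VO2"]})
    gt = rf.ground_truth(cfg)["VO2"]
    # log scale residuals are exactly the generated Gaussian noise
    resid = logged.values_matrix("VO2", "ONB") - gt["mu"]
    assert abs(resid.std(ddof=1) - 0.05) / 0.05 < 0.35


def test_invalid_configs_rejected(single_var_config):
    with pytest.raises(ConfigError):
        make_single_var_config(grid_step_s=-5.0)
    with pytest.raises(ConfigError):
        make_single_var_config(sigma=0.0)
    with pytest.raises(ConfigError):
        # fewer than 5 grid points
        make_single_var_config(grid_end_s=120.0, grid_step_s=30.0)


def test_default_config_covers_all_trial_variables():
    cfg = rf.default_config(seed=0)
    assert len(cfg.variables) == 19
    assert cfg.n_subjects == 18
    assert cfg.grid.size == 121
    ds = rf.generate_dataset(cfg)
    assert len(ds.subjects) == 18
    assert set(ds.variables) == {v.name for v in cfg.variables}
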