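"""Isotherm behaviour, Kd fitting, and bootstrap uncertainty."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciliascreen import (
    DoseResponse,
    SimulationConfig,
    binding_isotherm,
    bootstrap_ci,
    compare_kd,
    compute_fnorm,
    fit_kd,
    gen_mst_experiment,
)
from ciliascreen.binding import attach_ci


def make_dose_response(L, y, T=100e-9):
    return DoseResponse(pd.DataFrame({"conc_M": L, "fnorm": y}),
                        target_conc=T)


# ---------------------------------------------------------------------------
# Fnorm from raw traces


def test_fnorm_flat_trace_is_unity():
    t = np.linspace(0, 30, 301)
    f = np.full_like(t, 500.0)
    assert compute_fnorm(t, f, (0, 5), (20, 25)) == pytest.approx(1.0)
    assert compute_fnorm(t, f, (0, 5), (20, 25), permille=True) == \
        pytest.approx(1000.0)


def test_fnorm_two_phase_trace_recovers_depletion():
    t = np.linspace(0, 30, 3001)
    f = np.where(t < 10, 800.0, 800.0 * 0.9)
    assert compute_fnorm(t, f, (0, 5), (20, 25)) == pytest.approx(0.9, abs=1e-9)


def test_fnorm_window_validation():
    t = np.linspace(0, 30, 301)
    f = np.ones_like(t)
    with pytest.raises(ValueError, match="precede"):
        compute_fnorm(t, f, (10, 20), (5, 8))
    with pytest.raises(ValueError, match="outside"):
        compute_fnorm(t, f, (0, 5), (20, 40))
    with pytest.raises(ValueError, match="degenerate"):
        compute_fnorm(t, np.zeros_like(t), (0, 5), (20, 25))


# ---------------------------------------------------------------------------
# the 1:1 ligand-depletion isotherm


def test_isotherm_zero_ligand_gives_baseline():
    assert binding_isotherm(0.0, 100e-9, 1e-6, baseline=7.5) == 7.5


def test_isotherm_saturates_to_baseline_plus_amplitude():
    v = binding_isotherm(1.0, 100e-9, 1e-6, baseline=2.0, amplitude=3.0)
    assert v == pytest.approx(5.0, rel=1e-4)


@settings(max_examples=30, deadline=None)
@given(kd=st.floats(1e-9, 1e-3), T=st.floats(1e-9, 1e-5))
def test_isotherm_bounded_and_monotone(kd, T):
    L = np.logspace(-10, 0, 200)
    fb = binding_isotherm(L, T, kd)
    assert np.all(fb >= 0) and np.all(fb <= 1.0 + 1e-12)
    assert np.all(np.diff(fb) >= -1e-12)


def test_isotherm_no_depletion_limit():
    """When T << Kd the quadratic reduces to L/(L+Kd): half-saturation
    at L = Kd."""
    kd, T = 1e-5, 1e-9                       # T/Kd = 1e-4
    fb = binding_isotherm(kd, T, kd)
    assert fb == pytest.approx(0.5, abs=1e-3)
    hyper = binding_isotherm(kd, T, kd, depletion=False)
    assert hyper == pytest.approx(0.5, rel=1e-12)


def test_depletion_matters_when_target_comparable():
    """At T ~ Kd the quadratic predicts less free-ligand binding than the
    hyperbola."""
    kd = 100e-9
    fb_q = binding_isotherm(kd, 100e-9, kd)
    fb_h = binding_isotherm(kd, 100e-9, kd, depletion=False)
    assert fb_q < fb_h


# ---------------------------------------------------------------------------
# fitting


def test_noiseless_fit_recovers_generating_parameters():
    cfg = SimulationConfig(seed=0, noise_sd=0.0, kd_true=1e-6)
    fit = fit_kd(gen_mst_experiment(cfg))
    assert fit.converged
    assert fit.kd == pytest.approx(1e-6, rel=1e-6)
    assert fit.baseline == pytest.approx(cfg.fnorm_baseline, rel=1e-6)
    assert fit.amplitude == pytest.approx(cfg.fnorm_amplitude, rel=1e-4)


def test_fit_scale_equivariance():
    cfg = SimulationConfig(seed=4, noise_sd=0.0, kd_true=5e-6)
    dr = gen_mst_experiment(cfg)
    c = 1e3
    scaled = DoseResponse(dr.frame.assign(conc_M=dr.conc * c),
                          target_conc=dr.target_conc * c)
    assert fit_kd(scaled).kd == pytest.approx(c * fit_kd(dr).kd, rel=1e-4)


def test_fit_recovery_under_noise():
    """WT-like design: median recovered Kd over 20 seeds within 10%."""
    vals = []
    for s in range(20):
        fit = fit_kd(gen_mst_experiment(SimulationConfig(seed=s)))
        assert fit.converged
        vals.append(fit.kd)
    assert np.median(vals) == pytest.approx(10.2e-6, rel=0.10)


def test_unconstrained_kd_not_reported():
    """A Kd far above the titration top cannot be pinned and must be
    refused rather than reported."""
    cfg = SimulationConfig(seed=1, noise_sd=0.0, kd_true=5e-3)  # 45x the top
    fit = fit_kd(gen_mst_experiment(cfg))
    assert not fit.converged
    assert np.isnan(fit.kd)
    assert "not reported" in fit.message


def test_fit_input_validation():
    with pytest.raises(ValueError, match="4 distinct"):
        fit_kd(make_dose_response([1e-6, 2e-6, 4e-6], [1, 2, 3]))
    L = [1e-6, 2e-6, 4e-6, 8e-6]
    with pytest.raises(ValueError, match="2 orders"):
        fit_kd(make_dose_response(L, [1, 2, 3, 4]))


# ---------------------------------------------------------------------------
# bootstrap and comparison


def test_bootstrap_deterministic_and_tight_when_noiseless():
    cfg = SimulationConfig(seed=2, noise_sd=0.0)
    dr = gen_mst_experiment(cfg)
    fit = fit_kd(dr)
    a = bootstrap_ci(dr, fit, n_boot=50, seed=3)
    b = bootstrap_ci(dr, fit, n_boot=50, seed=3)
    assert a["kd_ci95"] == b["kd_ci95"]
    lo, hi = a["kd_ci95"]
    assert hi / lo == pytest.approx(1.0, rel=1e-5)
    assert lo <= fit.kd <= hi


def test_bootstrap_requires_converged_fit_and_spread():
    cfg = SimulationConfig(seed=2)
    dr = gen_mst_experiment(cfg)
    fit = fit_kd(dr)
    bad = make_dose_response([1e-6] * 6, np.arange(6.0))
    with pytest.raises(ValueError, match="one concentration"):
        bootstrap_ci(bad, fit, n_boot=10, seed=0)


def test_compare_kd_identity_and_ratio():
    cfg = SimulationConfig(seed=5, noise_sd=0.0)
    fit = fit_kd(gen_mst_experiment(cfg))
    assert compare_kd(fit, fit)["ratio"] == pytest.approx(1.0)
    fit5 = fit_kd(gen_mst_experiment(cfg.replace(kd_true=51e-6)))
    assert compare_kd(fit, fit5)["ratio"] == pytest.approx(5.0, rel=1e-3)


def test_compare_kd_rejects_unconverged():
    cfg = SimulationConfig(seed=5, noise_sd=0.0)
    good = fit_kd(gen_mst_experiment(cfg))
    bad = fit_kd(gen_mst_experiment(cfg.replace(kd_true=5e-3)))
    with pytest.raises(ValueError, match="converged"):
        compare_kd(good, bad)


def test_compare_kd_bootstrap_interval_covers_true_ratio():
    cfg = SimulationConfig(seed=6)
    dr_a = gen_mst_experiment(cfg)
    dr_b = gen_mst_experiment(cfg.replace(seed=7, kd_true=51e-6))
    fit_a, fit_b = fit_kd(dr_a), fit_kd(dr_b)
    boot_a = bootstrap_ci(dr_a, fit_a, n_boot=100, seed=1)
    boot_b = bootstrap_ci(dr_b, fit_b, n_boot=100, seed=2)
    out = compare_kd(fit_a, fit_b, boot_a["samples"], boot_b["samples"])
    lo, hi = out["ratio_ci95"]
    assert lo < 5.0 < hi
    fit_a2 = attach_ci(fit_a, boot_a)
    assert fit_a2.kd_ci[0] <= fit_a.kd <= fit_a2.kd_ci[1]
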