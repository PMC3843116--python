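"""Per-site prediction, statistics, sensitivity Monte Carlo and the pipeline."""

import json

import numpy as np
import pytest

from lamellae.analysis import (
    CorrelationTable,
    ModulusInterpolator,
    SensitivityConfig,
    compare_distributions,
    compare_groups,
    pearson_r2,
    predict_sites,
    run_pipeline,
    sensitivity_mc,
)
from lamellae.errors import DegenerateGroupError, UndefinedCorrelationError
from lamellae.homogenization import FibrilArrayParams, fibril_array_stiffness
from lamellae.indentation import direction_from_theta, indentation_modulus
from lamellae.sitematch import IndentSite, RigidTransform
from lamellae.synthetic import CohortConfig


# ------------------------------------------------------------- interpolator
def test_interpolator_accuracy(modulus_interp, rng):
    """Grid interpolation within 0.01 GPa of the exact model chain."""
    for _ in range(6):
        phi = rng.uniform(0.30, 0.45)
        theta = rng.uniform(0.0, 75.0)
        exact = indentation_modulus(
            fibril_array_stiffness(FibrilArrayParams(phi_mineral=phi)),
            direction_from_theta(theta),
            (96, 48),
        )
        assert modulus_interp(phi, theta) == pytest.approx(exact, abs=0.01)


def test_interpolator_vectorized(modulus_interp):
    phis = np.array([0.36, 0.38, 0.40])
    thetas = np.array([0.0, 30.0, 60.0])
    out = modulus_interp(phis, thetas)
    assert out.shape == (3,)
    assert out[0] == pytest.approx(modulus_interp(0.36, 0.0), rel=1e-12)


def test_interpolator_bounds_error(modulus_interp):
    with pytest.raises(ValueError):
        modulus_interp(0.05, 30.0)


# ----------------------------------------------------------------- predict
def test_predict_sites_axial_identity():
    """theta=0 sites: oriented and axial prediction coincide."""
    sites = [IndentSite(id=0, x=0, y=0, phi_avg=0.38, theta_avg=0.0)]
    out, n_bad = predict_sites(sites)
    assert n_bad == 0
    assert out[0].E_pred == pytest.approx(out[0].E_pred0, rel=1e-9)
    C = fibril_array_stiffness(FibrilArrayParams())
    assert out[0].E_pred0 == pytest.approx(
        indentation_modulus(C, direction_from_theta(0.0), (48, 24)), rel=1e-9
    )


def test_predict_sites_orientation_softens():
    sites = [
        IndentSite(id=i, x=0, y=0, phi_avg=0.38, theta_avg=t)
        for i, t in enumerate([10.0, 32.3, 60.0])
    ]
    out, _ = predict_sites(sites)
    for s in out:
        assert s.E_pred < s.E_pred0


def test_predict_sites_skips_missing_and_flags_infeasible():
    sites = [
        IndentSite(id=0, x=0, y=0),  # no covariates
        IndentSite(id=1, x=0, y=0, phi_avg=0.38, theta_avg=20.0),
        # q*phi > f_fibril under these params is impossible with defaults;
        # an all-void foam (phi=0) is the reachable infeasible case
        IndentSite(id=2, x=0, y=0, phi_avg=0.0, theta_avg=20.0),
    ]
    out, n_bad = predict_sites(sites)
    assert n_bad == 1
    assert out[0].E_pred is None
    assert out[1].E_pred is not None
    assert out[2].quality == "infeasible_model"


# -------------------------------------------------------------- statistics
def test_pearson_r2_oracles(rng):
    x = rng.uniform(size=200)
    assert pearson_r2(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)
    assert pearson_r2(x, -3 * x) == pytest.approx(1.0, abs=1e-12)
    y = rng.uniform(size=200)  # independent
    assert pearson_r2(x, y) < 0.05
    with pytest.raises(UndefinedCorrelationError):
        pearson_r2(x, np.full_like(x, 2.0))
    with pytest.raises(UndefinedCorrelationError):
        pearson_r2([1.0, 2.0], [1.0, 2.0])


def test_compare_groups_detects_shift(rng):
    a = rng.normal(20, 2, 50)
    b = rng.normal(30, 2, 50)  # 5 SD apart
    c = rng.normal(20.1, 2, 50)
    values = np.concatenate([a, b, c])
    labels = ["a"] * 50 + ["b"] * 50 + ["c"] * 50
    table = compare_groups(values, labels)
    assert set(table.columns) >= {"group1", "group2", "meandiff", "p-adj", "reject"}
    ab = table[(table.group1 == "a") & (table.group2 == "b")].iloc[0]
    ac = table[(table.group1 == "a") & (table.group2 == "c")].iloc[0]
    assert bool(ab["reject"]) and float(ab["p-adj"]) < 0.001
    assert not bool(ac["reject"])


def test_compare_groups_type_one_error_rate():
    """Under the null, Tukey HSD rejects ~alpha of the time."""
    rng = np.random.default_rng(123)
    n_rej = 0
    n_rep = 300
    labels = ["a"] * 25 + ["b"] * 25 + ["c"] * 25
    for _ in range(n_rep):
        values = rng.normal(size=75)
        table = compare_groups(values, labels)
        n_rej += int(table["reject"].any())
    # familywise alpha=0.05; binomial 3-sigma band around 0.05
    assert 0.01 <= n_rej / n_rep <= 0.10


def test_compare_groups_degenerate():
    with pytest.raises(DegenerateGroupError):
        compare_groups([1.0, 2.0], ["a", "a"])
    with pytest.raises(DegenerateGroupError):
        compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])


def test_compare_distributions(rng):
    a = rng.normal(24, 5, 400)
    b = rng.normal(24, 5, 400)
    res = compare_distributions(a, b)
    assert res["rank_p"] > 0.01 and res["t_p"] > 0.01
    res = compare_distributions(a, b + 3.0)
    assert res["rank_p"] < 1e-6 and res["t_p"] < 1e-6
    # paired, identical samples
    res = compare_distributions(a, a.copy(), paired=True)
    assert res["rank_p"] == 1.0 and res["t_p"] == 1.0


# -------------------------------------------------------------- sensitivity
def test_sensitivity_degenerate_ranges_constant():
    """Zero-width ranges at the defaults reproduce the single-point model."""
    cfg = SensitivityConfig(
        phi_fixed=0.34, q_range=(0.25, 0.25), f_fibril_range=(0.53, 0.53),
        theta_range=(0.0, 0.0), n_draws=8, seed=1,
    )
    res = sensitivity_mc(cfg)
    M = indentation_modulus(
        fibril_array_stiffness(FibrilArrayParams(phi_mineral=0.34)),
        direction_from_theta(0.0), (48, 24),
    )
    assert np.allclose(res.values, M, rtol=1e-9)
    assert res.E_min == pytest.approx(res.E_max)


def test_sensitivity_extremes_align_with_orientation():
    """Softest draws lie at high fibril angle, stiffest near the axis."""
    res = sensitivity_mc(SensitivityConfig(n_draws=400, seed=7))
    d = res.draws
    assert d.shape == (400, 4)
    assert d.loc[d.E_ind_GPa.idxmax(), "theta_deg"] < 45.0
    assert d.loc[d.E_ind_GPa.idxmin(), "theta_deg"] > 45.0
    assert res.E_min == d.E_ind_GPa.min()
    assert res.E_max == d.E_ind_GPa.max()
    assert res.n_rejected >= 0
    counts, edges = res.histogram(bins=10)
    assert counts.sum() == 400


def test_sensitivity_rejects_infeasible_draws():
    """A range crossing the q*phi > f_fibril boundary must reject draws."""
    cfg = SensitivityConfig(
        phi_fixed=0.5, q_range=(0.25, 0.75), f_fibril_range=(0.25, 0.30),
        theta_range=(0.0, 0.0), n_draws=50, seed=3,
    )
    res = sensitivity_mc(cfg)
    assert res.n_rejected > 0
    assert len(res.values) == 50
    # all retained draws are feasible: every modulus is finite and positive
    assert np.all(np.isfinite(res.values)) and np.all(res.values > 0)


def test_sensitivity_seeded_determinism():
    a = sensitivity_mc(SensitivityConfig(n_draws=64, seed=5))
    b = sensitivity_mc(SensitivityConfig(n_draws=64, seed=5))
    assert np.array_equal(a.values, b.values)
    assert a.n_rejected == b.n_rejected


# ------------------------------------------------------------------ pipeline
def small_cohort(**kw) -> CohortConfig:
    base = dict(n_patterns=4, seed=11)
    base.update(kw)
    return CohortConfig(**base)


def test_pipeline_summary_and_outputs(tmp_path):
    cfg = small_cohort()
    summary = run_pipeline(cfg, out_dir=tmp_path)
    n = cfg.n_sites
    assert summary["n_performed"] == n
    assert summary["n_retained"] == n - round(cfg.reject_fraction * n)
    assert abs(summary["recovered_transform"]["dx_um"] - 3.0) < 0.25
    assert abs(summary["recovered_transform"]["dy_um"] + 2.0) < 0.25
    assert summary["mean_E_pred_GPa"] < summary["mean_E_pred0_GPa"]
    assert summary["r2"]["E_pred_GPa"] > 0.1  # coupled mode with noise
    for name in ("sites.csv", "correlation_table.csv", "summary.json"):
        assert (tmp_path / name).exists()
    on_disk = json.loads((tmp_path / "summary.json").read_text())
    assert on_disk == summary


def test_pipeline_deterministic():
    cfg = small_cohort()
    a = run_pipeline(cfg)
    b = run_pipeline(cfg)
    assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)


def test_pipeline_noiseless_coupled_r2_is_one():
    cfg = small_cohort(
        E_noise_sd=0.0, measurement_basis="disk",
        misregistration=RigidTransform(0.0, 0.0, 0.0),
    )
    summary = run_pipeline(cfg)
    assert summary["r2"]["E_pred_GPa"] > 0.999


def test_pipeline_decoupled_r2_near_zero():
    summary = run_pipeline(small_cohort(decoupled=True))
    assert summary["r2"]["E_pred_GPa"] < 0.02
    assert summary["r2"]["phi"] < 0.02


def test_correlation_table_structure():
    rng = np.random.default_rng(2)
    sites = []
    for i in range(40):
        phi = rng.uniform(0.35, 0.41)
        th = rng.uniform(5, 60)
        sites.append(
            IndentSite(id=i, x=0, y=0, E_meas=rng.normal(24, 5), phi_avg=phi,
                       theta_avg=th)
        )
    sites, _ = predict_sites(sites)
    table = CorrelationTable.from_sites(sites)
    assert list(table.rows["variable"]) == [
        "phi", "theta_deg", "E_pred0_GPa", "E_pred_GPa", "E_meas_GPa"
    ]
    assert table.rows["r2_vs_E_meas"].iloc[:4].between(0, 1).all()
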