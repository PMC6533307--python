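"""CCC design construction, quadratic fitting, ANOVA, and surface optimization."""

import numpy as np
import pytest

from phenolprofiler import rsm
from phenolprofiler.errors import (
    IncompleteDesignError,
    InvalidFactorError,
    InvalidRegionError,
    SingularDesignError,
)
from phenolprofiler.rsm import (
    DEFAULT_FACTORS,
    FactorSpec,
    build_ccc_design,
    code_value,
    fit_quadratic,
    optimize_surface,
    predict,
    quadratic_design_matrix,
    uncode_value,
)
from phenolprofiler.synthgen import SurfaceSpec, gen_response_surface


@pytest.mark.parametrize(
    "k, alpha, n_center, expected_runs",
    [
        (3, 1.68, 6, 20),  # 8 factorial + 6 axial + 6 centre
        (2, 1.414, 0, 8),  # 4 factorial + 4 axial
        (3, 1.68, 1, 15),
    ],
)
def test_design_run_counts(k, alpha, n_center, expected_runs):
    factors = [FactorSpec(f"f{i}", 0.0, 1.0) for i in range(k)]
    design = build_ccc_design(factors, alpha=alpha, n_center=n_center)
    assert design.n_runs == expected_runs
    roles = [p.role for p in design.points]
    assert roles.count("factorial") == 2**k
    assert roles.count("axial") == 2 * k
    assert roles.count("center") == n_center


def test_design_matches_observed_run_order(extraction_design):
    """Constructed coded pattern equals the published 20-run layout."""
    built = build_ccc_design(DEFAULT_FACTORS, alpha=1.68, n_center=6)
    assert np.allclose(built.coded_matrix(), extraction_design.coded_matrix())
    assert [p.role for p in built.points] == [p.role for p in extraction_design.points]


def test_design_balance_and_factorial_orthogonality():
    design = build_ccc_design(DEFAULT_FACTORS)
    coded = design.coded_matrix()
    assert np.allclose(coded.sum(axis=0), 0.0)
    factorial = coded[:8]
    gram = factorial.T @ factorial
    assert np.allclose(gram, np.diag(np.diag(gram)))


def test_axial_uncoded_values():
    """Axial time at +1.68 lands at 46.8 min (displayed as 47)."""
    design = build_ccc_design(DEFAULT_FACTORS, alpha=1.68)
    time_axial = [p for p in design.points if p.role == "axial" and p.coded[0] > 0]
    assert time_axial[0].uncoded == pytest.approx((46.8, 20.0, 50.0))


def test_invalid_design_parameters():
    with pytest.raises(InvalidFactorError):
        build_ccc_design(DEFAULT_FACTORS, alpha=0.5)
    with pytest.raises(InvalidFactorError):
        FactorSpec("bad", 10.0, 0.0)


@pytest.mark.parametrize(
    "uncoded, expected",
    [(30.0, 0.0), (20.0, -1.0), (46.8, 1.68)],
)
def test_code_value_time_axis(uncoded, expected):
    f = DEFAULT_FACTORS[0]
    assert code_value(uncoded, f) == pytest.approx(expected)


def test_code_uncode_round_trip():
    f = FactorSpec("t", 30.0, 10.0)
    assert code_value(uncode_value(0.7, f), f) == pytest.approx(0.7, abs=1e-14)


def test_fit_reproduces_reported_r_squared(fitted_surface):
    """The full quadratic on the 20 observed runs explains ~92% of variance."""
    assert fitted_surface.r_squared == pytest.approx(0.9211, abs=0.005)
    assert fitted_surface.p_value < 0.001
    assert fitted_surface.df_model == 9
    assert fitted_surface.df_residual == 10


def test_exact_recovery_of_known_coefficients():
    """Noise-free responses from any coefficient vector are interpolated exactly."""
    rng = np.random.default_rng(7)
    truth = rng.normal(size=10)
    design = build_ccc_design(DEFAULT_FACTORS)
    design = gen_response_surface(SurfaceSpec(tuple(truth)), design)
    model = fit_quadratic(design)
    assert np.allclose(model.coefficients, truth, atol=1e-8)
    assert model.r_squared == pytest.approx(1.0, abs=1e-10)


def test_monte_carlo_coefficient_estimates_unbiased():
    """With response noise sd 0.05, mean estimates stay within 3 SE of truth."""
    truth = np.array([1.1, 0.05, 0.15, 0.07, 0.02, -0.07, -0.05, -0.07, 0.0, 0.01])
    design = build_ccc_design(DEFAULT_FACTORS)
    n_rep, sd = 200, 0.05
    estimates = np.empty((n_rep, 10))
    for r in range(n_rep):
        d = gen_response_surface(SurfaceSpec(tuple(truth), noise_sd=sd, seed=1000 + r), design)
        estimates[r] = fit_quadratic(d).coefficients
    X = quadratic_design_matrix(design.coded_matrix())
    cov = sd**2 * np.linalg.inv(X.T @ X)
    se_mean = np.sqrt(np.diag(cov) / n_rep)
    assert np.all(np.abs(estimates.mean(axis=0) - truth) < 3 * se_mean)


def test_fit_requires_responses_and_full_rank():
    design = build_ccc_design(DEFAULT_FACTORS)
    with pytest.raises(IncompleteDesignError):
        fit_quadratic(design)
    # collapse every run onto the centre -> rank-deficient basis
    degenerate = design.with_responses(np.ones(design.n_runs))
    flat_points = tuple(
        rsm.DesignPoint(coded=(0.0, 0.0, 0.0), uncoded=p.uncoded, role="center", response=1.0)
        for p in degenerate.points
    )
    degenerate = rsm.CCCDesign(degenerate.factors, degenerate.alpha, flat_points)
    with pytest.raises(SingularDesignError):
        fit_quadratic(degenerate)


def test_anova_decomposition(extraction_design, fitted_surface):
    tab = rsm.anova_table(fitted_surface, extraction_design)
    assert tab.loc["pure_error", "df"] == 5  # six centre replicates
    assert tab.loc["model", "p"] < 0.001
    total = tab.loc["model", "ss"] + tab.loc["residual", "ss"]
    assert total == pytest.approx(tab.loc["total", "ss"], rel=1e-12)
    lof = tab.loc["residual", "ss"] - tab.loc["pure_error", "ss"]
    assert tab.loc["lack_of_fit", "ss"] == pytest.approx(lof, rel=1e-12)


def test_anova_zero_noise_residual():
    design = build_ccc_design(DEFAULT_FACTORS)
    design = gen_response_surface(SurfaceSpec((1.0,) + (0.2,) * 9), design)
    model = fit_quadratic(design)
    tab = rsm.anova_table(model, design)
    assert tab.loc["residual", "ss"] == pytest.approx(0.0, abs=1e-16)


def test_anova_without_center_replicates_flags_lack_of_fit():
    design = build_ccc_design(DEFAULT_FACTORS, n_center=1)
    design = gen_response_surface(
        SurfaceSpec((1.0,) + (0.1,) * 9, noise_sd=0.05, seed=3), design
    )
    model = fit_quadratic(design)
    tab = rsm.anova_table(model, design)
    assert np.isnan(tab.loc["lack_of_fit", "ss"])


def test_predict_trivial_models():
    zero = rsm.QuadraticSurfaceModel(0.0, (0.0,) * 3, (0.0,) * 3, (0.0,) * 3, 1, 0, 0, 9, 0)
    assert predict(zero, (0.3, -0.8, 1.2)) == 0.0
    const = rsm.QuadraticSurfaceModel(2.5, (0.0,) * 3, (0.0,) * 3, (0.0,) * 3, 1, 0, 0, 9, 0)
    assert predict(const, (1.0, 1.0, -1.0)) == 2.5


def test_optimum_reproduces_reported_condition(extraction_design, fitted_surface):
    """Maximizing over the factorial cube recovers 20 min, 1:30 g/mL, ~57 degC."""
    opt = optimize_surface(fitted_surface, factors=extraction_design.factors)
    t_min, ratio, temp = opt.uncoded_opt
    assert t_min == pytest.approx(20.0, abs=0.2)
    assert ratio == pytest.approx(30.0, abs=0.2)
    assert temp == pytest.approx(57.0, abs=1.0)
    assert opt.predicted_response == pytest.approx(1.29, abs=0.01)
    assert opt.predicted_response == pytest.approx(
        predict(fitted_surface, opt.coded_opt), rel=1e-9
    )


def test_concave_bowl_optimum_at_origin():
    model = rsm.QuadraticSurfaceModel(
        0.0, (0.0,) * 3, (-1.0, -1.0, -1.0), (0.0,) * 3, 1.0, 0.0, 0.0, 9, 0
    )
    opt = optimize_surface(model)
    assert np.allclose(opt.coded_opt, 0.0, atol=1e-8)
    assert opt.predicted_response == pytest.approx(0.0, abs=1e-12)


def test_optimizer_dominates_grid_oracle():
    """Optimizer value >= brute-force 0.05-grid maximum for seeded random models."""
    rng = np.random.default_rng(42)
    axis = np.arange(-1.0, 1.0 + 1e-9, 0.05)
    mesh = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    X = quadratic_design_matrix(pts)
    for _ in range(50):
        beta = rng.normal(size=10)
        model = rsm.QuadraticSurfaceModel(
            beta[0], tuple(beta[1:4]), tuple(beta[4:7]), tuple(beta[7:10]),
            1.0, 0.0, 0.0, 9, 0,
        )
        oracle = float((X @ beta).max())
        opt = optimize_surface(model, grid_resolution=0.02)
        assert opt.predicted_response >= oracle - 1e-9


def test_scale_equivariance(extraction_design, fitted_surface):
    """Scaling responses by c scales coefficients and optimum value, not R^2."""
    c = 3.7
    scaled = extraction_design.with_responses(c * extraction_design.responses())
    scaled_model = fit_quadratic(scaled)
    assert np.allclose(scaled_model.coefficients, c * fitted_surface.coefficients)
    assert scaled_model.r_squared == pytest.approx(fitted_surface.r_squared, rel=1e-9)
    opt = optimize_surface(fitted_surface, factors=extraction_design.factors)
    opt_scaled = optimize_surface(scaled_model, factors=extraction_design.factors)
    assert np.allclose(opt_scaled.coded_opt, opt.coded_opt, atol=1e-6)
    assert opt_scaled.predicted_response == pytest.approx(
        c * opt.predicted_response, rel=1e-6
    )


def test_unbounded_region_rejected(fitted_surface):
    with pytest.raises(InvalidRegionError):
        optimize_surface(fitted_surface, region=[(-np.inf, 1), (-1, 1), (-1, 1)])
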