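"""Central composite circumscribed (CCC) designs and second-order response surfaces.

The ultrasound-assisted extraction of total phenolics is modelled as a full
quadratic polynomial in three coded factors (extraction time, solid/liquid
ratio expressed as the liquid denominator D in "1:D g/mL", and temperature).
A CCC design combines a 2^3 factorial block at coded levels +/-1, axial
points at +/-alpha on each axis, and replicated centre points. The surface
is fitted by ordinary least squares on the coded factors and maximized over
a box in coded space by a dense grid scan refined with a bounded local
polish.

Coded and uncoded units are linked by ``x = center + step * z`` for each
factor, so the factorial levels +/-1 correspond to ``center +/- step``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize as _sciopt
from scipy import stats as _scistats

from .errors import (
    IncompleteDesignError,
    InvalidFactorError,
    InvalidRegionError,
    SingularDesignError,
)

__all__ = [
    "FactorSpec",
    "DesignPoint",
    "CCCDesign",
    "QuadraticSurfaceModel",
    "OptimizationResult",
    "build_ccc_design",
    "code_value",
    "uncode_value",
    "fit_quadratic",
    "anova_table",
    "predict",
    "optimize_surface",
    "quadratic_design_matrix",
    "DEFAULT_FACTORS",
]

#: Column order of the full quadratic basis in k=3 factors.
QUADRATIC_TERMS_3 = (
    "1", "x1", "x2", "x3", "x1^2", "x2^2", "x3^2", "x1*x2", "x1*x3", "x2*x3",
)


@dataclass(frozen=True)
class FactorSpec:
    """One extraction factor with its coded <-> uncoded mapping.

    ``center`` is the uncoded value at coded 0 and ``step`` the uncoded
    change per coded unit, so coded +/-1 are the factorial levels.
    """

    name: str
    center: float
    step: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise InvalidFactorError(f"factor {self.name!r}: center must be finite")
        if not (self.step > 0 and np.isfinite(self.step)):
            raise InvalidFactorError(f"factor {self.name!r}: step must be > 0")


def code_value(x: float, f: FactorSpec) -> float:
    """Map an uncoded factor value to coded units: (x - center) / step."""
    return (x - f.center) / f.step


def uncode_value(z: float, f: FactorSpec) -> float:
    """Map a coded value back to uncoded units: center + step * z."""
    return f.center + f.step * z


#: Factor layout of the flower-extraction experiment: time (min), the
#: solid/liquid denominator D of "1:D g/mL", and temperature (degC).
DEFAULT_FACTORS: tuple[FactorSpec, FactorSpec, FactorSpec] = (
    FactorSpec("time", center=30.0, step=10.0, unit="min"),
    FactorSpec("ratio", center=20.0, step=10.0, unit="mL-per-g"),
    FactorSpec("temperature", center=50.0, step=10.0, unit="degC"),
)


@dataclass(frozen=True)
class DesignPoint:
    """A single experimental run: coded levels, uncoded levels, optional response."""

    coded: tuple[float, ...]
    uncoded: tuple[float, ...]
    role: Literal["factorial", "axial", "center"]
    response: float | None = None


@dataclass(frozen=True)
class CCCDesign:
    """A circumscribed central composite design for k = len(factors) factors."""

    factors: tuple[FactorSpec, ...]
    alpha: float
    points: tuple[DesignPoint, ...]

    @property
    def n_runs(self) -> int:
        return len(self.points)

    @property
    def n_center(self) -> int:
        return sum(1 for p in self.points if p.role == "center")

    def responses(self) -> np.ndarray:
        if any(p.response is None for p in self.points):
            raise IncompleteDesignError("design has points without responses")
        return np.array([p.response for p in self.points], dtype=float)

    def coded_matrix(self) -> np.ndarray:
        return np.array([p.coded for p in self.points], dtype=float)

    def with_responses(self, responses: Sequence[float]) -> "CCCDesign":
        if len(responses) != self.n_runs:
            raise IncompleteDesignError(
                f"expected {self.n_runs} responses, got {len(responses)}"
            )
        pts = tuple(
            replace(p, response=float(r)) for p, r in zip(self.points, responses)
        )
        return replace(self, points=pts)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with run order, coded and uncoded levels, response."""
        k = len(self.factors)
        rows = []
        for i, p in enumerate(self.points, start=1):
            row: dict = {"run": i, "role": p.role}
            for j in range(k):
                row[f"x{j + 1}_coded"] = p.coded[j]
                row[f"x{j + 1}_uncoded"] = p.uncoded[j]
            row["response"] = np.nan if p.response is None else p.response
            rows.append(row)
        return pd.DataFrame(rows)


def build_ccc_design(
    factors: Sequence[FactorSpec],
    alpha: float = 1.68,
    n_center: int = 6,
) -> CCCDesign:
    """Construct a CCC design: 2^k factorial + 2k axial + n_center centre runs.

    Factorial runs enumerate the +/-1 corners with the first factor varying
    fastest; axial runs place -alpha then +alpha on each axis in factor
    order; centre runs come last. For k = 3, n_center = 6 this is the
    20-run layout of the extraction experiment.
    """
    factors = tuple(factors)
    k = len(factors)
    if k < 2:
        raise InvalidFactorError("a CCC design needs at least 2 factors")
    if not alpha > 1:
        raise InvalidFactorError("alpha must exceed 1 (axial outside the cube)")
    if n_center < 0:
        raise InvalidFactorError("n_center must be >= 0")

    points: list[DesignPoint] = []

    # 2^k factorial corners, first factor fastest (standard run-order layout).
    for levels in itertools.product((-1.0, 1.0), repeat=k):
        coded = tuple(reversed(levels))
        points.append(_make_point(coded, factors, "factorial"))
    # 2k axial points at +/-alpha, one axis at a time.
    for axis in range(k):
        for sign in (-1.0, 1.0):
            coded = tuple(sign * alpha if j == axis else 0.0 for j in range(k))
            points.append(_make_point(coded, factors, "axial"))
    # Replicated centre points.
    for _ in range(n_center):
        points.append(_make_point((0.0,) * k, factors, "center"))

    return CCCDesign(factors=factors, alpha=float(alpha), points=tuple(points))


def _make_point(
    coded: tuple[float, ...],
    factors: tuple[FactorSpec, ...],
    role: Literal["factorial", "axial", "center"],
) -> DesignPoint:
    uncoded = tuple(uncode_value(z, f) for z, f in zip(coded, factors))
    return DesignPoint(coded=coded, uncoded=uncoded, role=role)


def quadratic_design_matrix(coded: np.ndarray) -> np.ndarray:
    """Full second-order basis [1, x1..xk, x1^2..xk^2, all pairwise products]."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = coded.shape
    cols = [np.ones(n)]
    cols.extend(coded[:, j] for j in range(k))
    cols.extend(coded[:, j] ** 2 for j in range(k))
    for a in range(k):
        for b in range(a + 1, k):
            cols.append(coded[:, a] * coded[:, b])
    return np.column_stack(cols)


@dataclass(frozen=True)
class QuadraticSurfaceModel:
    """Fitted full quadratic surface on coded factors, with fit statistics."""

    intercept: float
    linear: tuple[float, ...]
    quadratic: tuple[float, ...]
    interaction: tuple[float, ...]  # pairs (1,2), (1,3), ..., (k-1,k)
    r_squared: float
    f_statistic: float
    p_value: float
    df_model: int
    df_residual: int

    @property
    def n_factors(self) -> int:
        return len(self.linear)

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficient vector in design-matrix column order."""
        return np.concatenate(
            ([self.intercept], self.linear, self.quadratic, self.interaction)
        )


def fit_quadratic(design: CCCDesign) -> QuadraticSurfaceModel:
    """Fit the full quadratic by OLS on the coded factors.

    Requires at least as many responded runs as coefficients (10 for three
    factors) and a full-rank design matrix.
    """
    y = design.responses()
    X = quadratic_design_matrix(design.coded_matrix())
    n, p = X.shape
    if n < p:
        raise IncompleteDesignError(
            f"need >= {p} responded runs for the full quadratic, got {n}"
        )
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError("design matrix is rank deficient")

    res = sm.OLS(y, X).fit()
    beta = np.asarray(res.params, dtype=float)
    sse = float(res.ssr)
    df_model = p - 1
    df_resid = n - p
    if df_resid > 0 and sse > 0:
        r2 = float(res.rsquared)
        f_stat = float(res.fvalue)
        p_val = float(res.f_pvalue)
    else:
        # exact interpolation: statsmodels' F is degenerate
        r2, f_stat, p_val = 1.0, np.inf, 0.0

    k = design.coded_matrix().shape[1]
    return QuadraticSurfaceModel(
        intercept=float(beta[0]),
        linear=tuple(beta[1 : 1 + k]),
        quadratic=tuple(beta[1 + k : 1 + 2 * k]),
        interaction=tuple(beta[1 + 2 * k :]),
        r_squared=float(r2),
        f_statistic=float(f_stat),
        p_value=p_val,
        df_model=df_model,
        df_residual=df_resid,
    )


def predict(model: QuadraticSurfaceModel, coded_point: Sequence[float]) -> float:
    """Evaluate the fitted second-order polynomial at a coded point."""
    x = quadratic_design_matrix(np.asarray(coded_point, dtype=float))
    return float((x @ model.coefficients)[0])


def anova_table(model: QuadraticSurfaceModel, design: CCCDesign) -> pd.DataFrame:
    """Decompose variation into model / residual, and residual into lack-of-fit
    plus pure error estimated from the centre-point replicates.

    Returns a frame with rows model, residual, lack_of_fit, pure_error,
    total and columns ss, df, ms, F, p. Without >= 2 centre replicates the
    lack-of-fit rows carry NaN (flagged, not an exception).
    """
    y = design.responses()
    X = quadratic_design_matrix(design.coded_matrix())
    yhat = X @ model.coefficients
    sse = float(((y - yhat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    ssm = sst - sse
    df_m, df_r = model.df_model, model.df_residual

    center_resp = [p.response for p in design.points if p.role == "center"]
    rows = {
        "model": [ssm, df_m],
        "residual": [sse, df_r],
    }
    if len(center_resp) >= 2:
        c = np.asarray(center_resp, dtype=float)
        ss_pe = float(((c - c.mean()) ** 2).sum())
        df_pe = len(c) - 1
        ss_lof = sse - ss_pe
        df_lof = df_r - df_pe
        rows["lack_of_fit"] = [ss_lof, df_lof]
        rows["pure_error"] = [ss_pe, df_pe]
    else:
        rows["lack_of_fit"] = [np.nan, np.nan]
        rows["pure_error"] = [np.nan, np.nan]
    rows["total"] = [sst, df_m + df_r]

    tab = pd.DataFrame.from_dict(rows, orient="index", columns=["ss", "df"])
    tab["ms"] = tab["ss"] / tab["df"].replace(0, np.nan)
    tab["F"] = np.nan
    tab["p"] = np.nan
    ms_resid = tab.loc["residual", "ms"]
    if ms_resid > 0:
        tab.loc["model", "F"] = tab.loc["model", "ms"] / ms_resid
        tab.loc["model", "p"] = _scistats.f.sf(tab.loc["model", "F"], df_m, df_r)
    ms_pe = tab.loc["pure_error", "ms"]
    if np.isfinite(ms_pe) and ms_pe > 0 and tab.loc["lack_of_fit", "df"] > 0:
        f_lof = tab.loc["lack_of_fit", "ms"] / ms_pe
        tab.loc["lack_of_fit", "F"] = f_lof
        tab.loc["lack_of_fit", "p"] = _scistats.f.sf(
            f_lof, tab.loc["lack_of_fit", "df"], tab.loc["pure_error", "df"]
        )
    return tab


@dataclass(frozen=True)
class OptimizationResult:
    """Constrained maximizer of a fitted surface, in coded and uncoded units."""

    coded_opt: tuple[float, ...]
    uncoded_opt: tuple[float, ...]
    predicted_response: float
    region: str


def optimize_surface(
    model: QuadraticSurfaceModel,
    region: Sequence[tuple[float, float]] | None = None,
    factors: Sequence[FactorSpec] = DEFAULT_FACTORS,
    grid_resolution: float = 0.01,
) -> OptimizationResult:
    """Maximize the fitted surface over a box in coded space.

    A dense grid scan (spacing ``grid_resolution`` coded units, enumerated
    in ascending lexicographic order so ties resolve to the smallest coded
    point) locates the basin; a bounded quasi-Newton polish refines it. The
    polished point is kept only if it improves on the grid maximum. The
    default region is the factorial cube [-1, 1]^k.
    """
    k = model.n_factors
    if region is None:
        region = [(-1.0, 1.0)] * k
        region_label = "factorial cube [-1,1]^3"
    else:
        region = [(float(lo), float(hi)) for lo, hi in region]
        region_label = "box " + "x".join(f"[{lo:g},{hi:g}]" for lo, hi in region)
    if len(region) != k:
        raise InvalidRegionError(f"region must have {k} intervals")
    for lo, hi in region:
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise InvalidRegionError("region must be a finite, ordered box")

    axes = [
        np.linspace(lo, hi, max(2, int(np.ceil((hi - lo) / grid_resolution)) + 1))
        if hi > lo
        else np.array([lo])
        for lo, hi in region
    ]
    # Evaluate the polynomial over the full grid by broadcasting sparse
    # axes (no design matrix materialized). C-order argmax returns the
    # first maximum, i.e. the lexicographically smallest coded point.
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    vals = np.asarray(model.intercept, dtype=float)
    for j, g in enumerate(grids):
        vals = vals + model.linear[j] * g + model.quadratic[j] * g**2
    pair = 0
    for a in range(k):
        for b in range(a + 1, k):
            vals = vals + model.interaction[pair] * grids[a] * grids[b]
            pair += 1
    vals = np.broadcast_to(vals, tuple(len(ax) for ax in axes))
    best = np.unravel_index(int(np.argmax(vals)), vals.shape)
    x0 = np.array([axes[j][best[j]] for j in range(k)])
    v0 = float(vals[best])

    res = _sciopt.minimize(
        lambda x: -predict(model, x),
        x0,
        method="L-BFGS-B",
        bounds=region,
    )
    if res.success and -res.fun > v0:
        x_opt, v_opt = np.clip(res.x, [lo for lo, _ in region], [hi for _, hi in region]), float(-res.fun)
    else:
        x_opt, v_opt = x0, v0

    uncoded = tuple(uncode_value(z, f) for z, f in zip(x_opt, factors))
    return OptimizationResult(
        coded_opt=tuple(float(z) for z in x_opt),
        uncoded_opt=uncoded,
        predicted_response=v_opt,
        region=region_label,
    )
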