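"""Factorial regression-model search linking survey responses to raster summaries.

Six survey responses (total / monoculture-only / intercrop-only cassava
density, each unweighted and density-weighted) are regressed on extracted
raster summaries.  The model space is the full cross of

* the cassava map variable: production or harvest area, at the point (0 km)
  or summarized over a 2/5/10 km buffer by one of seven statistics,
* its functional form: linear, logarithmic (with a data-driven offset),
  quadratic (orthogonal polynomials) or penalized spline,
* optionally a population covariate (same distance/summary structure; forms
  linear, log, independent spline, or a dependent 2-d spline with the
  cassava variable),
* optionally a settlement covariate (mean only — the layer is binary; same
  four forms), and
* optionally a joint 2-d spline over population and settlement.

Models whose terms are all parametric are ordinary least squares fits
(``modeltype = "linear"``); any smooth term makes the model an additive
model (``modeltype = "gam"``).  For every fitted model the Gaussian
log-likelihood, AIC, BIC and adjusted R^2 are extracted; the information
criteria support two conventions: ``"standard"`` (AIC = -2 logLik + 2p) and
``"as_printed"`` (AIC = -logLik + 2p), which never disagree on the ordering
of two models with equal parameter count.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gam import GAMFit, Smooth1D, TensorSmooth, fit_gam
from .geo_extract import STATISTICS, covariate_column

logger = logging.getLogger(__name__)

RESPONSE_VARIABLES = (
    "tot_density",
    "tot_density_w",
    "mono_density",
    "mono_density_w",
    "inter_density",
    "inter_density_w",
)

PARAMETRIC_FORMS = ("linear", "log", "quadratic")
CASSAVA_FORMS = PARAMETRIC_FORMS + ("spline",)
COVARIATE_FORMS = ("linear", "log", "spline", "spline2d")
_SMOOTH_FORMS = {"spline", "spline2d", "joint2d"}


def offset_constant(x) -> float:
    """Half the minimum non-zero value — the offset c used inside log(x + c)."""
    x = np.asarray(x, dtype=float)
    positive = x[x > 0]
    if positive.size == 0:
        raise ValueError("offset constant undefined for an all-zero variable")
    return float(positive.min()) / 2.0


@dataclass(frozen=True)
class CovariateSpec:
    """One extracted raster summary entering a model under a functional form."""

    layer: str           # production | harvest | population | settlement
    distance_km: float
    statistic: str
    form: str            # linear | log | quadratic | spline | spline2d | joint2d

    @property
    def column(self) -> str:
        return covariate_column(self.layer, self.distance_km, self.statistic)


@dataclass(frozen=True)
class ModelSpec:
    """One point in the factorial model space."""

    response: str
    cassava: CovariateSpec
    population: CovariateSpec | None = None
    settlement: CovariateSpec | None = None
    joint_pop_settle_2d: bool = False

    def __post_init__(self) -> None:
        if self.joint_pop_settle_2d and (self.population is None or self.settlement is None):
            raise ValueError("a joint 2-d population-settlement spline requires both covariates")
        if self.cassava.distance_km == 0 and self.cassava.statistic != "mean":
            raise ValueError("point extraction (distance 0) forces summary = mean")

    @property
    def modeltype(self) -> str:
        forms = {self.cassava.form}
        for cov in (self.population, self.settlement):
            if cov is not None:
                forms.add(cov.form)
        return "gam" if forms & _SMOOTH_FORMS else "linear"

    def key(self) -> tuple:
        def cov_key(c):
            return ("-",) if c is None else (c.layer, c.distance_km, c.statistic, c.form)

        return (
            self.response,
            cov_key(self.cassava),
            cov_key(self.population),
            cov_key(self.settlement),
            self.joint_pop_settle_2d,
        )


@dataclass
class FitResult:
    """Fit diagnostics for one model."""

    spec: ModelSpec
    n: int
    p: float
    loglik: float
    aic: float
    bic: float
    adj_r2: float
    converged: bool
    convention: str = "standard"
    fit: object = field(default=None, repr=False)


def information_criteria(
    loglik: float,
    p: float,
    n: int,
    y: np.ndarray,
    fitted: np.ndarray,
    convention: str = "standard",
) -> tuple[float, float, float]:
    """(AIC, BIC, adjusted R^2) under the requested convention.

    ``standard``:  AIC = -2 logLik + 2p,  BIC = -2 logLik + log(n) p.
    ``as_printed``: AIC = -logLik + 2p,   BIC = -logLik + log(n) p.
    adj R^2 = 1 - [RSS / (n - p)] / [TSS / (n - 1)]; undefined when n <= p.
    """
    if convention == "standard":
        aic = -2.0 * loglik + 2.0 * p
        bic = -2.0 * loglik + np.log(n) * p
    elif convention == "as_printed":
        aic = -loglik + 2.0 * p
        bic = -loglik + np.log(n) * p
    else:
        raise ValueError(f"unknown information-criterion convention {convention!r}")
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if n > p:
        rss = float(np.sum((y - fitted) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        adj_r2 = 1.0 - (rss / (n - p)) / (tss / (n - 1)) if tss > 0 else float("nan")
    else:
        adj_r2 = float("nan")
    return float(aic), float(bic), float(adj_r2)


# ----------------------------------------------------------------------
# design-column construction


def _orthogonal_poly(x: np.ndarray, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial columns of degree 1..degree (no intercept)."""
    x = np.asarray(x, dtype=float)
    V = np.vander(x, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    return Q[:, 1:]


def _transform_columns(x: np.ndarray, form: str) -> np.ndarray:
    if form == "linear":
        return x[:, None]
    if form == "log":
        c = offset_constant(x) if np.any(x == 0) else 0.0
        return np.log(x + c)[:, None]
    if form == "quadratic":
        return _orthogonal_poly(x, 2)
    raise ValueError(f"form {form!r} is not parametric")


def _build_design(spec: ModelSpec, data: pd.DataFrame):
    """(y, X_parametric, smooths, smooth_data) for one model spec."""
    y = data[spec.response].to_numpy(dtype=float)
    n = y.size
    X_cols = [np.ones((n, 1))]
    smooths: list = []
    smooth_data: dict[str, np.ndarray] = {}

    def values(cov: CovariateSpec) -> np.ndarray:
        if cov.column not in data.columns:
            raise KeyError(f"covariate column {cov.column!r} missing from data")
        return data[cov.column].to_numpy(dtype=float)

    x_cass = values(spec.cassava)
    covs = [c for c in (spec.population, spec.settlement) if c is not None]
    has_dependent_2d = any(c.form == "spline2d" for c in covs)

    # cassava main effect, absorbed into a tensor when a dependent 2-d
    # spline with cassava is requested
    if not has_dependent_2d:
        if spec.cassava.form == "spline":
            smooths.append(Smooth1D(spec.cassava.column))
            smooth_data[spec.cassava.column] = x_cass
        else:
            X_cols.append(_transform_columns(x_cass, spec.cassava.form))

    if spec.joint_pop_settle_2d:
        xp, xs = values(spec.population), values(spec.settlement)
        name = f"{spec.population.column}:{spec.settlement.column}"
        smooths.append(TensorSmooth(name))
        smooth_data[name] = np.c_[xp, xs]
        # cassava main effect handled above (no dependent 2-d here)
    else:
        for cov in covs:
            x = values(cov)
            if cov.form == "spline2d":
                name = f"{spec.cassava.column}:{cov.column}"
                smooths.append(TensorSmooth(name))
                smooth_data[name] = np.c_[x_cass, x]
            elif cov.form == "spline":
                smooths.append(Smooth1D(cov.column))
                smooth_data[cov.column] = x
            else:
                X_cols.append(_transform_columns(x, cov.form))

    return y, np.hstack(X_cols), smooths, smooth_data


# ----------------------------------------------------------------------
# fitting


def _ols_result(spec: ModelSpec, y, X, convention: str) -> FitResult:
    n = y.size
    p = int(np.linalg.matrix_rank(X))
    if p < X.shape[1]:
        # degenerate design (e.g. constant transformed covariate): flag, keep row
        return FitResult(spec, n, p, float("nan"), float("nan"), float("nan"), float("nan"), False, convention)
    res = sm.OLS(y, X).fit()
    loglik = float(res.llf)
    aic, bic, adj = information_criteria(loglik, p, n, y, res.fittedvalues, convention)
    return FitResult(spec, n, p, loglik, aic, bic, adj, True, convention, fit=res)


def fit_baseline(response, x, transform: str = "log", convention: str = "standard") -> FitResult:
    """Baseline OLS of a survey response on one (transformed) map variable.

    ``transform`` is ``"log"`` (y ~ log(x + c)) or ``"linear"`` (y ~ x); the
    response itself is never transformed.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size:
        raise ValueError("response and explanatory variable must have equal length")
    if y.size < 3:
        raise ValueError("baseline fit requires at least 3 observations")
    spec = ModelSpec("baseline", CovariateSpec("production", 0, "mean", transform))
    cols = _transform_columns(x, transform)
    X = np.column_stack([np.ones(y.size), cols])
    if np.allclose(cols.std(axis=0), 0.0):
        return FitResult(spec, y.size, 1, float("nan"), float("nan"), float("nan"), float("nan"), False, convention)
    return _ols_result(spec, y, X, convention)


def fit_candidate(
    spec: ModelSpec,
    data: pd.DataFrame,
    convention: str = "standard",
    method: str = "GCV",
) -> FitResult:
    """Fit one model of the factorial space on the assembled covariate table."""
    y, X_par, smooths, smooth_data = _build_design(spec, data)
    n = y.size
    try:
        if not smooths:
            if np.allclose(X_par[:, 1:].std(axis=0), 0.0):
                raise np.linalg.LinAlgError("degenerate design")
            return _ols_result(spec, y, X_par, convention)
        gfit: GAMFit = fit_gam(y, X_par, smooths, smooth_data, method=method)
        p = gfit.edf
        loglik = gfit.loglik
        aic, bic, adj = information_criteria(loglik, p, n, y, gfit.fitted, convention)
        return FitResult(spec, n, p, loglik, aic, bic, adj, True, convention, fit=gfit)
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("model %s failed to converge: %s", spec.key(), exc)
        return FitResult(spec, n, float("nan"), float("nan"), float("nan"), float("nan"), float("nan"), False, convention)


# ----------------------------------------------------------------------
# enumeration


@dataclass
class SearchConfig:
    """Restrictions on the factorial model space."""

    responses: tuple = ("tot_density",)
    cass_types: tuple = ("production", "harvest")
    cass_distances: tuple = (0, 2, 5, 10)
    cass_summaries: tuple = STATISTICS
    cass_forms: tuple = CASSAVA_FORMS
    include_population: bool = True
    population_distances: tuple = (0, 2, 5, 10)
    population_summaries: tuple = STATISTICS
    population_forms: tuple = COVARIATE_FORMS
    include_settlement: bool = True
    settlement_distances: tuple = (2, 5, 10)
    settlement_forms: tuple = COVARIATE_FORMS
    allow_joint_2d: bool = True

    def __post_init__(self) -> None:
        if not self.responses or not self.cass_types or not self.cass_forms:
            raise ValueError("search configuration must allow at least one model")
        for d in itertools.chain(self.cass_distances, self.population_distances, self.settlement_distances):
            if d not in (0, 2, 5, 10):
                raise ValueError(f"buffer distance {d} not in the allowed set {{0, 2, 5, 10}}")


def _variable_combos(distances, summaries) -> list[tuple[float, str]]:
    """(distance, summary) pairs; the point (0 km) always has summary mean."""
    combos = []
    for d in distances:
        if d == 0:
            combos.append((0, "mean"))
        else:
            combos.extend((d, s) for s in summaries)
    return combos


def enumerate_model_space(config: SearchConfig) -> list[ModelSpec]:
    """All distinct model specifications allowed by the configuration."""
    cass_opts = [
        CovariateSpec(t, d, s, f)
        for t in config.cass_types
        for d, s in _variable_combos(config.cass_distances, config.cass_summaries)
        for f in config.cass_forms
    ]
    pop_opts: list[CovariateSpec | None] = [None]
    pop_var_combos = []
    if config.include_population:
        pop_var_combos = _variable_combos(config.population_distances, config.population_summaries)
        pop_opts += [
            CovariateSpec("population", d, s, f)
            for d, s in pop_var_combos
            for f in config.population_forms
        ]
    settle_opts: list[CovariateSpec | None] = [None]
    settle_var_combos = []
    if config.include_settlement:
        settle_var_combos = _variable_combos(config.settlement_distances, ("mean",))
        settle_opts += [
            CovariateSpec("settlement", d, s, f)
            for d, s in settle_var_combos
            for f in config.settlement_forms
        ]

    specs: dict[tuple, ModelSpec] = {}
    for resp in config.responses:
        for cass in cass_opts:
            for pop in pop_opts:
                for settle in settle_opts:
                    spec = ModelSpec(resp, cass, pop, settle)
                    specs[spec.key()] = spec
            if config.allow_joint_2d and config.include_population and config.include_settlement:
                for pd_, ps in pop_var_combos:
                    for sd, ss in settle_var_combos:
                        spec = ModelSpec(
                            resp,
                            cass,
                            CovariateSpec("population", pd_, ps, "joint2d"),
                            CovariateSpec("settlement", sd, ss, "joint2d"),
                            joint_pop_settle_2d=True,
                        )
                        specs[spec.key()] = spec
    out = sorted(specs.values(), key=lambda s: s.key())
    logger.info("enumerated %d distinct model specifications", len(out))
    return out


def expected_space_size(config: SearchConfig) -> int:
    """Closed-form count of the enumerated space (per cross-product algebra)."""
    n_cass = (
        len(config.cass_types)
        * len(_variable_combos(config.cass_distances, config.cass_summaries))
        * len(config.cass_forms)
    )
    n_popvar = (
        len(_variable_combos(config.population_distances, config.population_summaries))
        if config.include_population
        else 0
    )
    n_settlevar = (
        len(_variable_combos(config.settlement_distances, ("mean",)))
        if config.include_settlement
        else 0
    )
    pop_opts = 1 + n_popvar * len(config.population_forms)
    settle_opts = 1 + n_settlevar * len(config.settlement_forms)
    joint = n_popvar * n_settlevar if config.allow_joint_2d else 0
    return len(config.responses) * n_cass * (pop_opts * settle_opts + joint)


def fit_model_space(
    specs: list[ModelSpec],
    data: pd.DataFrame,
    convention: str = "standard",
    method: str = "GCV",
) -> list[FitResult]:
    """Fit every spec; non-converging fits are retained with missing criteria."""
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for spec in specs:
            results.append(fit_candidate(spec, data, convention=convention, method=method))
    n_failed = sum(1 for r in results if not r.converged)
    if n_failed:
        logger.info("%d of %d fits did not converge", n_failed, len(results))
    return results


def rank_models(results: list[FitResult]) -> tuple[pd.DataFrame, FitResult]:
    """Results sorted by AIC (ties: smaller p, then spec key); best model first."""
    converged = [r for r in results if r.converged]
    if not converged:
        raise ValueError("no converged model to rank")
    ordered = sorted(converged, key=lambda r: (r.aic, r.p, r.spec.key()))
    table = results_frame(ordered)
    return table, ordered[0]


def results_frame(results: list[FitResult]) -> pd.DataFrame:
    """One row per fitted model with factor levels and criteria."""
    rows = []
    for r in results:
        s = r.spec
        row = {
            "response": s.response,
            "modeltype": s.modeltype,
            "cass_type": s.cassava.layer,
            "cass_dist": s.cassava.distance_km,
            "cass_summary": s.cassava.statistic,
            "cass_form": s.cassava.form,
            "population_type": "included" if s.population is not None else "excluded",
            "population_dist": s.population.distance_km if s.population else float("nan"),
            "population_summary": s.population.statistic if s.population else "",
            "population_form": s.population.form if s.population else "",
            "settlement_type": "included" if s.settlement is not None else "excluded",
            "settlement_dist": s.settlement.distance_km if s.settlement else float("nan"),
            "settlement_form": s.settlement.form if s.settlement else "",
            "joint_pop_settle_2d": s.joint_pop_settle_2d,
            "n": r.n,
            "p": r.p,
            "logLik": r.loglik,
            "AIC": r.aic,
            "BIC": r.bic,
            "adj_R2": r.adj_r2,
            "converged": r.converged,
            "convention": r.convention,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def best_model_smooths(result: FitResult, data: pd.DataFrame, n_grid: int = 100) -> pd.DataFrame:
    """Fitted smooth estimates of the best model on per-term grids (for plotting)."""
    if not isinstance(result.fit, GAMFit):
        return pd.DataFrame(columns=["term", "axis", "x", "estimate", "se"])
    rows = []
    for block in result.fit._blocks:
        term = block.term
        if isinstance(term, Smooth1D):
            x = term._x
            grid = np.linspace(x.min(), x.max(), n_grid)
            est, se = result.fit.smooth_estimate(term.name, grid)
            for g, e, s_ in zip(grid, est, se):
                rows.append({"term": term.name, "axis": term.name, "x": g, "estimate": e, "se": s_})
        else:  # tensor: profile along each margin at the other's median
            x = term._x
            med = np.median(x, axis=0)
            for j, axis in enumerate(term.name.split(":")):
                grid = np.linspace(x[:, j].min(), x[:, j].max(), n_grid)
                pts = np.tile(med, (n_grid, 1))
                pts[:, j] = grid
                est, se = result.fit.smooth_estimate(term.name, pts)
                for g, e, s_ in zip(grid, est, se):
                    rows.append({"term": term.name, "axis": axis, "x": g, "estimate": e, "se": s_})
    return pd.DataFrame(rows)
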