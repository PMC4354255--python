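"""Maximum-likelihood fitting of depletion functional responses with
indicator-variable treatment coding, plus bootstrap confidence envelopes.

Treatment coding replaces the attack rate and handling time by additive
expansions over 0/1 indicators, e.g. for a prey-coded model

    a = aI + aB * B_i + aS * S_i,     h = hI + hB * B_i + hS * S_i,

where the intercepts (aI, hI) belong to the base level and each effect is the
offset of one treatment level (or, for interactions, the product of its main
indicators).  The likelihood treats each pot's kill count as
``Binomial(N0, Ne(a_cell, h_cell, N0, T) / N0)`` with ``Ne`` the Rogers
Type II expectation, so depletion is accounted for and effects can be read
straight off the parameter vector as in linear regression: estimate, Wald SE
from the inverse observed Hessian, z score, two-sided normal p.

Parameters are optimised on the natural scale (effects may legitimately be
negative); parameter vectors implying a nonpositive attack rate or negative
handling time in any observed cell receive an infinite penalty, which steers
the optimiser without a transformation.

Uncertainty around fitted curves uses nonparametric case bootstrapping of
whole pots, stratified by treatment-by-density cell so every resample keeps
the factorial layout, with per-density equi-tailed percentile envelopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .design import PREDATOR_SPECIES, PREY_SPECIES
from .response import _rogers_core

__all__ = [
    "ModelSpec",
    "FitResult",
    "BootstrapEnvelope",
    "between_module_spec",
    "within_module_spec",
    "no_treatment_spec",
    "build_indicator_rows",
    "nll_binomial",
    "fit_fr",
    "fit_variant",
    "contrast_table",
    "bootstrap_fr",
    "predict_curve_ci",
]

#: known levels per design column, in canonical (base-first by default) order
FACTOR_LEVELS = {
    "prey_species": list(PREY_SPECIES),
    "predator_species": list(PREDATOR_SPECIES),
    "parasitised": [False, True],
    "fish_present": [False, True],
}

DEFAULT_BASE_LEVELS = {
    "prey_species": "A_aquaticus",
    "predator_species": "G_d_celticus",
    "parasitised": False,
    "fish_present": False,
}

_PCLIP = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """Which treatment terms modify the attack rate and handling time.

    ``a_terms`` / ``h_terms`` are tuples of terms; a term is a tuple of design
    columns, e.g. ``("predator_species",)`` for a main effect or
    ``("predator_species", "parasitised")`` for their interaction.  The
    simplified-attack-rate model has ``a_terms = ()`` (intercept only).
    ``variant`` selects the response family; treatment terms are supported for
    the Type II (Rogers) family, while variants I and III are intercept-only
    families used in AIC comparisons.
    """

    a_terms: tuple = ()
    h_terms: tuple = ()
    base_levels: tuple = tuple(sorted(DEFAULT_BASE_LEVELS.items()))
    variant: str = "II"

    @property
    def bases(self) -> dict:
        return dict(self.base_levels)

    def with_base(self, **levels) -> "ModelSpec":
        bases = self.bases
        bases.update(levels)
        return ModelSpec(self.a_terms, self.h_terms, tuple(sorted(bases.items())), self.variant)

    def __post_init__(self):
        if self.variant not in ("I", "II", "III"):
            raise ValueError(f"unknown response variant {self.variant!r}")
        if self.variant in ("I", "III") and (self.a_terms or self.h_terms):
            raise ValueError(
                f"treatment terms are only supported for variant II, "
                f"not {self.variant!r}"
            )


def between_module_spec(base_prey: str = "A_aquaticus") -> ModelSpec:
    """Prey-coded model comparing the three community modules."""
    spec = ModelSpec(a_terms=(("prey_species",),), h_terms=(("prey_species",),))
    return spec.with_base(prey_species=base_prey)


def within_module_spec(simplified_a: bool = True, interactions: bool = True) -> ModelSpec:
    """Within-module model over amphipod species, parasitism and fish presence.

    By default the attack rate is intercept-only (the simplified model) and
    the handling time carries all three main effects plus their two- and
    three-way interactions.
    """
    mains = (("predator_species",), ("fish_present",), ("parasitised",))
    h_terms = mains
    if interactions:
        h_terms = mains + (
            ("predator_species", "fish_present"),
            ("predator_species", "parasitised"),
            ("parasitised", "fish_present"),
            ("predator_species", "parasitised", "fish_present"),
        )
    a_terms = () if simplified_a else h_terms
    return ModelSpec(a_terms=a_terms, h_terms=h_terms)


def no_treatment_spec(variant: str = "II") -> ModelSpec:
    """Single-curve model with no treatment effects (any variant)."""
    return ModelSpec(variant=variant)


def _term_columns(term, bases):
    """Expand one term into (name, [(col, level), ...]) indicator columns."""
    level_lists = []
    for col in term:
        if col not in FACTOR_LEVELS:
            raise ValueError(f"unknown design factor {col!r}")
        base = bases.get(col)
        level_lists.append([(col, lev) for lev in FACTOR_LEVELS[col] if lev != base])
    columns = [[]]
    for options in level_lists:
        columns = [prefix + [opt] for opt in options for prefix in [*columns]]
    out = []
    for combo in columns:
        name = ":".join(f"{col}[{lev}]" for col, lev in combo)
        out.append((name, combo))
    return out


def _indicator_matrix(units: pd.DataFrame, terms, bases):
    names, cols = [], []
    for term in terms:
        for col in term:
            seen = set(units[col].unique())
            known = set(FACTOR_LEVELS[col]) | {bases.get(col)}
            unseen = seen - known
            if unseen:
                raise ValueError(
                    f"column {col!r} contains level(s) {sorted(map(str, unseen))} "
                    "not present in the model specification"
                )
        for name, combo in _term_columns(term, bases):
            ind = np.ones(len(units), dtype=float)
            for col, lev in combo:
                ind *= (units[col] == lev).to_numpy(dtype=float)
            names.append(name)
            cols.append(ind)
    matrix = np.column_stack(cols) if cols else np.empty((len(units), 0))
    return matrix, names


def build_indicator_rows(units: pd.DataFrame, spec: ModelSpec):
    """Indicator matrices (attack, handling) for each experimental unit.

    Returns ``(Xa, a_names, Xh, h_names)``: design matrices without the
    intercept column (the intercept is implicit) and the deterministic,
    documented column labels ``"column[level]"`` joined by ``:`` for
    interactions.  Base-level units map to all-zero rows.
    """
    bases = spec.bases
    xa, a_names = _indicator_matrix(units, spec.a_terms, bases)
    xh, h_names = _indicator_matrix(units, spec.h_terms, bases)
    return xa, a_names, xh, h_names


class _Prepared:
    """Record table compressed to unique (indicator-row, density) combos.

    The binomial log likelihood depends on the data only through per-combo
    kill totals, so each likelihood evaluation costs O(#combos) regardless of
    the number of pots.
    """

    def __init__(self, records: pd.DataFrame, spec: ModelSpec, t: float):
        self.spec = spec
        self.t = float(t)
        self.n_records = len(records)
        xa, self.a_names, xh, self.h_names = build_indicator_rows(records, spec)
        self.ka, self.kh = xa.shape[1], xh.shape[1]
        n0 = records["density"].to_numpy(dtype=float)
        ne = records["killed"].to_numpy(dtype=float)
        key = np.column_stack([xa, xh, n0])
        uniq, inverse = np.unique(key, axis=0, return_inverse=True)
        self.xa_u = uniq[:, : self.ka]
        self.xh_u = uniq[:, self.ka : self.ka + self.kh]
        self.n0_u = uniq[:, -1]
        self.combo_of_record = inverse
        self.n_u = len(uniq)
        self.record_ne = ne
        self.record_n0 = n0
        self.sum_ne = np.bincount(inverse, weights=ne, minlength=self.n_u)
        self.sum_miss = np.bincount(inverse, weights=n0 - ne, minlength=self.n_u)
        # log binomial coefficients: constant in theta, included so logLik/AIC
        # are proper and comparable with GLM outputs
        self.log_binom_const = float(
            np.sum(gammaln(n0 + 1) - gammaln(ne + 1) - gammaln(n0 - ne + 1))
        )

    @property
    def n_params(self):
        if self.spec.variant == "II":
            return 2 + self.ka + self.kh
        if self.spec.variant == "I":
            return 1
        return 3  # variant III: b, c, h

    def expected(self, theta):
        """Per-combo expected kills; NaN-free, or None if theta infeasible."""
        v = self.spec.variant
        if v == "II":
            a = theta[0] + self.xa_u @ theta[1 : 1 + self.ka]
            h = theta[1 + self.ka] + self.xh_u @ theta[2 + self.ka :]
            if np.any(a <= 0) or np.any(h < 0):
                return None
            return _rogers_core(a, h, self.n0_u, self.t)
        if v == "I":
            (a,) = theta
            if a <= 0:
                return None
            return self.n0_u * -np.expm1(-a * self.t)
        b, c, h = theta
        if b <= 0 or c < 0 or h < 0:
            return None
        a_eff = b * self.n0_u / (1.0 + c * self.n0_u)
        return _rogers_core(a_eff, h, self.n0_u, self.t)

    def nll(self, theta, sum_ne=None, sum_miss=None):
        ne_hat = self.expected(np.asarray(theta, dtype=float))
        if ne_hat is None or not np.all(np.isfinite(ne_hat)):
            return np.inf
        p = np.clip(ne_hat / self.n0_u, _PCLIP, 1.0 - _PCLIP)
        if sum_ne is None:
            sum_ne, sum_miss = self.sum_ne, self.sum_miss
        ll = float(sum_ne @ np.log(p) + sum_miss @ np.log1p(-p))
        return -(ll + self.log_binom_const)

    def cell_row(self, levels: dict):
        """Indicator rows (xa, xh) for a single treatment cell."""
        unit = dict(self.spec.bases)
        unit.update(levels)
        frame = pd.DataFrame([unit])
        xa, _, xh, _ = build_indicator_rows(frame, self.spec)
        return xa[0], xh[0]


def nll_binomial(theta, records: pd.DataFrame, spec: ModelSpec, t: float = 1.0):
    """Negative binomial log likelihood of ``theta`` for validated records.

    ``-sum log Binomial(killed; N0, Ne_hat/N0)`` with the per-cell Rogers
    expectation; infeasible parameter vectors return ``+inf``.  The fitter
    uses a cached, combo-compressed version of this same quantity.
    """
    if len(records) == 0:
        return 0.0
    return _Prepared(records, spec, t).nll(np.asarray(theta, dtype=float))


@dataclass
class FitResult:
    """MLE output in regression-table form."""

    names: list
    theta: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    aic: float
    n_params: int
    n_records: int
    converged: bool
    boundary: bool
    se_available: bool
    message: str
    spec: ModelSpec
    t: float
    starts: list = field(repr=False, default_factory=list)
    _prep: _Prepared = field(repr=False, default=None)

    def cell_params(self, levels: dict | None = None):
        """(a, h) for one treatment cell (Type II fits)."""
        if self.spec.variant != "II":
            raise ValueError("cell_params is defined for variant II fits")
        xa, xh = self._prep.cell_row(levels or {})
        ka = self._prep.ka
        a = self.theta[0] + xa @ self.theta[1 : 1 + ka]
        h = self.theta[1 + ka] + xh @ self.theta[2 + ka :]
        return float(a), float(h)

    def summary(self, decimals=None) -> pd.DataFrame:
        return contrast_table(self, decimals=decimals)


def _start_values(prep: _Prepared):
    """Heuristic starts: attack rate from a disc-equation linearisation at the
    two lowest densities, handling time from the reciprocal maximum kill."""
    n0, ne = prep.record_n0, prep.record_ne
    low = np.isin(n0, np.sort(np.unique(n0))[:2])
    ratio = float(np.clip(np.mean(ne[low] / n0[low]), 1e-3, 0.95))
    a0 = -np.log1p(-ratio) / prep.t
    h0 = prep.t / max(1.0, float(ne.max()))
    v = prep.spec.variant
    if v == "I":
        return np.array([a0])
    if v == "III":
        mid = float(np.median(np.unique(n0)))
        return np.array([a0 / mid, 0.1, h0])
    theta = np.zeros(prep.n_params)
    theta[0] = a0
    theta[1 + prep.ka] = h0
    return theta


def _fd_hessian(fun, theta, rel_step=1e-5):
    k = len(theta)
    steps = rel_step * np.maximum(np.abs(theta), 1.0)
    hess = np.empty((k, k))
    f0 = fun(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        fpp = fun(theta + ei)
        fmm = fun(theta - ei)
        hess[i, i] = (fpp + fmm - 2 * f0) / steps[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            fij = fun(theta + ei + ej) - fun(theta + ei - ej)
            fij -= fun(theta - ei + ej) - fun(theta - ei - ej)
            hess[i, j] = hess[j, i] = fij / (4 * steps[i] * steps[j])
    return hess


def _minimise(prep, theta0, maxiter_mult=400, refine=True):
    res = optimize.minimize(
        prep.nll,
        theta0,
        method="Nelder-Mead",
        options={
            "maxiter": maxiter_mult * len(theta0),
            "xatol": 1e-7,
            "fatol": 1e-9,
        },
    )
    if refine and np.isfinite(res.fun):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res2 = optimize.minimize(prep.nll, res.x, method="BFGS")
                if np.isfinite(res2.fun) and res2.fun <= res.fun:
                    return res2.x, float(res2.fun), True
            except Exception:
                pass
    return res.x, float(res.fun), bool(res.success)


def _prepare(records, spec, t):
    if len(records) < 1:
        raise ValueError("cannot fit an empty record set")
    if records["density"].nunique() < 2:
        raise ValueError("fitting requires at least 2 distinct prey densities")
    return _Prepared(records, spec, t)


def fit_fr(
    records: pd.DataFrame,
    spec: ModelSpec = None,
    starts=None,
    n_starts: int = 5,
    t: float = 1.0,
    jitter_seed: int = 0,
) -> FitResult:
    """Fit a functional-response model by maximum likelihood.

    Optimisation is multi-start (one heuristic start plus jittered copies,
    intercepts scaled by uniform(0.5, 1.5) factors), Nelder-Mead simplex
    refined by BFGS; the covariance is the inverse of a central
    finite-difference observed Hessian at the optimum (relative step 1e-5).
    A singular or non-positive Hessian leaves estimates in place with SEs
    flagged unavailable.  Saturated data (every pot eating all its prey)
    are reported with ``boundary=True`` and ``converged=False``.
    """
    spec = spec or ModelSpec()
    prep = _prepare(records, spec, t)
    theta0 = _start_values(prep) if starts is None else np.asarray(starts, dtype=float)
    rng = np.random.default_rng(jitter_seed)

    start_list = [theta0]
    for _ in range(max(0, n_starts - 1)):
        jit = theta0.copy()
        scale = rng.uniform(0.5, 1.5, size=jit.shape)
        # jitter intercept-like entries only; zero effect starts stay zero
        jit = np.where(jit != 0, jit * scale, 0.0)
        start_list.append(jit)

    best = None
    any_success = False
    for s in start_list:
        x, fval, ok = _minimise(prep, s)
        any_success = any_success or ok
        if np.isfinite(fval) and (best is None or fval < best[1]):
            best = (x, fval, ok)
    if best is None or not np.isfinite(best[1]):
        raise RuntimeError(
            "functional-response fit failed from every start "
            f"(best objective {best[1] if best else np.nan})"
        )
    theta, nll_opt, _ = best

    saturated = bool(np.all(prep.record_ne == prep.record_n0))
    ne_hat = prep.expected(theta)
    clamped = ne_hat is not None and bool(
        np.all(ne_hat / prep.n0_u >= 1.0 - 2 * _PCLIP)
    )
    boundary = saturated or clamped

    k = prep.n_params
    cov = np.full((k, k), np.nan)
    se = np.full(k, np.nan)
    se_available = False
    message = "ok"
    try:
        hess = _fd_hessian(prep.nll, theta)
        if np.all(np.isfinite(hess)):
            cov_try = np.linalg.inv(hess)
            diag = np.diag(cov_try)
            if np.all(np.isfinite(diag)) and np.all(diag > 0):
                cov = cov_try
                se = np.sqrt(diag)
                se_available = True
            else:
                message = "observed Hessian not positive definite; SEs unavailable"
        else:
            message = "non-finite Hessian; SEs unavailable"
    except np.linalg.LinAlgError:
        message = "singular Hessian; SEs unavailable"
    if boundary:
        message = "fit at the saturation boundary (all prey consumed)"

    with np.errstate(invalid="ignore", divide="ignore"):
        z = theta / se
        p = 2.0 * stats.norm.sf(np.abs(z))

    if spec.variant == "II":
        names = ["a:Intercept"] + [f"a:{n}" for n in prep.a_names]
        names += ["h:Intercept"] + [f"h:{n}" for n in prep.h_names]
    elif spec.variant == "I":
        names = ["a:Intercept"]
    else:
        names = ["b:Intercept", "c:Intercept", "h:Intercept"]

    loglik = -nll_opt
    return FitResult(
        names=names,
        theta=np.asarray(theta, dtype=float),
        cov=cov,
        se=se,
        z=z,
        p=p,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        n_params=k,
        n_records=prep.n_records,
        converged=bool(any_success and se_available and not boundary),
        boundary=boundary,
        se_available=se_available,
        message=message,
        spec=spec,
        t=t,
        starts=[np.asarray(s) for s in start_list],
        _prep=prep,
    )


def fit_variant(records: pd.DataFrame, variant: str, t: float = 1.0, **kwargs) -> FitResult:
    """Convenience: single-curve (no-treatment) fit of one response family."""
    return fit_fr(records, no_treatment_spec(variant), t=t, **kwargs)


def contrast_table(fit: FitResult, contrasts=None, decimals=None) -> pd.DataFrame:
    """Regression-style table: one row per parameter, or custom contrasts.

    A custom contrast is a ``(label, weights)`` pair; its estimate is
    ``c' theta`` with delta-method SE ``sqrt(c' V c)``.  ``decimals=3``
    reproduces the 3-decimal layout of published coefficient tables.
    """
    rows = []
    if contrasts is None:
        for name, est, se, z, p in zip(fit.names, fit.theta, fit.se, fit.z, fit.p):
            param, _, label = name.partition(":")
            rows.append(
                {
                    "Parameter": param,
                    "Contrast": label or "Intercept",
                    "Estimate": est,
                    "SE": se,
                    "z value": z,
                    "P": p,
                }
            )
    else:
        if not fit.se_available:
            raise ValueError("contrasts require a fit with an available covariance")
        for label, weights in contrasts:
            c = np.asarray(weights, dtype=float)
            if c.shape != (fit.n_params,):
                raise ValueError(
                    f"contrast {label!r} has {c.size} weights, "
                    f"model has {fit.n_params} parameters"
                )
            est = float(c @ fit.theta)
            se = float(np.sqrt(c @ fit.cov @ c))
            z = est / se if se > 0 else np.nan
            rows.append(
                {
                    "Parameter": "contrast",
                    "Contrast": label,
                    "Estimate": est,
                    "SE": se,
                    "z value": z,
                    "P": 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    if decimals is not None:
        for col in ("Estimate", "SE", "z value", "P"):
            table[col] = table[col].round(decimals)
    return table


@dataclass
class BootstrapEnvelope:
    """Equi-tailed percentile envelope of bootstrap-refitted response curves."""

    n_boot: int
    n_failed: int
    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    draws: np.ndarray = field(repr=False)
    cell: dict = field(default_factory=dict)
    seed: int | None = None
    high_failure: bool = False
    level: float = 0.95

    @property
    def n_kept(self):
        return self.n_boot - self.n_failed


_STRATA_COLS = ["prey_species", "predator_species", "parasitised", "fish_present", "density"]


def _curves_from_draws(prep, draws, cell, grid, t):
    xa, xh = prep.cell_row(cell or {})
    ka = prep.ka
    a = draws[:, 0] + draws[:, 1 : 1 + ka] @ xa
    h = draws[:, 1 + ka] + draws[:, 2 + ka :] @ xh
    return _rogers_core(a[:, None], h[:, None], grid[None, :], t)


def bootstrap_fr(
    records: pd.DataFrame,
    spec: ModelSpec = None,
    n_boot: int = 1500,
    seed: int | None = None,
    t: float = 1.0,
    cell: dict | None = None,
    grid=None,
    base_fit: FitResult | None = None,
) -> BootstrapEnvelope:
    """Case bootstrap of the fitted response, stratified by treatment x density.

    Whole pots are resampled with replacement within each treatment-by-density
    stratum (preserving the factorial layout), the model is refitted to each
    resample starting from the point estimate, failed refits are dropped and
    counted, and per-density 2.5/97.5 percentiles of the predicted curve for
    ``cell`` (default: the base level) form the envelope.  Same seed, same
    envelope.  A failure rate above 20% attaches a warning flag.
    """
    spec = spec or ModelSpec()
    if spec.variant != "II":
        raise ValueError("bootstrap envelopes are implemented for variant II fits")
    records = records.reset_index(drop=True)
    if base_fit is None:
        base_fit = fit_fr(records, spec, t=t)
    if base_fit.boundary:
        raise ValueError("cannot bootstrap from a boundary (saturated) fit")
    prep = base_fit._prep
    theta_hat = base_fit.theta

    strata_cols = [c for c in _STRATA_COLS if c in records.columns]
    strata = [idx.to_numpy() for _, idx in records.groupby(strata_cols).groups.items()]

    ne = prep.record_ne
    miss = prep.record_n0 - prep.record_ne
    combo = prep.combo_of_record

    grid_arr = (
        np.sort(records["density"].unique()).astype(float)
        if grid is None
        else np.asarray(grid, dtype=float)
    )
    if np.any(grid_arr <= 0):
        raise ValueError("prediction grid densities must be positive")

    draws = []
    n_failed = 0
    counts = np.empty(len(records))
    for b in range(n_boot):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(b,))
            if seed is not None
            else None
        )
        counts[:] = 0.0
        for idx in strata:
            # resampling n_s pots with replacement == multinomial pot counts
            counts[idx] = rng.multinomial(len(idx), np.full(len(idx), 1.0 / len(idx)))
        sum_ne = np.bincount(combo, weights=counts * ne, minlength=prep.n_u)
        sum_miss = np.bincount(combo, weights=counts * miss, minlength=prep.n_u)
        res = optimize.minimize(
            prep.nll,
            theta_hat,
            args=(sum_ne, sum_miss),
            method="Nelder-Mead",
            options={"maxiter": 250 * len(theta_hat), "xatol": 1e-5, "fatol": 1e-7},
        )
        if np.isfinite(res.fun) and res.success:
            draws.append(res.x)
        else:
            n_failed += 1

    high_failure = n_failed > 0.2 * n_boot
    if high_failure:
        warnings.warn(
            f"bootstrap: {n_failed}/{n_boot} refits failed (>20%); "
            "envelope may be unreliable",
            stacklevel=2,
        )
    draws_arr = np.asarray(draws) if draws else np.empty((0, prep.n_params))
    if len(draws_arr):
        curves = _curves_from_draws(prep, draws_arr, cell, grid_arr, t)
        lower = np.percentile(curves, 2.5, axis=0)
        upper = np.percentile(curves, 97.5, axis=0)
    else:
        lower = np.full_like(grid_arr, np.nan)
        upper = np.full_like(grid_arr, np.nan)
    return BootstrapEnvelope(
        n_boot=n_boot,
        n_failed=n_failed,
        grid=grid_arr,
        lower=lower,
        upper=upper,
        draws=draws_arr,
        cell=dict(cell or {}),
        seed=seed,
        high_failure=high_failure,
    )


def predict_curve_ci(
    fit: FitResult, envelope: BootstrapEnvelope, grid=None
) -> pd.DataFrame:
    """Plot-ready table (density, mean, lower, upper) for the envelope's cell.

    The mean row is the Rogers expectation at the fitted cell parameters; the
    band is recomputed from the stored bootstrap draws, so any positive grid
    works.  A zero attack rate collapses the curve and band to zero, flagged
    in the ``collapsed`` column.
    """
    grid_arr = envelope.grid if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid_arr <= 0):
        raise ValueError("prediction grid densities must be positive")
    a, h = fit.cell_params(envelope.cell)
    mean = _rogers_core(a, h, grid_arr, fit.t)
    if len(envelope.draws):
        curves = _curves_from_draws(fit._prep, envelope.draws, envelope.cell, grid_arr, fit.t)
        lower = np.percentile(curves, 2.5, axis=0)
        upper = np.percentile(curves, 97.5, axis=0)
    else:
        lower = np.full_like(grid_arr, np.nan)
        upper = np.full_like(grid_arr, np.nan)
    collapsed = bool(a == 0 or np.all(upper - lower == 0))
    return pd.DataFrame(
        {
            "density": grid_arr,
            "mean": mean,
            "lower": lower,
            "upper": upper,
            "collapsed": collapsed,
        }
    )
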