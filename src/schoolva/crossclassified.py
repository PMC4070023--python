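"""Cross-classified school x neighbourhood linear random-effects models by REML.

The model for pupil BMI-SDS is

    y = X beta + Z_s u + Z_n v + e,
    u ~ N(0, var_school I),  v ~ N(0, var_neighbourhood I),
    e ~ N(0, var_residual I),  mutually independent,

with pupils crossed (not nested) between schools and neighbourhoods.
Estimation maximises the REML log-likelihood profiled over the residual
variance, as a function of the variance ratios gamma_f =
var_f / var_residual, optimised on the log scale.  All linear algebra
goes through the mixed-model equations with the sparse crossed
incidence matrices reduced to dense q x q cross-products (q = number of
schools + neighbourhoods, a few hundred), so each objective evaluation
is a single Cholesky factorisation.

Reported per-school "expected residuals" are empirical BLUPs — the
predicted school random effects at the REML variance estimates, shrunk
towards zero in proportion to the school's information — with
prediction standard errors from the inverse mixed-model coefficient
matrix.  Unshrunken per-school mean residuals are also available
(:func:`raw_school_residuals`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse, stats

from .synthetic_cohort import ETHNICITY_CATEGORIES

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "FittedModel",
    "ModelError",
    "RankDeficientError",
    "NotConvergedError",
    "fit_reml",
    "icc",
    "school_blups",
    "raw_school_residuals",
]

logger = logging.getLogger(__name__)

_REF_ETHNICITY = ETHNICITY_CATEGORIES[0]  # White-British
_Z975 = float(stats.norm.ppf(0.975))

# variance ratios at or below this are treated as a boundary (zero) estimate
_BOUNDARY_GAMMA = 1e-9


class ModelError(ValueError):
    """Invalid model specification or data for fitting."""


class RankDeficientError(ModelError):
    """Fixed-effect design matrix is not full rank."""


class NotConvergedError(RuntimeError):
    """Downstream use of a fit that did not converge."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: fixed-effect adjustment, random factors, cohort subset.

    ``adjusted=True`` includes ethnicity (4 indicator contrasts against
    White-British) and normalised deprivation as pupil-level fixed
    effects; ``adjusted=False`` is the intercept-only null model used
    for ICC decomposition.  ``cohort`` selects both cohorts pooled, or
    Reception / Year6 alone (the cohort-specific fits behind the
    value-added score).
    """

    adjusted: bool = True
    include_neighbourhood: bool = True
    cohort: str = "both"
    cohort_indicator: bool = False

    def __post_init__(self):
        if self.cohort not in ("both", "Reception", "Year6"):
            raise ModelError("cohort must be 'both', 'Reception' or 'Year6'")
        if self.cohort_indicator and self.cohort != "both":
            raise ModelError("cohort_indicator only makes sense with cohort='both'")

    @property
    def is_null(self) -> bool:
        return not self.adjusted and not self.cohort_indicator


@dataclass(frozen=True)
class VarianceComponents:
    var_school: float
    var_neighbourhood: float
    var_residual: float

    def __post_init__(self):
        if self.var_school < 0 or self.var_neighbourhood < 0:
            raise ModelError("variance components must be non-negative")
        if not self.var_residual > 0:
            raise ModelError("residual variance must be positive")

    @property
    def total(self) -> float:
        return self.var_school + self.var_neighbourhood + self.var_residual


@dataclass
class FittedModel:
    spec: ModelSpec
    beta: pd.DataFrame            # index: term; estimate, se, ci_lower, ci_upper
    components: VarianceComponents
    reml_loglik: float
    blups: dict                   # factor -> DataFrame(level: residual, se, n_pupils)
    converged: bool
    n_obs: int
    n_schools: int
    n_lsoas: int
    n_dropped: int
    objective_path: list = field(default_factory=list, repr=False)

    def summary_dict(self) -> dict:
        """JSON-ready fit summary (fixed effects, components, ICC-style shares)."""
        comp = self.components
        return {
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_schools": int(self.n_schools),
            "n_lsoas": int(self.n_lsoas),
            "n_dropped": int(self.n_dropped),
            "reml_loglik": float(self.reml_loglik),
            "variance_components": {
                "school": comp.var_school,
                "neighbourhood": comp.var_neighbourhood,
                "residual": comp.var_residual,
            },
            "fixed_effects": {
                term: {
                    "estimate": float(row["estimate"]),
                    "se": float(row["se"]),
                    "ci_lower": float(row["ci_lower"]),
                    "ci_upper": float(row["ci_upper"]),
                }
                for term, row in self.beta.iterrows()
            },
        }


def _design_matrices(records: pd.DataFrame, spec: ModelSpec, response: str):
    required = [response, "school_id"]
    if spec.include_neighbourhood:
        required.append("lsoa_id")
    if spec.adjusted:
        required += ["ethnicity", "imd_norm"]
    if spec.cohort != "both" or spec.cohort_indicator:
        required.append("cohort")
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ModelError(f"records missing columns {missing}")

    df = records
    if spec.cohort != "both":
        df = df[df["cohort"] == spec.cohort]
        if df.empty:
            raise ModelError(f"no records for cohort {spec.cohort!r}")
    n_before = len(df)
    df = df.dropna(subset=required)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("fit_reml: dropped %d records with missing values", n_dropped)

    y = df[response].to_numpy(dtype=float)
    cols = {"const": np.ones(len(df))}
    if spec.adjusted:
        eth = df["ethnicity"]
        unknown = set(eth.unique()) - set(ETHNICITY_CATEGORIES)
        if unknown:
            raise ModelError(f"unknown ethnicity categories {sorted(unknown)}")
        present = set(eth.unique())
        for cat in ETHNICITY_CATEGORIES[1:]:
            if cat not in present:
                logger.info("fit_reml: ethnicity category %r absent, "
                            "indicator omitted", cat)
                continue
            cols[f"ethnicity[{cat}]"] = (eth == cat).to_numpy(dtype=float)
        cols["imd_norm"] = df["imd_norm"].to_numpy(dtype=float)
    if spec.cohort_indicator:
        cols["cohort[Year6]"] = (df["cohort"] == "Year6").to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    names = list(cols)

    # rank check: name the aliased column from the QR diagonal
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 100
    bad = np.flatnonzero(diag <= tol)
    if bad.size:
        raise RankDeficientError(
            f"fixed-effect design is rank deficient: column {names[bad[0]]!r} "
            "is aliased")

    factors = []
    school_codes, school_levels = pd.factorize(df["school_id"], sort=True)
    factors.append(("school", school_codes, np.asarray(school_levels)))
    if spec.include_neighbourhood:
        lsoa_codes, lsoa_levels = pd.factorize(df["lsoa_id"], sort=True)
        factors.append(("neighbourhood", lsoa_codes, np.asarray(lsoa_levels)))
    for name, codes, levels in factors:
        if len(levels) < 2:
            raise ModelError(f"random factor {name!r} needs >= 2 levels")
    return df, y, X, names, factors, n_dropped


class _REMLProblem:
    """Profiled REML objective over log variance ratios, via cross-products."""

    def __init__(self, y, X, factors):
        n = len(y)
        self.n, self.p = n, X.shape[1]
        self.block_names = [f[0] for f in factors]
        self.block_sizes = [len(f[2]) for f in factors]
        Zs = [sparse.csr_matrix(
                (np.ones(n), (np.arange(n), codes)),
                shape=(n, len(levels)))
              for _, codes, levels in factors]
        Z = sparse.hstack(Zs, format="csr")
        self.q = Z.shape[1]
        self.ZtZ = np.asarray(Z.T.dot(Z).todense())
        self.XtZ = np.asarray(Z.T.dot(X)).T          # p x q
        self.Zty = Z.T.dot(y)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.path = []

    def _gamma_inv_diag(self, gammas):
        return np.concatenate([
            np.full(m, 1.0 / g) for m, g in zip(self.block_sizes, gammas)])

    def neg2_remll(self, log_gammas):
        gammas = np.exp(np.clip(np.asarray(log_gammas, dtype=float), -34.0, 10.0))
        M = self.ZtZ + np.diag(self._gamma_inv_diag(gammas))
        try:
            cf = linalg.cho_factor(M, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        logdet_M = 2.0 * np.sum(np.log(np.diag(cf[0])))
        logdet_G = float(sum(m * np.log(g)
                             for m, g in zip(self.block_sizes, gammas)))
        A = linalg.cho_solve(cf, self.XtZ.T, check_finite=False)   # q x p
        b = linalg.cho_solve(cf, self.Zty, check_finite=False)
        Sxx = self.XtX - self.XtZ @ A
        Sxy = self.Xty - self.XtZ @ b
        try:
            cf_x = linalg.cho_factor(Sxx, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        logdet_Sxx = 2.0 * np.sum(np.log(np.diag(cf_x[0])))
        beta = linalg.cho_solve(cf_x, Sxy, check_finite=False)
        quad = self.yty - float(self.Zty @ b) - float(Sxy @ beta)
        dof = self.n - self.p
        if quad <= 0:
            return np.inf
        sigma2 = quad / dof
        val = (dof * (1.0 + np.log(2.0 * np.pi) + np.log(sigma2))
               + logdet_M + logdet_G + logdet_Sxx)
        self.path.append(float(val))
        return val

    def solve_at(self, gammas):
        """Everything needed for reporting at fixed variance ratios."""
        active = [g > 0 for g in gammas]
        M = self.ZtZ + np.diag(np.concatenate([
            np.full(m, 1.0 / g if g > 0 else 1e12)
            for m, g in zip(self.block_sizes, gammas)]))
        # exact-zero components: treat as infinite precision (BLUP -> 0)
        C = np.block([[self.XtX, self.XtZ], [self.XtZ.T, M]])
        rhs = np.concatenate([self.Xty, self.Zty])
        Cinv = linalg.inv(C)
        sol = Cinv @ rhs
        beta = sol[:self.p]
        u = sol[self.p:]
        quad = self.yty - float(rhs @ sol)
        sigma2 = quad / (self.n - self.p)
        cov = sigma2 * Cinv
        beta_se = np.sqrt(np.diag(cov)[:self.p])
        u_var = np.diag(cov)[self.p:].copy()
        # split u / se by block
        out = {}
        pos = 0
        for name, m, g, act in zip(self.block_names, self.block_sizes,
                                   gammas, active):
            ub = u[pos:pos + m]
            sb = np.sqrt(np.maximum(u_var[pos:pos + m], 0.0))
            if not act:
                ub = np.zeros(m)
                sb = np.zeros(m)
            out[name] = (ub, sb)
            pos += m
        return beta, beta_se, out, sigma2


def _newton_polish(f, x0: np.ndarray, h: float = 1e-4,
                   max_steps: int = 3) -> np.ndarray:
    """Central-difference Newton refinement of a smooth local minimum."""
    x = np.asarray(x0, dtype=float)
    d = x.size
    fx = f(x)
    for _ in range(max_steps):
        grad = np.empty(d)
        hess = np.empty((d, d))
        fp = np.empty(d)
        fm = np.empty(d)
        for i in range(d):
            e = np.zeros(d)
            e[i] = h
            fp[i], fm[i] = f(x + e), f(x - e)
            grad[i] = (fp[i] - fm[i]) / (2 * h)
            hess[i, i] = (fp[i] - 2 * fx + fm[i]) / h ** 2
        for i in range(d):
            for j in range(i + 1, d):
                ei = np.zeros(d); ei[i] = h
                ej = np.zeros(d); ej[j] = h
                fpp = f(x + ei + ej)
                hess[i, j] = hess[j, i] = (
                    fpp - fp[i] - fp[j] + fx) / h ** 2
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        eig_ok = np.all(np.linalg.eigvalsh(hess) > 0)
        if not eig_ok or not np.all(np.isfinite(step)):
            break
        step = np.clip(step, -0.5, 0.5)
        x_new = x - step
        f_new = f(x_new)
        if not np.isfinite(f_new) or f_new > fx + 1e-6:
            break
        x, fx = x_new, f_new
        if np.max(np.abs(step)) < 1e-9:
            break
    return x


def fit_reml(records: pd.DataFrame, spec: ModelSpec | None = None, *,
             response: str = "bmi_sds", max_iter: int = 500,
             tol: float = 1e-10) -> FittedModel:
    """Fit the cross-classified model by REML.

    ``records`` must carry the response column (default ``bmi_sds``),
    ``school_id`` and, as required by ``spec``, ``lsoa_id``,
    ``ethnicity``, ``imd_norm`` and ``cohort``.  Variance components are
    constrained non-negative; ratios collapsing below 1e-9 are pinned to
    an exact zero and the factor refitted out of the model.
    """
    if spec is None:
        spec = ModelSpec()
    df, y, X, names, factors, n_dropped = _design_matrices(records, spec, response)
    prob = _REMLProblem(y, X, factors)
    n_fac = len(factors)

    nm_options = {"xatol": 1e-6, "fatol": max(tol, 1e-8),
                  "maxiter": max_iter * 20, "maxfev": max_iter * 20}
    x0 = np.full(n_fac, np.log(0.05))
    res = optimize.minimize(
        prob.neg2_remll, x0, method="Nelder-Mead", options=nm_options)
    gammas = np.exp(np.clip(res.x, -34.0, 10.0))
    converged = bool(res.success) and np.isfinite(res.fun)

    # boundary handling: refit with near-zero components dropped
    fixed_zero = gammas <= _BOUNDARY_GAMMA
    if fixed_zero.any() and not fixed_zero.all():
        free = ~fixed_zero

        def obj_sub(lg):
            full = np.full(n_fac, -np.inf)
            full[free] = lg
            return prob.neg2_remll(full)

        res2 = optimize.minimize(
            obj_sub, np.log(gammas[free]), method="Nelder-Mead",
            options=nm_options)
        if res2.fun <= res.fun + 1e-9:
            gammas = np.where(free, 0.0, 0.0)
            gammas[free] = np.exp(np.clip(res2.x, -34.0, 10.0))
            converged = bool(res2.success) and np.isfinite(res2.fun)
            res = res2
    gammas = np.where(gammas <= _BOUNDARY_GAMMA, 0.0, gammas)

    # Newton polish on the active ratios: the simplex stalls at the
    # objective's rounding noise (~1e-8 in log-gamma); a few
    # finite-difference Newton steps average that noise out.
    active = gammas > 0
    if active.any():
        lg = np.log(gammas[active])

        def f_sub(v):
            full = np.full(n_fac, -np.inf)
            full[active] = v
            return prob.neg2_remll(full)

        lg = _newton_polish(f_sub, lg)
        gammas = gammas.copy()
        gammas[active] = np.exp(lg)

    beta, beta_se, u_blocks, sigma2 = prob.solve_at(gammas)
    loglik = -0.5 * prob.neg2_remll(np.log(np.where(gammas > 0, gammas, 1e-15)))
    if not np.isfinite(loglik):
        loglik = -0.5 * float(res.fun)

    comp_map = dict(zip(prob.block_names, gammas * sigma2))
    components = VarianceComponents(
        var_school=float(comp_map.get("school", 0.0)),
        var_neighbourhood=float(comp_map.get("neighbourhood", 0.0)),
        var_residual=float(sigma2),
    )

    beta_df = pd.DataFrame(
        {"estimate": beta, "se": beta_se,
         "ci_lower": beta - _Z975 * beta_se,
         "ci_upper": beta + _Z975 * beta_se},
        index=pd.Index(names, name="term"))

    blups = {}
    for (name, codes, levels), _ in zip(factors, range(n_fac)):
        ub, sb = u_blocks[name]
        counts = np.bincount(codes, minlength=len(levels))
        blups[name] = pd.DataFrame(
            {"residual": ub, "se": sb, "n_pupils": counts},
            index=pd.Index(levels, name="level"))

    n_lsoas = len(blups["neighbourhood"]) if "neighbourhood" in blups else (
        df["lsoa_id"].nunique() if "lsoa_id" in df.columns else 0)
    fit = FittedModel(
        spec=spec, beta=beta_df, components=components,
        reml_loglik=float(loglik), blups=blups, converged=converged,
        n_obs=len(df), n_schools=len(blups["school"]), n_lsoas=int(n_lsoas),
        n_dropped=n_dropped, objective_path=list(np.minimum.accumulate(prob.path)))
    if not converged:
        logger.warning("fit_reml did not converge: %s", res.message)
    return fit


def icc(fit: FittedModel) -> dict[str, float]:
    """Per-factor intraclass correlations from a *null* (intercept-only) model.

    ICC_f = var_f / (var_school + var_neighbourhood + var_residual).
    Raises on adjusted models: ICC decomposition is defined for the
    unconditional variance only.
    """
    if not fit.spec.is_null:
        raise ModelError("ICCs are defined for null (intercept-only) models; "
                         "refit with ModelSpec(adjusted=False)")
    total = fit.components.total
    out = {"school": fit.components.var_school / total}
    if "neighbourhood" in fit.blups:
        out["neighbourhood"] = fit.components.var_neighbourhood / total
    return out


def school_blups(fit: FittedModel) -> pd.DataFrame:
    """Per-school expected residuals (BLUPs) with prediction SEs.

    Columns ``school_id, residual, se, n_pupils``; refuses a fit that
    did not converge.
    """
    if not fit.converged:
        raise NotConvergedError("refusing BLUPs from a non-converged fit")
    if "school" not in fit.blups:
        raise ModelError("fit has no school factor")
    out = fit.blups["school"].copy()
    out.index.name = "school_id"
    return out


def raw_school_residuals(records: pd.DataFrame, fit: FittedModel, *,
                         response: str = "bmi_sds") -> pd.Series:
    """Unshrunken alternative to BLUPs: per-school mean of y - X beta-hat."""
    df, y, X, _, factors, _ = _design_matrices(records, fit.spec, response)
    resid = y - X @ fit.beta["estimate"].to_numpy()
    codes, levels = None, None
    for name, c, lv in factors:
        if name == "school":
            codes, levels = c, lv
    sums = np.bincount(codes, weights=resid, minlength=len(levels))
    counts = np.bincount(codes, minlength=len(levels))
    return pd.Series(sums / counts, index=pd.Index(levels, name="school_id"))
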