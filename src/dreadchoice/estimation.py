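"""Maximum-likelihood fitting of value models to choice data.

Parameters are estimated by Nelder-Mead simplex search wrapped in a random
multistart overlay.  Box bounds are enforced by transformation: each
parameter is mapped onto the open bounded interval through a logistic
bijection, so the simplex explores an unconstrained space.  An exhaustive
log-scale grid search (with a local 10x-resolution refinement) provides an
independent verification of the simplex optimum for the three-parameter
models, and central-difference curvature diagnostics confirm that the
returned point is a local maximum of the likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .likelihood import ChoiceDataset, log_choice_probability
from .valuation import (
    PARAM_BOUNDS,
    ModelParams,
    ModelSpec,
    WeibullUtilityParams,
    delay_cost_mask,
    utility,
    value_difference_core,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "bound_transform",
    "bound_transform_inverse",
    "fit_subject",
    "grid_search",
    "verify_curvature",
    "central_second_partials",
]


@dataclass(frozen=True)
class FitConfig:
    """Multistart optimizer configuration.

    Desk-scale defaults (20 starts, 1 restart) keep a full model-comparison
    run fast; ``FitConfig.exhaustive()`` restores the exhaustive procedure
    of 100 uniform starts repeated 1000 times.
    """

    n_starts: int = 20
    n_restarts: int = 1
    presample_factor: int = 40  # cheap random points screened per NM start
    xatol: float = 1e-6
    fatol: float = 1e-6
    maxiter: int | None = None
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    check_curvature: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_starts < 1 or self.n_restarts < 1:
            raise ValueError("n_starts and n_restarts must be >= 1")

    @classmethod
    def exhaustive(cls, **kw) -> "FitConfig":
        return cls(n_starts=100, n_restarts=1000, **kw)

    def bounds_for(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, PARAM_BOUNDS[name])


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    spec: ModelSpec
    params: ModelParams
    loglik: float
    n_obs: int
    n_starts: int
    converged: bool
    params_at_bound: tuple[str, ...] = ()
    curvature_positive: bool | None = None
    grid_delta: float | None = None
    method: str = "simplex"
    subject_id: str = ""
    frame: str = ""

    @property
    def k(self) -> int:
        return self.spec.k

    def free_values(self) -> dict[str, float]:
        return {p: getattr(self.params, p) for p in self.spec.free_params}


# ---------------------------------------------------------------------------
# bound transformation


def bound_transform(theta, names, bounds: dict | None = None) -> np.ndarray:
    """Map unbounded values onto the open parameter box (logistic per axis)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if not np.all(np.isfinite(theta)):
        raise ValueError("bound_transform requires finite input")
    out = np.empty_like(theta)
    for i, name in enumerate(names):
        lo, hi = (bounds or PARAM_BOUNDS).get(name, PARAM_BOUNDS[name])
        out[i] = lo + (hi - lo) * expit(theta[i])
    return out


def bound_transform_inverse(values, names, bounds: dict | None = None) -> np.ndarray:
    """Inverse map; raises on values at (or outside) a bound."""
    values = np.atleast_1d(np.asarray(values, dtype=float))
    out = np.empty_like(values)
    for i, name in enumerate(names):
        lo, hi = (bounds or PARAM_BOUNDS).get(name, PARAM_BOUNDS[name])
        z = (values[i] - lo) / (hi - lo)
        if not (0.0 < z < 1.0):
            raise ValueError(f"{name}={values[i]} is on or outside [{lo}, {hi}]")
        out[i] = logit(z)
    return out


# ---------------------------------------------------------------------------
# likelihood plumbing


def _neg_loglik_factory(data: ChoiceDataset, spec: ModelSpec,
                        wparams: WeibullUtilityParams | None):
    """Fast negative log-likelihood over the free-parameter vector (natural units).

    Specialized per model with all data-dependent quantities hoisted out of
    the closure; this sits inside every Nelder-Mead evaluation, so each call
    is a handful of vector ops on the trial arrays.
    """
    u_s = np.asarray(utility(data.x_sooner, spec, wparams), dtype=float)
    u_l = np.asarray(utility(data.x_later, spec, wparams), dtype=float)
    t_s = np.asarray(data.t_sooner, dtype=float)
    t_l = np.asarray(data.t_later, dtype=float)
    sign = np.where(data.choice == 1, 1.0, -1.0)
    m = spec.model_id

    def score(dv, beta):
        z = (beta * sign) * dv
        return float(np.logaddexp(0.0, -z).sum())

    if m == "null":
        sdv = sign * -(u_l - u_s)

        def negll(theta):
            return float(np.logaddexp(0.0, -theta[0] * sdv).sum())

        return negll

    if m == "exp_discount":
        def negll(theta):
            beta, gp = theta
            return score(gp**t_s * u_s - gp**t_l * u_l, beta)

        return negll

    if m == "fixed_delay_cost":
        mask = delay_cost_mask(t_s, t_l, spec.delay_cost_convention)

        def negll(theta):
            beta, gp, A = theta
            return score(gp**t_s * u_s - gp**t_l * u_l + A * mask, beta)

        return negll

    if m == "constant_dread":
        tu_s, tu_l = t_s * u_s, t_l * u_l

        def negll(theta):
            beta, gp, alpha = theta
            dv = gp**t_s * u_s - gp**t_l * u_l - alpha * (tu_l - tu_s)
            return score(dv, beta)

        return negll

    if m == "undiscounted_dread":
        def negll(theta):
            beta, gp, alpha = theta
            pw_s, pw_l = gp**t_s, gp**t_l
            if gp >= 1.0 - 1e-12:
                S_s, S_l = t_s, t_l
            else:
                f = gp / (1.0 - gp)
                S_s, S_l = f * (1.0 - pw_s), f * (1.0 - pw_l)
            dv = (pw_s * u_s - pw_l * u_l) - alpha * (u_l * S_l - u_s * S_s)
            return score(dv, beta)

        return negll

    if m == "restricted_dread":
        def negll(theta):
            beta, gp, alpha = theta
            dv = (gp**t_s * u_s * (1.0 + alpha * t_s)
                  - gp**t_l * u_l * (1.0 + alpha * t_l))
            return score(dv, beta)

        return negll

    if m == "general_dread":
        def negll(theta):
            beta, gp, gd, alpha = theta
            pw_s, pw_l = gp**t_s, gp**t_l
            if abs(gd - gp) < 1e-9:
                S_s, S_l = t_s * pw_s, t_l * pw_l
            else:
                f = gp / (gd - gp)
                S_s, S_l = f * (gd**t_s - pw_s), f * (gd**t_l - pw_l)
            dv = (pw_s * u_s - pw_l * u_l) - alpha * (u_l * S_l - u_s * S_s)
            return score(dv, beta)

        return negll

    raise ValueError(f"unknown model_id {m!r}")


def _grid_loglik(data: ChoiceDataset, spec: ModelSpec, theta: np.ndarray,
                 wparams: WeibullUtilityParams | None,
                 chunk: int = 4096) -> np.ndarray:
    """Log-likelihood at each row of an (G, k) natural-unit parameter grid."""
    u_s = np.asarray(utility(data.x_sooner, spec, wparams), dtype=float)
    u_l = np.asarray(utility(data.x_later, spec, wparams), dtype=float)
    t_s, t_l = data.t_sooner, data.t_later
    sign = np.where(data.choice == 1, 1.0, -1.0)
    mask = (delay_cost_mask(t_s, t_l, spec.delay_cost_convention)
            if spec.model_id == "fixed_delay_cost" else 0.0)
    names = spec.free_params
    out = np.empty(len(theta))
    for a in range(0, len(theta), chunk):
        block = theta[a:a + chunk]
        cols = {n: block[:, i][:, None] for i, n in enumerate(names)}
        dv = value_difference_core(
            u_s, u_l, t_s, t_l, spec.model_id,
            cols.get("gamma_p", 1.0), cols.get("gamma_d", 1.0),
            cols.get("alpha", 0.0), cols.get("A", 0.0), mask)
        out[a:a + chunk] = np.sum(
            log_choice_probability(sign * dv, cols["beta"]), axis=1)
    return out


def _draw_starts(names, config: FitConfig, rng: np.random.Generator,
                 n: int) -> np.ndarray:
    """Random candidate points in natural units.

    All parameters draw uniformly between their bounds except beta, drawn
    log-uniformly: its bound spans four orders of magnitude and uniform draws
    would almost never land in the behaviorally relevant decade.
    """
    cols = []
    for name in names:
        lo, hi = config.bounds_for(name)
        if name == "beta":
            lo_eff = max(lo, 1e-5 * hi)
            cols.append(np.exp(rng.uniform(np.log(lo_eff), np.log(hi), n)))
        else:
            cols.append(rng.uniform(lo, hi, n))
    starts = np.column_stack(cols)
    # keep starts strictly interior so the inverse transform is defined
    for i, name in enumerate(names):
        lo, hi = config.bounds_for(name)
        eps = 1e-9 * (hi - lo)
        starts[:, i] = np.clip(starts[:, i], lo + eps, hi - eps)
    return starts


def _multistart_minimize(negll, names, config: FitConfig,
                         rng: np.random.Generator,
                         extra_starts: list[np.ndarray] | None = None):
    """Best-of multistart Nelder-Mead in the unbounded transformed space.

    ``extra_starts`` are natural-unit warm starts always included in the
    start set (used e.g. to seed restricted fits from nested solutions).
    Returns (best natural-unit vector, best loglik, converged flag,
    params-at-bound names).
    """
    bounds = {n: config.bounds_for(n) for n in names}
    k = len(names)
    lo_arr = np.array([bounds[n][0] for n in names])
    span_arr = np.array([bounds[n][1] - bounds[n][0] for n in names])

    def negll_unbounded(theta_unb):
        return negll(lo_arr + span_arr * expit(theta_unb))

    best_val = np.inf
    best_theta = None
    best_conv = False
    n_fail = 0
    for _ in range(config.n_restarts):
        # screen a cheap pool of random points; half the NM starts come from
        # the best screened points, half stay purely random for diversity
        pool = _draw_starts(names, config, rng,
                            max(config.n_starts * config.presample_factor,
                                config.n_starts))
        pool_vals = np.array([negll(p) for p in pool])
        pool_vals[~np.isfinite(pool_vals)] = np.inf
        n_best = (config.n_starts + 1) // 2
        order = np.argsort(pool_vals)
        idx = list(order[:n_best])
        idx.extend(rng.choice(len(pool), size=config.n_starts - n_best,
                              replace=False))
        starts = list(pool[np.array(idx, dtype=int)])
        for w in extra_starts or []:
            w = np.asarray(w, dtype=float)
            eps = 1e-9 * span_arr
            starts.append(np.clip(w, lo_arr + eps, lo_arr + span_arr - eps))
        for s in starts:
            theta0 = bound_transform_inverse(s, names, bounds)
            try:
                res = minimize(
                    negll_unbounded, theta0, method="Nelder-Mead",
                    options={"xatol": config.xatol, "fatol": config.fatol,
                             "maxiter": config.maxiter or 400 * k,
                             "maxfev": config.maxiter or 400 * k})
            except Exception:
                n_fail += 1
                continue
            if not np.isfinite(res.fun):
                n_fail += 1
                continue
            logger.debug("start %s -> negll %.6f (%s)",
                         np.array2string(s, precision=4), res.fun,
                         "converged" if res.success else "max-iter")
            if res.fun < best_val:
                best_val = res.fun
                best_theta = res.x
                best_conv = bool(res.success)
    if best_theta is None:
        raise RuntimeError(
            f"all {config.n_starts * config.n_restarts} starts failed "
            f"({n_fail} evaluation failures)")
    nat = bound_transform(best_theta, names, bounds)
    at_bound = tuple(
        n for n, v in zip(names, nat)
        if min(v - bounds[n][0], bounds[n][1] - v) < 1e-6 * (bounds[n][1] - bounds[n][0])
    )
    return nat, -best_val, best_conv, at_bound


def fit_subject(data: ChoiceDataset, spec: ModelSpec,
                config: FitConfig | None = None, seed: int | None = None,
                wparams: WeibullUtilityParams | None = None) -> FitResult:
    """Maximum-likelihood fit of one model to one subject's choices."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    negll = _neg_loglik_factory(data, spec, wparams)
    names = spec.free_params
    nat, loglik, converged, at_bound = _multistart_minimize(negll, names, config, rng)
    params = spec.params_from_vector(nat)
    curv = None
    if config.check_curvature and not at_bound:
        diag = verify_curvature(data, spec, params, wparams=wparams)
        curv = diag["all_positive"]
    return FitResult(spec=spec, params=params, loglik=loglik, n_obs=len(data),
                     n_starts=config.n_starts * config.n_restarts,
                     converged=converged, params_at_bound=at_bound,
                     curvature_positive=curv, subject_id=data.subject_id,
                     frame=data.frame)


# ---------------------------------------------------------------------------
# grid search


def _log_grid(lo: float, hi: float, resolution: int) -> np.ndarray:
    """Log-scale grid between bounds; a zero endpoint is replaced by a small
    epsilon (1e-5 of the non-zero bound's magnitude) since a log grid cannot
    include zero.  A negative box (the delay cost A) is gridded as a negated
    log scale."""
    if hi <= 0.0:  # e.g. A in [-50, 0]
        return -_log_grid(-hi, -lo, resolution)[::-1]
    lo_eff = lo if lo > 0 else 1e-5 * hi
    return np.geomspace(lo_eff, hi, resolution)


def grid_search(data: ChoiceDataset, spec: ModelSpec, resolution: int = 25,
                refine: bool = True, wparams: WeibullUtilityParams | None = None,
                simplex_result: FitResult | None = None,
                config: FitConfig | None = None,
                allow_large: bool = False) -> FitResult:
    """Exhaustive log-scale grid evaluation of the likelihood surface.

    Mirrors the verification used alongside simplex optimization: sample each
    free parameter on a log scale between its bounds, evaluate every grid
    point (chunked, so memory stays bounded), then optionally refine at 10x
    resolution around the grid optimum and around a supplied simplex optimum.
    """
    config = config or FitConfig()
    names = spec.free_params
    if len(names) > 3 and not allow_large:
        raise ValueError(
            f"grid search is restricted to <= 3 free parameters "
            f"({spec.model_id} has {len(names)}); pass allow_large=True to override")

    axes = [_log_grid(*config.bounds_for(n), resolution) for n in names]
    mesh = np.meshgrid(*axes, indexing="ij")
    theta = np.column_stack([m.ravel() for m in mesh])
    ll = _grid_loglik(data, spec, theta, wparams)
    best_idx = int(np.argmax(ll))
    best_theta, best_ll = theta[best_idx], float(ll[best_idx])

    if refine:
        coarse_ratios = []
        for i, n in enumerate(names):
            ax = axes[i]
            mags = np.abs(ax)
            mags = mags[mags > 0]
            coarse_ratios.append(
                (mags.max() / mags.min()) ** (1.0 / (len(ax) - 1))
                if len(ax) > 1 else 2.0)

        def local_pass(center, ratios):
            local_axes = []
            for i, n in enumerate(names):
                ax = axes[i]
                lo_b, hi_b = config.bounds_for(n)
                neg = hi_b <= 0  # negative box (the delay cost A)
                mags = np.abs(ax[::-1]) if neg else ax
                c = max(abs(center[i]), abs(mags[0]) * 1e-3)
                lo = max(abs(mags[0]) / ratios[i], c / ratios[i])
                hi = min(abs(mags[-1]), c * ratios[i])
                local = np.geomspace(lo, max(hi, lo * (1 + 1e-12)), 21)
                local_axes.append(-local[::-1] if neg else local)
            lm = np.meshgrid(*local_axes, indexing="ij")
            ltheta = np.column_stack([m.ravel() for m in lm])
            lll = _grid_loglik(data, spec, ltheta, wparams)
            li = int(np.argmax(lll))
            return float(lll[li]), ltheta[li]

        centers = [best_theta]
        if simplex_result is not None:
            centers.append(np.array(
                [getattr(simplex_result.params, n) for n in names]))
        for center in centers:
            ll1, th1 = local_pass(center, coarse_ratios)
            # second pass at the refined step size around the local optimum
            fine_ratios = [r ** 0.1 for r in coarse_ratios]
            ll2, th2 = local_pass(th1, fine_ratios)
            for ll_c, th_c in ((ll1, th1), (ll2, th2)):
                if ll_c > best_ll:
                    best_ll, best_theta = ll_c, th_c

    params = spec.params_from_vector(best_theta)
    delta = (best_ll - simplex_result.loglik) if simplex_result is not None else None
    return FitResult(spec=spec, params=params, loglik=best_ll, n_obs=len(data),
                     n_starts=len(theta), converged=True, method="grid",
                     grid_delta=delta, subject_id=data.subject_id,
                     frame=data.frame)


# ---------------------------------------------------------------------------
# curvature diagnostics


def central_second_partials(f, theta, steps) -> np.ndarray:
    """Diagonal second partial derivatives of f by central differences."""
    theta = np.asarray(theta, dtype=float)
    steps = np.broadcast_to(np.asarray(steps, dtype=float), theta.shape)
    f0 = f(theta)
    out = np.empty_like(theta)
    for i, h in enumerate(steps):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        out[i] = (f(tp) - 2.0 * f0 + f(tm)) / h**2
    return out


def verify_curvature(data: ChoiceDataset, spec: ModelSpec, params: ModelParams,
                     wparams: WeibullUtilityParams | None = None,
                     rel_step: float = 1e-4,
                     config: FitConfig | None = None) -> dict:
    """Central-difference second partials of -loglik at a candidate optimum.

    At a proper local maximum of the likelihood every diagonal second partial
    of the negative log-likelihood is positive.  Parameters on a bound make
    the test inapplicable there (flagged, not evaluated).
    """
    config = config or FitConfig()
    negll = _neg_loglik_factory(data, spec, wparams)
    names = spec.free_params
    theta = np.array([getattr(params, n) for n in names], dtype=float)
    second: dict[str, float | None] = {}
    applicable = True
    for i, n in enumerate(names):
        lo, hi = config.bounds_for(n)
        h = rel_step * (hi - lo)
        if theta[i] - h <= lo or theta[i] + h >= hi:
            second[n] = None
            applicable = False
            continue
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        second[n] = float((negll(tp) - 2.0 * negll(theta) + negll(tm)) / h**2)
    vals = [v for v in second.values() if v is not None]
    return {
        "second_partials": second,
        "all_positive": all(v > 0 for v in vals) if (applicable and vals) else None,
        "applicable": applicable,
    }
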