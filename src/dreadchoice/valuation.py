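"""Value models for delayed painful outcomes.

Every model assigns a prospective option (pain magnitude ``x`` at integer
delay ``T``) a non-positive total value

    V(x, T) = -( gamma_P**T * u(x) + D(x, T) )

where ``u`` is the disutility of the pain itself (linear by default, or a
concave three-parameter Weibull estimated from visual-analogue ratings),
``gamma_P`` exponentially discounts the pain, and ``D`` is the accumulated
dread over the prospective moments ``t = 0 .. T-1``.  Instantaneous dread at
moment ``t`` is the discounted expectation of the pain, ``gamma_P**(T-t) *
u(x)``, itself discounted back to the present by ``gamma_D**t`` and weighted
by ``alpha``:

    D(x, T) = alpha * u(x) * sum_{t=0}^{T-1} gamma_D**t * gamma_P**(T-t)

The model family nests:

=================== =============================== =====================
model_id            dread term D(x, T)              free parameters
=================== =============================== =====================
null                0 (and gamma_P = 1)             beta
exp_discount        0                               beta, gamma_P
fixed_delay_cost    0; constant cost A on the       beta, gamma_P, A
                    (strictly) later option
constant_dread      alpha * T * u(x)                beta, gamma_P, alpha
undiscounted_dread  gamma_D = 1                     beta, gamma_P, alpha
restricted_dread    gamma_D = gamma_P               beta, gamma_P, alpha
                    => alpha * T * gamma_P**T * u
general_dread       free gamma_D                    beta, gamma_P,
                                                    gamma_D, alpha
=================== =============================== =====================

Undiscounted dread saturates with delay (aversion grows at a decreasing
rate); restricted/general dread with gamma_D < 1 peaks at an intermediate
delay, producing reversing time preference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .designs import ChoicePair

__all__ = [
    "ModelParams",
    "ModelSpec",
    "WeibullUtilityParams",
    "MODEL_IDS",
    "FREE_PARAMS",
    "PARAM_BOUNDS",
    "utility",
    "dread",
    "total_value",
    "pair_value_difference",
    "value_difference_core",
    "delay_cost_mask",
    "fit_weibull_utility",
    "weibull_utility",
]

#: Fitting bounds for each parameter (the optimizer's box constraints).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "beta": (0.0, 1000.0),
    "gamma_p": (0.0, 1.0),
    "gamma_d": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "A": (-50.0, 0.0),
}

#: Free parameters per model, in canonical fitting order.
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "null": ("beta",),
    "exp_discount": ("beta", "gamma_p"),
    "fixed_delay_cost": ("beta", "gamma_p", "A"),
    "constant_dread": ("beta", "gamma_p", "alpha"),
    "undiscounted_dread": ("beta", "gamma_p", "alpha"),
    "restricted_dread": ("beta", "gamma_p", "alpha"),
    "general_dread": ("beta", "gamma_p", "gamma_d", "alpha"),
}

MODEL_IDS = tuple(FREE_PARAMS)


@dataclass(frozen=True)
class ModelParams:
    """Parameter values for one value model.

    beta: softmax inverse temperature (>= 0).
    gamma_p: per-step discount factor for pain, in [0, 1].
    gamma_d: per-step discount factor applied to dread itself, in [0, 1].
    alpha: dread weight, in [0, 1].
    A: fixed delay cost attached to the later option, in [-50, 0].
    """

    beta: float
    gamma_p: float = 1.0
    gamma_d: float = 1.0
    alpha: float = 0.0
    A: float = 0.0

    def __post_init__(self):
        for name, (lo, hi) in PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PARAM_BOUNDS}


@dataclass(frozen=True)
class WeibullUtilityParams:
    """Concave Weibull disutility: u(x) = r_max * (1 - exp(-(x/scale)**shape))."""

    r_max: float
    scale: float
    shape: float

    def __post_init__(self):
        for name in ("r_max", "scale", "shape"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")


@dataclass(frozen=True)
class ModelSpec:
    """A value model identity plus its utility kind.

    delay_cost_convention (fixed_delay_cost only): "relative" attaches the
    constant A to the strictly later option of each pair (identifiable when
    both options are delayed, as in Exp 1); "absolute" attaches it to any
    option with T > 0 (natural for Exp 2, where the sooner option is today).
    """

    model_id: str
    utility_kind: str = "linear"
    delay_cost_convention: str = "relative"

    def __post_init__(self):
        if self.model_id not in FREE_PARAMS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.utility_kind not in ("linear", "weibull"):
            raise ValueError(f"unknown utility_kind {self.utility_kind!r}")
        if self.delay_cost_convention not in ("relative", "absolute"):
            raise ValueError("delay_cost_convention must be 'relative' or 'absolute'")

    @property
    def free_params(self) -> tuple[str, ...]:
        return FREE_PARAMS[self.model_id]

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.free_params)

    def params_from_vector(self, theta: np.ndarray) -> ModelParams:
        """Build full ModelParams from a free-parameter vector."""
        kw = dict(zip(self.free_params, np.asarray(theta, dtype=float)))
        return ModelParams(**kw)


def weibull_utility(x, wparams: WeibullUtilityParams):
    x = np.asarray(x, dtype=float)
    return wparams.r_max * -np.expm1(-((x / wparams.scale) ** wparams.shape))


def utility(magnitude, spec: ModelSpec, wparams: WeibullUtilityParams | None = None):
    """Disutility u(x) of a pain magnitude: linear identity or Weibull."""
    x = np.asarray(magnitude, dtype=float)
    if np.any(x < 0):
        raise ValueError("magnitude must be non-negative")
    if spec.utility_kind == "linear":
        return x
    if wparams is None:
        raise ValueError("Weibull utility requires wparams")
    return weibull_utility(x, wparams)


def _dread_sum(gamma_p, gamma_d, T):
    """sum_{t=0}^{T-1} gamma_d**t * gamma_p**(T-t), vectorized and stable.

    Closed form gamma_p * (gamma_d**T - gamma_p**T) / (gamma_d - gamma_p),
    with the T * gamma**T limit on the gamma_d ~= gamma_p diagonal.
    """
    gp = np.asarray(gamma_p, dtype=float)
    gd = np.asarray(gamma_d, dtype=float)
    T = np.asarray(T)
    diff = gd - gp
    near = np.abs(diff) < 1e-9
    safe = np.where(near, 1.0, diff)
    with np.errstate(invalid="ignore"):
        closed = gp * (gd**T - gp**T) / safe
    limit = T * gp**T
    return np.where(near, limit, closed)


def dread(magnitude, delay, params: ModelParams, spec: ModelSpec,
          wparams: WeibullUtilityParams | None = None):
    """Total accumulated dread D(x, T) for one model (0 when T = 0)."""
    T = np.asarray(delay)
    if np.any(T < 0):
        raise ValueError("delay must be non-negative")
    u = utility(magnitude, spec, wparams)
    m = spec.model_id
    if m in ("null", "exp_discount", "fixed_delay_cost"):
        return np.zeros(np.broadcast(u, T).shape) if (np.ndim(u) or np.ndim(T)) else 0.0
    if m == "constant_dread":
        return params.alpha * T * u
    if m == "undiscounted_dread":
        return params.alpha * u * _dread_sum(params.gamma_p, 1.0, T)
    if m == "restricted_dread":
        return params.alpha * u * _dread_sum(params.gamma_p, params.gamma_p, T)
    if m == "general_dread":
        return params.alpha * u * _dread_sum(params.gamma_p, params.gamma_d, T)
    raise ValueError(f"unknown model_id {m!r}")


def total_value(pair: ChoicePair, which: str, params: ModelParams,
                spec: ModelSpec, wparams: WeibullUtilityParams | None = None) -> float:
    """Signed total value V (<= 0) of one option of a pair."""
    if which not in ("sooner", "later"):
        raise ValueError("which must be 'sooner' or 'later'")
    opt = pair.sooner if which == "sooner" else pair.later
    u = float(utility(opt.magnitude, spec, wparams))
    T = opt.delay
    if spec.model_id == "null":
        return -u
    v = -(params.gamma_p**T * u)
    if spec.model_id == "fixed_delay_cost":
        if spec.delay_cost_convention == "relative":
            is_later = which == "later" and pair.delay_difference > 0
        else:
            is_later = T > 0
        return v + (params.A if is_later else 0.0)
    return v - float(dread(opt.magnitude, T, params, spec, wparams))


def delay_cost_mask(t_s, t_l, convention: str):
    """Signed indicator by which the fixed delay cost A enters V_l - V_s."""
    t_s = np.asarray(t_s)
    t_l = np.asarray(t_l)
    if convention == "relative":
        return (t_l > t_s).astype(float)
    return (t_l > 0).astype(float) - (t_s > 0).astype(float)


def value_difference_core(u_s, u_l, t_s, t_l, model_id: str,
                          gamma_p, gamma_d, alpha, A, later_mask):
    """V(later) - V(sooner) from precomputed disutilities; fully broadcastable.

    Parameters may be scalars or arrays shaped to broadcast against the trial
    axis (e.g. a (G, 1) parameter grid against (n,) trials), which is how the
    exhaustive grid search evaluates the likelihood surface in bulk.
    """
    if model_id == "null":
        return -(u_l - u_s)
    dv = -(gamma_p**t_l * u_l - gamma_p**t_s * u_s)
    if model_id == "exp_discount":
        return dv
    if model_id == "fixed_delay_cost":
        return dv + A * later_mask
    if model_id == "constant_dread":
        return dv - alpha * (t_l * u_l - t_s * u_s)
    if model_id == "undiscounted_dread":
        gd = 1.0
    elif model_id == "restricted_dread":
        gd = gamma_p
    elif model_id == "general_dread":
        gd = gamma_d
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    return dv - alpha * (
        u_l * _dread_sum(gamma_p, gd, t_l) - u_s * _dread_sum(gamma_p, gd, t_s)
    )


def pair_value_difference(x_s, x_l, t_s, t_l, params: ModelParams, spec: ModelSpec,
                          wparams: WeibullUtilityParams | None = None):
    """Vectorized V(later) - V(sooner) over arrays of pairs.

    This is the quantity the softmax choice rule consumes.
    """
    u_s = utility(x_s, spec, wparams)
    u_l = utility(x_l, spec, wparams)
    t_s = np.asarray(t_s)
    t_l = np.asarray(t_l)
    mask = (delay_cost_mask(t_s, t_l, spec.delay_cost_convention)
            if spec.model_id == "fixed_delay_cost" else 0.0)
    return value_difference_core(u_s, u_l, t_s, t_l, spec.model_id,
                                 params.gamma_p, params.gamma_d, params.alpha,
                                 params.A, mask)


def fit_weibull_utility(ratings) -> WeibullUtilityParams:
    """Least-squares fit of the three-parameter Weibull to (magnitude, rating).

    ``ratings`` is an iterable of (magnitude, VAS rating) or an (n, 2) array.
    Multi-started from a coarse grid of initial values; flat (constant)
    ratings trigger a warning and a degenerate flat fit at the mean rating.
    """
    arr = np.asarray(list(ratings) if not isinstance(ratings, np.ndarray) else ratings,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("ratings must be (magnitude, rating) rows")
    x, r = arr[:, 0], arr[:, 1]
    if len(x) < 4 or len(np.unique(x)) < 3:
        raise ValueError("need >= 4 ratings spanning >= 3 distinct magnitudes")

    if np.ptp(r) < 1e-12:
        warnings.warn("all ratings identical: returning a flat Weibull fit",
                      stacklevel=2)
        level = max(float(r[0]), 1e-9)
        # tiny scale => curve saturates at r_max essentially everywhere
        return WeibullUtilityParams(r_max=level, scale=1e-6, shape=1.0)

    def resid(theta):
        r_max, scale, shape = np.exp(theta)  # positivity by log-parameterization
        return r_max * -np.expm1(-((x / scale) ** shape)) - r

    xm = max(np.max(x), 1e-6)
    best = None
    for r0 in (np.max(r), 1.5 * np.max(r), 3.0 * np.max(r)):
        for s0 in (0.25 * xm, 0.5 * xm, xm, 2.0 * xm):
            for k0 in (0.5, 1.0, 2.0):
                theta0 = np.log([max(r0, 1e-6), s0, k0])
                try:
                    sol = least_squares(resid, theta0, method="lm", max_nfev=2000)
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
    if best is None:
        raise RuntimeError("Weibull fit failed from every starting point")
    r_max, scale, shape = np.exp(best.x)
    return WeibullUtilityParams(r_max=float(r_max), scale=float(scale),
                                shape=float(shape))
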