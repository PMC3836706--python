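"""Fixed-effects model comparison and the framing restriction battery.

Models are scored with the Bayesian Information Criterion,

    BIC = -2 L + k ln(n),

where L is the maximized log-likelihood of the choices being scored, k the
number of free parameters and n the number of choices entering that
likelihood.  Group-level comparison is fixed-effects: each subject is fitted
separately and per-subject BICs (equivalently log-likelihoods) are summed.
Nested models are additionally compared by likelihood-ratio tests; at the
group level per-subject chi-square statistics and degrees of freedom are
summed, so freeing one parameter in each of N subjects gives df = N.

The framing battery refits the general dread-discounting model jointly to
the pain and relief frames while restricting which of (beta, gamma_P,
gamma_D, alpha) may differ between frames: the fully free variant has eight
parameters, the single-parameter variants five, and the fully shared variant
four.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import (
    FitConfig,
    FitResult,
    _multistart_minimize,
    _neg_loglik_factory,
    fit_subject,
)
from .likelihood import ChoiceDataset, dataset_loglik
from .valuation import ModelParams, ModelSpec, WeibullUtilityParams

__all__ = [
    "bic",
    "ComparisonEntry",
    "group_compare",
    "likelihood_ratio_test",
    "FRAMING_VARIANTS",
    "framing_battery",
    "FramingFit",
]

#: Which of the general dread model's parameters differ between frames.
FRAMING_VARIANTS: dict[str, frozenset] = {
    "all_framing": frozenset({"beta", "gamma_p", "gamma_d", "alpha"}),
    "beta_framing": frozenset({"beta"}),
    "gammaP_framing": frozenset({"gamma_p"}),
    "gammaD_framing": frozenset({"gamma_d"}),
    "alpha_framing": frozenset({"alpha"}),
    "no_framing": frozenset(),
}

_GENERAL = ModelSpec("general_dread")


def bic(L: float, k: int, n: int) -> float:
    """Bayesian Information Criterion: -2L + k ln(n); lower is better."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * L + k * np.log(n)


@dataclass
class ComparisonEntry:
    model_id: str
    k: int
    n: int
    loglik: float

    @property
    def bic(self) -> float:
        return bic(self.loglik, self.k, self.n)


def group_compare(per_subject_fits: dict[str, dict[str, FitResult]]) -> pd.DataFrame:
    """Fixed-effects ranking of models over a cohort of per-subject fits.

    ``per_subject_fits`` maps subject -> model_id -> FitResult; every subject
    must be fitted under every model.  Returns a table ranked by summed BIC
    with per-model summed log-likelihood, k, n, and delta-BIC to the winner.
    """
    if not per_subject_fits:
        raise ValueError("no fits supplied")
    models = sorted({m for fits in per_subject_fits.values() for m in fits})
    gaps = [(s, m) for s, fits in per_subject_fits.items() for m in models
            if m not in fits]
    if gaps:
        raise ValueError(f"missing fits for (subject, model): {gaps}")

    rows = []
    for m in models:
        fits = [per_subject_fits[s][m] for s in per_subject_fits]
        L = sum(f.loglik for f in fits)
        summed_bic = sum(bic(f.loglik, f.k, f.n_obs) for f in fits)
        rows.append({
            "model_id": m,
            "k": fits[0].k,
            "n": sum(f.n_obs for f in fits),
            "loglik": L,
            "bic": summed_bic,
        })
    table = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
    table["delta_bic"] = table["bic"] - table["bic"].iloc[0]
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def likelihood_ratio_test(L_full: float, L_restricted: float, df: int):
    """Likelihood-ratio test of a restricted model nested in a full one.

    Returns (likelihood ratio, chi-square statistic, p-value).  A full-model
    likelihood below the restricted one signals an optimizer failure, not
    evidence, and raises.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if L_full < L_restricted - 1e-9:
        raise ValueError(
            "L_full < L_restricted: the nested fit beat the full fit; "
            "refit the full model (more starts) before testing")
    chi2 = max(2.0 * (L_full - L_restricted), 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return float(np.exp(L_full - L_restricted)), chi2, p


# ---------------------------------------------------------------------------
# framing battery


@dataclass
class FramingFit:
    """Joint two-frame fit of the general dread model under one variant."""

    variant: str
    subject_id: str
    loglik: float
    k: int
    n: int
    params_pain: dict[str, float]
    params_relief: dict[str, float]

    @property
    def bic(self) -> float:
        return bic(self.loglik, self.k, self.n)


def _fit_variant(pain: ChoiceDataset, relief: ChoiceDataset, variant: str,
                 config: FitConfig, rng: np.random.Generator,
                 wparams: WeibullUtilityParams | None = None,
                 warm_starts: list[np.ndarray] | None = None) -> FramingFit:
    free_between = FRAMING_VARIANTS[variant]
    base = list(_GENERAL.free_params)  # beta, gamma_p, gamma_d, alpha
    extra = [p for p in base if p in free_between]
    names = base + extra  # shared block then relief-frame overrides
    n = len(pain) + len(relief)

    neg_p = _neg_loglik_factory(pain, _GENERAL, wparams)
    neg_r = _neg_loglik_factory(relief, _GENERAL, wparams)
    idx_extra = {p: len(base) + j for j, p in enumerate(extra)}

    def negll(theta_nat: np.ndarray) -> float:
        shared = theta_nat[: len(base)]
        relief_vec = shared.copy()
        for p, j in idx_extra.items():
            relief_vec[base.index(p)] = theta_nat[j]
        return neg_p(shared) + neg_r(relief_vec)

    nat, loglik, _, _ = _multistart_minimize(negll, names, config, rng,
                                             extra_starts=warm_starts)
    shared = dict(zip(base, nat[: len(base)]))
    relief_params = dict(shared)
    for p, j in idx_extra.items():
        relief_params[p] = nat[j]
    return FramingFit(variant=variant, subject_id=pain.subject_id,
                      loglik=loglik, k=len(names), n=n,
                      params_pain=shared, params_relief=relief_params)


def framing_battery(pain_data: dict[str, ChoiceDataset],
                    relief_data: dict[str, ChoiceDataset],
                    fit_config: FitConfig | None = None, seed: int = 0,
                    wparams: dict[str, WeibullUtilityParams] | None = None):
    """Fit all six framing variants per subject and rank by summed BIC.

    ``pain_data`` and ``relief_data`` map subject -> ChoiceDataset; both
    frames must be present for every subject.  Returns (table, fits) where
    the table has one row per variant with summed loglik/BIC, rank, and the
    group likelihood-ratio test of the variant against no_framing
    (per-subject chi-squares and dfs summed).
    """
    config = fit_config or FitConfig()
    missing = set(pain_data) ^ set(relief_data)
    if missing:
        raise ValueError(f"subjects missing one frame: {sorted(missing)}")
    if not pain_data:
        raise ValueError("no subjects supplied")

    rng = np.random.default_rng(seed)
    fits: dict[str, dict[str, FramingFit]] = {v: {} for v in FRAMING_VARIANTS}
    base = list(_GENERAL.free_params)
    for sid in sorted(pain_data):
        wp = (wparams or {}).get(sid)
        pain, relief = pain_data[sid], relief_data[sid]

        # anchors: independent per-frame fits (the exact all_framing optimum)
        # and a pooled both-frames fit (the exact no_framing problem)
        fit_p = fit_subject(pain, _GENERAL, config,
                            seed=int(rng.integers(2**31)), wparams=wp)
        fit_r = fit_subject(relief, _GENERAL, config,
                            seed=int(rng.integers(2**31)), wparams=wp)
        pooled = pain.pooled_with(relief)
        fit_0 = fit_subject(pooled, _GENERAL, config,
                            seed=int(rng.integers(2**31)), wparams=wp)
        vec_p = np.array([getattr(fit_p.params, p) for p in base])
        vec_r = np.array([getattr(fit_r.params, p) for p in base])
        vec_0 = np.array([getattr(fit_0.params, p) for p in base])

        fits["all_framing"][sid] = FramingFit(
            variant="all_framing", subject_id=sid,
            loglik=fit_p.loglik + fit_r.loglik, k=8,
            n=len(pain) + len(relief),
            params_pain=dict(zip(base, vec_p)),
            params_relief=dict(zip(base, vec_r)))
        # no_framing refit through the same joint machinery (empty free set)
        # so the restricted variants never outwork it by sheer search effort
        fits["no_framing"][sid] = _fit_variant(
            pain, relief, "no_framing", config,
            np.random.default_rng(rng.integers(2**31)), wp,
            warm_starts=[vec_0, 0.5 * (vec_p + vec_r)])
        if fit_0.loglik > fits["no_framing"][sid].loglik:
            fits["no_framing"][sid] = FramingFit(
                variant="no_framing", subject_id=sid,
                loglik=fit_0.loglik, k=4, n=len(pain) + len(relief),
                params_pain=dict(zip(base, vec_0)),
                params_relief=dict(zip(base, vec_0)))
        vec_0 = np.array([fits["no_framing"][sid].params_pain[p] for p in base])

        for variant, free in FRAMING_VARIANTS.items():
            if variant in ("all_framing", "no_framing"):
                continue
            extra = [p for p in base if p in free]
            # warm starts: shared block from the pooled fit with the freed
            # parameter split per frame, and the pain-frame fit likewise
            warms = []
            for shared_vec in (vec_0, vec_p):
                w = np.concatenate(
                    [shared_vec, [vec_r[base.index(p)] for p in extra]])
                warms.append(w)
            warms.append(np.concatenate(
                [vec_0, [vec_0[base.index(p)] for p in extra]]))
            sub_rng = np.random.default_rng(rng.integers(2**31))
            fits[variant][sid] = _fit_variant(
                pain, relief, variant, config, sub_rng, wp,
                warm_starts=warms)

        # rescue pass: the single-parameter families overlap heavily, so a
        # variant trailing the best sibling by multiple log-units is an
        # optimizer failure, not evidence; give it one refit at double effort
        singles = [v for v in FRAMING_VARIANTS
                   if v not in ("all_framing", "no_framing")]
        best_single = max(fits[v][sid].loglik for v in singles)
        retry_cfg = replace(config, n_starts=2 * config.n_starts)
        for variant in singles:
            f = fits[variant][sid]
            if f.loglik < best_single - 2.0:
                extra = [p for p in base if p in FRAMING_VARIANTS[variant]]
                own = np.array([f.params_pain[p] for p in base]
                               + [f.params_relief[p] for p in extra])
                warms = [own,
                         np.concatenate([vec_0,
                                         [vec_r[base.index(p)] for p in extra]]),
                         np.concatenate([vec_p,
                                         [vec_r[base.index(p)] for p in extra]])]
                refit = _fit_variant(
                    pain, relief, variant, retry_cfg,
                    np.random.default_rng(rng.integers(2**31)), wp,
                    warm_starts=warms)
                if refit.loglik > f.loglik:
                    fits[variant][sid] = refit

        # every restricted solution is a feasible all_framing point, so the
        # all_framing per-frame likelihoods are floored at the best variant
        # solution (protects the nesting hierarchy against start-set luck)
        best_p = dict(fits["all_framing"][sid].params_pain)
        best_r = dict(fits["all_framing"][sid].params_relief)
        l_p = dataset_loglik(pain, _GENERAL, ModelParams(**best_p), wp)
        l_r = dataset_loglik(relief, _GENERAL, ModelParams(**best_r), wp)
        for variant in FRAMING_VARIANTS:
            if variant == "all_framing":
                continue
            f = fits[variant][sid]
            cand_p = dataset_loglik(pain, _GENERAL,
                                    ModelParams(**f.params_pain), wp)
            cand_r = dataset_loglik(relief, _GENERAL,
                                    ModelParams(**f.params_relief), wp)
            if cand_p > l_p:
                l_p, best_p = cand_p, dict(f.params_pain)
            if cand_r > l_r:
                l_r, best_r = cand_r, dict(f.params_relief)
        fits["all_framing"][sid] = FramingFit(
            variant="all_framing", subject_id=sid, loglik=l_p + l_r, k=8,
            n=len(pain) + len(relief), params_pain=best_p,
            params_relief=best_r)

    rows = []
    for variant, per_subj in fits.items():
        L = sum(f.loglik for f in per_subj.values())
        summed_bic = sum(f.bic for f in per_subj.values())
        df_per = len(FRAMING_VARIANTS[variant])
        row = {"variant": variant, "k": 4 + df_per, "loglik": L,
               "bic": summed_bic}
        if variant != "no_framing" and df_per > 0:
            chi2 = 0.0
            lrs = []
            for sid, f in per_subj.items():
                l0 = fits["no_framing"][sid].loglik
                chi2 += max(2.0 * (f.loglik - l0), 0.0)
                lrs.append(max(f.loglik - l0, 0.0))
            df_group = df_per * len(per_subj)
            row["lr_chi2"] = chi2
            row["lr_df"] = df_group
            row["lr_p"] = float(stats.chi2.sf(chi2, df_group))
            row["geometric_mean_individual_lr"] = float(np.exp(np.mean(lrs)))
        else:
            row.update(lr_chi2=np.nan, lr_df=0, lr_p=np.nan,
                       geometric_mean_individual_lr=np.nan)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
    table["delta_bic"] = table["bic"] - table["bic"].iloc[0]
    table["rank"] = np.arange(1, len(table) + 1)
    return table, fits
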