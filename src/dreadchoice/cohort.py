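"""Synthetic agents, cohorts and full study-like datasets with known truth.

Agents choose stochastically through the same softmax rule the models are
fitted with, so simulation and likelihood share a single value computation
and empirical choice frequencies converge to the model probabilities.  The
generators emulate the two study designs (interleaved shock task, dental
appointment grid) and the post-session visual-analogue rating staircase, and
every function is deterministic given its seed.

The default phenotype cohort mirrors the published Experiment-1 composition
of 25 modeled subjects: 7 zero / 4 positive / 12 negative / 2 reversing time
preference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .designs import ChoicePair, DesignConfig, generate_exp1_choice_set, generate_exp2_choice_set
from .likelihood import ChoiceDataset, log_choice_probability
from .valuation import (
    ModelParams,
    ModelSpec,
    WeibullUtilityParams,
    pair_value_difference,
    weibull_utility,
)

__all__ = [
    "AgentSpec",
    "CohortSpec",
    "StudyBundle",
    "simulate_agent",
    "simulate_ratings",
    "simulate_study",
    "recovery_experiment",
    "phenotype_mix_cohort",
    "PHENOTYPE_PRESETS",
]

#: Generating models for the four behavioral phenotypes.  High beta makes
#: choices close to deterministic, as the classification analysis assumes.
#: The reversing preset pairs restricted dread with a concave (Weibull)
#: utility: the aversiveness peak of (1 + alpha*T) * gamma**T sits near
#: delay 17 -- inside the near-term sooner delays of the design -- and the
#: compressed magnitude differences let the dread channel dominate choice,
#: which is what makes the down-then-up choice curve observable.
PHENOTYPE_PRESETS: dict[str, tuple[str, dict]] = {
    "zero": ("null", {"beta": 2.0}),
    "positive": ("exp_discount", {"beta": 1.0, "gamma_p": 0.92}),
    "negative": ("undiscounted_dread", {"beta": 2.0, "gamma_p": 0.9, "alpha": 0.5}),
    "reversing": ("restricted_dread", {"beta": 1.0, "gamma_p": 0.945, "alpha": 1.0}),
}

#: Concave utility used by the reversing preset (see above).
REVERSING_WPARAMS = WeibullUtilityParams(r_max=10.0, scale=4.0, shape=1.5)


@dataclass(frozen=True)
class AgentSpec:
    """Ground truth for one simulated participant."""

    spec: ModelSpec
    params: ModelParams
    frame_overrides: dict = field(default_factory=dict)  # frame -> {param: value}
    phenotype: str = ""
    label: str = ""
    wparams: WeibullUtilityParams | None = None  # rating-generating utility

    def params_for_frame(self, frame: str) -> ModelParams:
        over = self.frame_overrides.get(frame)
        if not over:
            return self.params
        return replace(self.params, **over)


@dataclass(frozen=True)
class CohortSpec:
    """A cohort: agents, the experiment to emulate, and frames to simulate."""

    agents: tuple[AgentSpec, ...]
    experiment: int = 1
    frames: tuple[str, ...] = ("pain", "relief")
    design: DesignConfig = field(default_factory=DesignConfig)
    rating_noise_sd: float = 0.5
    simulate_ratings: bool = True

    def __post_init__(self):
        if not self.agents:
            raise ValueError("cohort must contain at least one agent")
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")


@dataclass
class StudyBundle:
    """Simulated datasets plus the generating-parameter manifest."""

    datasets: dict[str, dict[str, ChoiceDataset]]  # subject -> frame -> data
    ratings: dict[str, pd.DataFrame]
    manifest: dict
    experiment: int

    def subjects(self) -> list[str]:
        return sorted(self.datasets)


def simulate_agent(design: list[ChoicePair], agent: AgentSpec, seed: int,
                   frame: str = "unframed", subject_id: str = "agent") -> ChoiceDataset:
    """Simulate one agent's choices over a design through the softmax rule."""
    rng = np.random.default_rng(seed)
    params = agent.params_for_frame(frame)
    x_s = np.array([p.sooner.magnitude for p in design], dtype=float)
    x_l = np.array([p.later.magnitude for p in design], dtype=float)
    t_s = np.array([p.sooner.delay for p in design], dtype=float)
    t_l = np.array([p.later.delay for p in design], dtype=float)
    dv = pair_value_difference(x_s, x_l, t_s, t_l, params, agent.spec,
                               agent.wparams if agent.spec.utility_kind == "weibull" else None)
    p_later = np.exp(log_choice_probability(dv, params.beta))
    choices = (rng.random(len(design)) < p_later).astype(int)
    ds = ChoiceDataset.from_pairs(subject_id, frame, design, choices)
    return ds


def simulate_ratings(wparams: WeibullUtilityParams, noise_sd: float = 0.5,
                     magnitudes=None, seed: int = 0) -> pd.DataFrame:
    """Simulate the end-of-session rating staircase.

    Shock rate rises from the baseline (2 shocks/5 s) to the maximum
    (14 shocks/5 s) in steps of 2, then symmetrically descends; each stimulus
    receives a visual-analogue rating = Weibull disutility + Gaussian noise,
    clamped to the 0-10 scale.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if magnitudes is None:
        up = np.arange(2, 15, 2)
        magnitudes = np.concatenate([up, up[::-1]])
        phases = ["ascending"] * len(up) + ["descending"] * len(up)
    else:
        magnitudes = np.asarray(magnitudes, dtype=float)
        phases = ["custom"] * len(magnitudes)
    clean = weibull_utility(magnitudes, wparams)
    noisy = np.clip(clean + rng.normal(0.0, noise_sd, len(magnitudes)), 0.0, 10.0)
    return pd.DataFrame({"magnitude": magnitudes, "rating": noisy, "phase": phases})


def simulate_study(cohort: CohortSpec, seed: int) -> StudyBundle:
    """Simulate a full study: per-agent designs, choices, ratings, manifest."""
    rng = np.random.default_rng(seed)
    datasets: dict[str, dict[str, ChoiceDataset]] = {}
    ratings: dict[str, pd.DataFrame] = {}
    manifest: dict = {"seed": int(seed), "experiment": cohort.experiment,
                      "agents": {}}
    for i, agent in enumerate(cohort.agents):
        sid = agent.label or f"s{i:02d}"
        datasets[sid] = {}
        frames = cohort.frames if cohort.experiment == 1 else ("unframed",)
        for frame in frames:
            sub = int(rng.integers(2**31))
            if cohort.experiment == 1:
                design = generate_exp1_choice_set(cohort.design, seed=sub)
                design = [replace(p, frame=frame) for p in design]
            else:
                design = generate_exp2_choice_set(cohort.design)
            datasets[sid][frame] = simulate_agent(
                design, agent, seed=int(rng.integers(2**31)),
                frame=frame, subject_id=sid)
        if cohort.simulate_ratings and cohort.experiment == 1:
            wp = agent.wparams or WeibullUtilityParams(9.0, 8.0, 1.2)
            ratings[sid] = simulate_ratings(
                wp, cohort.rating_noise_sd, seed=int(rng.integers(2**31)))
        manifest["agents"][sid] = {
            "model_id": agent.spec.model_id,
            "utility_kind": agent.spec.utility_kind,
            "phenotype": agent.phenotype,
            "params": agent.params.as_dict(),
            "frame_overrides": {f: dict(o) for f, o in agent.frame_overrides.items()},
        }
    return StudyBundle(datasets=datasets, ratings=ratings, manifest=manifest,
                       experiment=cohort.experiment)


def phenotype_mix_cohort(counts: dict[str, int] | None = None,
                           frame_overrides: dict | None = None) -> CohortSpec:
    """The published Experiment-1 phenotype mix: 7 zero / 4 positive /
    12 negative / 2 reversing (of 25 modeled subjects)."""
    counts = counts or {"zero": 7, "positive": 4, "negative": 12, "reversing": 2}
    agents = []
    for phen, n in counts.items():
        model_id, kw = PHENOTYPE_PRESETS[phen]
        weibull = phen == "reversing"
        for j in range(n):
            agents.append(AgentSpec(
                spec=ModelSpec(model_id,
                               utility_kind="weibull" if weibull else "linear"),
                params=ModelParams(**kw),
                frame_overrides=frame_overrides or {},
                phenotype=phen, label=f"{phen}_{j:02d}",
                wparams=REVERSING_WPARAMS if weibull else None))
    return CohortSpec(agents=tuple(agents))


def recovery_experiment(model_id: str, param_grid: list[dict], n_agents: int,
                        n_choices: int, seed: int,
                        fit_config=None) -> pd.DataFrame:
    """Simulate-and-refit parameter recovery over a grid of true parameters.

    For each grid cell, ``n_agents`` agents are simulated on fresh
    counterbalanced designs of ``n_choices`` pairs and refitted under the
    generating model; the table reports true and fitted values, error, and
    per-cell bias/RMSE-ready columns.
    """
    from .estimation import FitConfig, fit_subject

    if not param_grid:
        raise ValueError("param_grid must be non-empty")
    fit_config = fit_config or FitConfig()
    spec = ModelSpec(model_id)
    rng = np.random.default_rng(seed)
    design_cfg = DesignConfig(n_choice_trials=n_choices)
    rows = []
    for cell_idx, cell in enumerate(param_grid):
        true = ModelParams(**cell)
        agent = AgentSpec(spec=spec, params=true)
        for a in range(n_agents):
            design = generate_exp1_choice_set(design_cfg, seed=int(rng.integers(2**31)))
            data = simulate_agent(design, agent, seed=int(rng.integers(2**31)),
                                  subject_id=f"cell{cell_idx}_a{a}")
            fit = fit_subject(data, spec, fit_config, seed=int(rng.integers(2**31)))
            row = {"cell": cell_idx, "agent": a, "n_choices": len(data),
                   "loglik": fit.loglik}
            for p in spec.free_params:
                row[f"true_{p}"] = getattr(true, p)
                row[f"fit_{p}"] = getattr(fit.params, p)
                row[f"err_{p}"] = getattr(fit.params, p) - getattr(true, p)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle I/O


def write_bundle(bundle: StudyBundle, outdir) -> None:
    """Write a bundle as a directory of per-subject CSVs plus a JSON manifest."""
    from pathlib import Path

    from .likelihood import write_choice_csv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, frames in bundle.datasets.items():
        for frame, ds in frames.items():
            write_choice_csv(ds, out / f"choices_{sid}_{frame}.csv")
    for sid, df in bundle.ratings.items():
        df.to_csv(out / f"ratings_{sid}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)


def read_bundle(indir) -> StudyBundle:
    from pathlib import Path

    from .likelihood import read_choice_csv

    ind = Path(indir)
    with open(ind / "manifest.json") as fh:
        manifest = json.load(fh)
    datasets: dict[str, dict[str, ChoiceDataset]] = {}
    for f in sorted(ind.glob("choices_*.csv")):
        for ds in read_choice_csv(f):
            datasets.setdefault(ds.subject_id, {})[ds.frame] = ds
    ratings = {
        f.stem.removeprefix("ratings_"): pd.read_csv(f)
        for f in sorted(ind.glob("ratings_*.csv"))
    }
    return StudyBundle(datasets=datasets, ratings=ratings, manifest=manifest,
                       experiment=int(manifest.get("experiment", 1)))
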