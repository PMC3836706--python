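# dreadchoice

Models of intertemporal choice over painful outcomes, for researchers in
decision neuroscience and behavioral science who study *dread*: the
disutility of waiting for an aversive event.  Standard discounting says a
punishment should be deferred; in practice many people prefer to "get it
over with", accepting *more* pain now to avoid waiting (negative time
preference).  `dreadchoice` provides the full analysis stack for this
phenomenon: generators for two study designs (an interleaved electric-shock
task and a hypothetical dental-appointment task), a nested family of value
models, softmax choice likelihoods, multistart maximum-likelihood fitting
with grid verification, fixed-effects BIC model comparison, a
framing-effect restriction battery, and model-free phenotype
classification — all exercised on synthetic cohorts with known ground
truth.

## The model

A prospective option with pain magnitude x at integer delay T has value

    V(x, T) = −[ γ_P^T · u(x) + D(x, T) ],
    D(x, T) = α · u(x) · Σ_{t=0}^{T−1} γ_D^t · γ_P^{T−t},

where u is the disutility of the pain (linear, or a concave three-parameter
Weibull estimated from ratings), γ_P discounts the pain itself, and D
accumulates moment-by-moment dread — the discounted expectation of the
pain — over the waiting period, weighted by α and itself discounted by γ_D.
Setting α = 0 recovers exponential discounting; γ_D = 1 gives
*undiscounted* dread (aversion grows with delay at a decreasing rate);
γ_D = γ_P gives the *restricted* form D = α·T·γ_P^T·u(x), whose aversion
peaks at an intermediate delay near −1/ln γ_P − 1/α and so predicts
*reversing* time preference.  Choices follow a softmax in the value
difference, p(i over j) = 1/(1 + e^{−β(v_i−v_j)}), and models are compared
by summed BIC = −2L + k·ln n across subjects (fixed effects), with
likelihood-ratio tests for nested pairs.

## A worked example

```python
import dreadchoice as dc

design = dc.generate_exp1_choice_set(dc.DesignConfig(n_choice_trials=190), seed=12)
truth  = dc.ModelParams(beta=0.25, gamma_p=0.9, alpha=0.5)
spec   = dc.ModelSpec("undiscounted_dread")
data   = dc.simulate_agent(design, dc.AgentSpec(spec=spec, params=truth), seed=21)

fit  = dc.fit_subject(data, spec, dc.FitConfig(n_starts=20), seed=3)
grid = dc.grid_search(data, spec, resolution=25, simplex_result=fit)
```

Running `python examples/02_simulate_and_fit.py` (exactly the code above
plus printing) gives:

    n choices:            190
    log-likelihood:       -29.43 (simplex), -29.44 (refined grid)
      beta       true   0.250   fitted   0.718
      gamma_p    true   0.900   fitted   0.947
      alpha      true   0.500   fitted   0.129

The maximized log-likelihoods from the simplex search and the exhaustive
refined grid agree to 0.01 log-units, so the optimizer found the global
optimum.  The pain discount factor γ_P is recovered to within 0.05 at this
sample size, while β and α trade off along a likelihood ridge (a sharper
softmax with weaker dread predicts similar choices) — which is why
recovery studies score γ_P.

The other scripts in `examples/` each demonstrate one capability: the
value-model family (`01`), fixed-effects model selection (`03`), phenotype
classification on the published 7/4/12/2 cohort mix (`04`), and the framing
restriction battery (`05`).  A thin CLI mirrors the pipeline for shell use:

    dreadchoice simulate --experiment 1 --agents preset_mix --seed 7 --out bundle/
    dreadchoice fit --bundle bundle/ --seed 3 --out fits/
    dreadchoice compare --fits fits/fits.csv --out comparison.csv
    dreadchoice classify --bundle bundle/ --out phenotypes.csv

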