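"""Fixed-effects BIC comparison across the model family.

Simulates a 3-subject cohort from the undiscounted dread model and fits all
seven models to every subject.  Summed BIC (lower = better) should select
the generating model: dread models beat delay-blind ones, and the extra
flexibility of the 4-parameter general form is penalized away.
"""

import numpy as np

import dreadchoice as dc

rng = np.random.default_rng(8)
cfg = dc.DesignConfig(n_choice_trials=190)
truth = dc.ModelParams(beta=1.5, gamma_p=0.85, alpha=0.5)
agent = dc.AgentSpec(spec=dc.ModelSpec("undiscounted_dread"), params=truth)

fits = {}
fc = dc.FitConfig(n_starts=8, check_curvature=False)
for i in range(3):
    design = dc.generate_exp1_choice_set(cfg, seed=int(rng.integers(2**31)))
    data = dc.simulate_agent(design, agent, seed=int(rng.integers(2**31)),
                             subject_id=f"s{i}")
    fits[f"s{i}"] = {
        m: dc.fit_subject(data, dc.ModelSpec(m), fc,
                          seed=int(rng.integers(2**31)))
        for m in dc.MODEL_IDS
    }

table = dc.group_compare(fits)
print(table[["rank", "model_id", "k", "loglik", "bic", "delta_bic"]]
      .to_string(index=False))
print("\nThe generating model (undiscounted_dread) should rank first; its")
print("delta_bic margin over the delay-blind null quantifies the dread effect.")
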