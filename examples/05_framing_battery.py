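"""Which parameter carries a framing effect?

Simulates a small two-frame cohort in which only the pain discount factor
gamma_P differs between the pain frame (0.95) and the relief frame (0.85),
then fits the six framing variants of the general dread model -- from fully
frame-specific (8 parameters) to fully shared (4) -- and ranks them by
summed BIC with likelihood-ratio tests against the no-framing null.
"""

import numpy as np

import dreadchoice as dc

rng = np.random.default_rng(3)
cfg = dc.DesignConfig()
pain, relief = {}, {}
for i in range(5):
    agent = dc.AgentSpec(
        spec=dc.ModelSpec("general_dread"),
        params=dc.ModelParams(beta=1.0, gamma_p=0.95, gamma_d=1.0, alpha=0.5),
        frame_overrides={"relief": {"gamma_p": 0.85}})
    sid = f"s{i}"
    d_p = dc.generate_exp1_choice_set(cfg, seed=int(rng.integers(2**31)))
    d_r = dc.generate_exp1_choice_set(cfg, seed=int(rng.integers(2**31)))
    pain[sid] = dc.simulate_agent(d_p, agent, seed=int(rng.integers(2**31)),
                                  frame="pain", subject_id=sid)
    relief[sid] = dc.simulate_agent(d_r, agent, seed=int(rng.integers(2**31)),
                                    frame="relief", subject_id=sid)

table, _ = dc.framing_battery(pain, relief,
                              dc.FitConfig(n_starts=6, check_curvature=False),
                              seed=11)
cols = ["rank", "variant", "k", "loglik", "bic", "lr_chi2", "lr_df", "lr_p"]
print(table[cols].to_string(index=False))
print("\nEvery framing variant crushes no_framing by likelihood ratio (the")
print("frames really differ); the single-parameter variants fit almost as")
print("well as the 8-parameter all_framing at half the complexity cost.")
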