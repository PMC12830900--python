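"""Label choices as explore/exploit with the two-parameter HMM and compare
against the Rescorla-Wagner alternative labeler.

The HMM treats choices as emissions of a latent goal state: explore emits
uniformly over arms, each exploit state repeats its arm deterministically.
Its two free parameters are the explore and exploit persistences.
"""

import numpy as np

from pupilexplore import behavior, synth

ses = synth.generate_session(bandit=synth.BanditConfig(n_trials=3000), seed=2)
choices = ses.trials["choice"].to_numpy()
rewards = ses.trials["reward"].to_numpy()
truth = ses.ground_truth["states"]

fit = behavior.fit_explore_hmm(choices, n_restarts=20, seed=0)
seq = behavior.viterbi_states(choices, fit.params)
print(f"fitted persistences: explore {fit.params.p_stay_explore:.3f} "
      f"(true 0.700), exploit {fit.params.p_stay_exploit:.3f} (true 0.950)")
acc_hmm = np.mean((seq.states == 0) == (truth == 0))

rw = behavior.fit_rescorla_wagner(choices, rewards, seed=0)
rl = behavior.rl_explore_labels(rw, choices)
acc_rl = np.mean(rl == (truth == 0))
print(f"RW fit: alpha={rw.alpha:.3f}, beta={rw.beta:.2f}")
print(f"label accuracy vs ground truth: HMM {acc_hmm:.3f}, RL {acc_rl:.3f}")
# the HMM labels recover the latent state better than the RL rule, which
# conflates exploration with errors of reward maximization

seg = behavior.detect_onsets(seq.states)
li_explore = behavior.learning_index(choices, rewards,
                                     np.flatnonzero(seq.states == 0))
li_exploit = behavior.learning_index(choices, rewards,
                                     np.flatnonzero(seq.states != 0))
print(f"onsets detected: {seg.onset.sum()}")
print(f"learning index (explore): {li_explore:.2f}, (exploit): {li_exploit:.2f}")
# more negative = switching is more reward-driven; learning is enhanced
# during explore-labeled trials
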