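"""Peri-onset pupil dynamics, lagged change, and matched-reward controls.

Shows the ramp-then-reset profile around exploration onsets, the change in
pupil between exploit pairs that do or do not span exploration, and the
matched-reward control comparison that separates arousal from reward
history.
"""

import numpy as np

from pupilexplore import behavior, pupil, synth

ses = synth.generate_session(bandit=synth.BanditConfig(n_trials=3000), seed=3)
states = ses.ground_truth["states"]
rewards = ses.trials["reward"].to_numpy()
series = pupil.preprocess_pupil(ses.trials["pupil_z"].to_numpy())
pz = series.values

onsets = np.flatnonzero(behavior.detect_onsets(states).onset)
peri = pupil.peri_event_matrix(pz, onsets, window=15, states=states)
pre = peri.mean[(peri.lags >= -4) & (peri.lags < 0)].mean()
post = peri.mean[(peri.lags > 0) & (peri.lags <= 4)].mean()
print(f"{len(onsets)} onsets; mean pupil 4 trials before: {pre:+.3f}, "
      f"4 trials after: {post:+.3f}")
# pupil is above baseline just before exploration and below it just after

lag = pupil.lagged_pupil_change(pz, states)
g = lag.groupby("crossed")["delta"].mean()
print(f"mean pupil change across exploit pairs: same bout {g.get(False, np.nan):+.3f}, "
      f"spanning exploration {g.get(True, np.nan):+.3f}")
# pairs separated by exploration show the reset; within-bout pairs the ramp

ms = pupil.match_reward_sequences(states, rewards, k=6, min_matches=1)
n_ctrl = sum(len(c) for c in ms.controls)
pre_vals = [pz[w].mean() for w in ms.onset_windows]
ctrl_vals = [pz[w : w + 6].mean() for ctrls in ms.controls for w in ctrls]
print(f"{len(ms.onset_indices)} onsets with 6-trial exploit history, "
      f"{n_ctrl} reward-matched controls")
print(f"pupil before exploration {np.mean(pre_vals):+.3f} vs matched controls "
      f"{np.mean(ctrl_vals):+.3f}")
# on real data, an offset that survives exact reward matching is the arousal
# signal predicting exploration beyond reward history; in this default
# synthetic world onsets are not coupled to pupil level, so the two traces
# should sit close together (enable phase_gate for an entrained world)
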