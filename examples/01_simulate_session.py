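"""Simulate one restless three-armed bandit session with known ground truth.

The generator produces the task environment (per-arm reward probabilities
random-walking on a 0.1 grid inside [0.1, 0.9]), a latent explore/exploit
agent, an arousal-like pupil trace, and Poisson spike counts.
"""

import numpy as np

from pupilexplore import synth

ses = synth.generate_session(bandit=synth.BanditConfig(n_trials=778), seed=1)
tr = ses.trials
gt = ses.ground_truth

print(f"trials: {len(tr)}, units: {ses.counts.shape[1]}")
print(f"explore trials: {(gt['states'] == synth.EXPLORE).sum()} "
      f"({(gt['states'] == synth.EXPLORE).mean():.1%})")
print(f"exploration onsets: {gt['onsets'].sum()}")
print(f"mean reward rate: {tr['reward'].mean():.3f}")
comp = gt["pupil_components"]
print(f"pupil ramp over session: {comp.ramp[-1] - comp.ramp[0]:.2f} z-units")
print(f"pupil on explore vs exploit trials: "
      f"{tr.loc[gt['states'] == 0, 'pupil_z'].mean():+.3f} vs "
      f"{tr.loc[gt['states'] != 0, 'pupil_z'].mean():+.3f}")
# the explore/exploit pupil offset echoes the arousal-gated world the
# generator encodes: pupil ramps between explore bouts and resets at onsets
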