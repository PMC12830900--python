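"""Wavelet phase of the pupil rhythm and phase-locking of exploration onsets.

A complex Morlet wavelet (period 5 trials, 5 cycles) extracts the per-trial
phase of the slow pupil oscillation; circular statistics then ask whether
exploration onsets cluster at a preferred phase.  In the gated world the
agent can only start exploring on the rising phase of the oscillation.
"""

import numpy as np

from pupilexplore import behavior, pupil, synth

ses = synth.generate_session(
    bandit=synth.BanditConfig(n_trials=20_000),
    pupil=synth.PupilGenConfig(phase_gate=True),
    seed=4,
)
states = ses.ground_truth["states"]
onsets = np.flatnonzero(behavior.detect_onsets(states).onset)

ps = pupil.morlet_phase(ses.trials["pupil_z"].to_numpy(), period_trials=5, cycles=5)
phases = ps.phase[onsets[ps.edge_mask[onsets]]]

res = pupil.phase_locking_stats(phases, n_boot=1000, seed=0)
print(f"n = {res.n} onset phases")
print(f"mean phase = {np.degrees(res.mean_angle):.1f} deg "
      f"(negative = rising phase of the oscillation)")
print(f"resultant length R = {res.resultant_length:.3f}")
print(f"bootstrap null: mean R = {res.null_mean:.3f}, "
      f"95% CI = [{res.null_ci[0]:.3f}, {res.null_ci[1]:.3f}]")
print(f"Hodges-Ajne p = {res.p_hodges_ajne:.2e}, bootstrap p = {res.p_boot:.4f}")
# R far above the uniform null shows onsets entrained to the pupil rhythm;
# at 3-second trials the 5-trial period sits in the Mayer-wave band:
print(f"5-trial cycle at 3 s/trial = {pupil.mayer_band_frequency(5, 3.0):.3f} Hz")
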