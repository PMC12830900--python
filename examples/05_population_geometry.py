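"""Choice-predictive subspace, decoding, scatter index, and neural speed.

Targeted dimensionality reduction fits two choice-discriminating hyperplanes
(the third is their negative sum); population activity is then analyzed in
that 2-d subspace: how well the upcoming choice can be decoded, how
scattered same-choice activity is, and how fast the population state moves.
Larger pupil flattens unit tuning, so decoding degrades and scatter grows
with pupil size.
"""

import numpy as np

from pupilexplore import neural, stats, synth

ses = synth.generate_session(bandit=synth.BanditConfig(n_trials=1500), seed=5)
choices = ses.trials["choice"].to_numpy()
pz = ses.trials["pupil_z"].to_numpy()

tensor = neural.prepare_population(ses.counts)
print(f"{tensor.included.sum()}/{len(tensor.included)} units pass the "
      f"2 spikes/s inclusion rule")

sub = neural.fit_choice_subspace(tensor, choices)
dec = neural.decode_choice_probability(tensor, sub, choices)
print(f"decoding accuracy: {dec.accuracy:.3f}; "
      f"mean decoded p(choice): {dec.p_choice.mean():.3f}")

proj = sub.project(tensor.counts[:, tensor.included])
sc = neural.scatter_index(proj, choices)
print(f"mean scatter index: {np.nanmean(sc.scatter):.3f} "
      f"(1 = no same-choice clustering)")

speed = neural.neural_speed(ses.binned_counts[:, tensor.included, :], sub)
print(f"mean neural speed: {speed.mean():.1f} subspace units/s")

for name, y in (("decoded p", dec.p_choice), ("scatter", sc.scatter)):
    g = stats.glm_session_dummies(y[~np.isnan(y)], pz[~np.isnan(y)])
    print(f"{name} ~ pupil slope: {g.params['x1']:+.4f} (p = {g.pvalues['x1']:.2e})")
# negative decoding slope and positive scatter slope with pupil reproduce
# the tuning-flattening world the generator encodes

table, summary = neural.unit_tuning_glm(tensor.rates[:, tensor.included], choices, pz)
print(f"tuned for choice: {summary['pct_choice_tuned']:.0f}%, "
      f"pupil-modulated: {summary['pct_pupil_modulated']:.0f}%, "
      f"choice x pupil interaction: {summary['pct_interaction']:.0f}%")
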