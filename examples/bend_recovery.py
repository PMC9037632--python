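"""Parameter recovery: impose bends with known ground truth, measure them.

Generates a 100-model ensemble of a 40-bp duplex with per-model bends
drawn uniformly in [0, 60] deg plus 0.3 A coordinate noise, then recovers
each bending angle from the curvilinear helical axis.  The mean absolute
recovery error (a few degrees) is the package's core accuracy statement.
"""

import numpy as np
from scipy.stats import spearmanr

from helixbend import (
    PerturbationSpec,
    bending_angle,
    build_ideal_duplex,
    duplex_pair_frames,
    generate_ensemble,
    helical_axis,
)

base = build_ideal_duplex("GCAU" * 10)
ensemble, truth = generate_ensemble(
    base, PerturbationSpec(bend_total=60, noise_sigma=0.3, n_models=100, seed=1)
)

recovered = []
for model in ensemble:
    frames, _ = duplex_pair_frames(model)
    recovered.append(bending_angle(helical_axis(frames)).bending_angle)
recovered = np.array(recovered)
imposed = truth["bend_imposed"].to_numpy()

mae = np.mean(np.abs(recovered - imposed))
rho = spearmanr(imposed, recovered).statistic
print(f"models: {len(ensemble)}, imposed bends 0-60 deg, noise 0.3 A")
print(f"mean absolute recovery error: {mae:.2f} deg  (criterion: <= 5)")
print(f"imposed-vs-recovered rank correlation: {rho:.3f}")
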