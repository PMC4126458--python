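"""Calibrate the plasticity steps on a synthetic training recording.

Generates 30 paired trials plus 2 min of spontaneous activity at the
detection statistics of the reference preparation (PN: 91.4% detected
stimuli, silent baseline; IO: 48.6% detected air-puffs over a 1.14-Hz
spontaneous background), counts the expected plasticity events per
condition, and solves the weighted least-squares system.
"""

import numpy as np

from eyeblink import CalibrationConstraints, ModelParams, calibrate_training
from eyeblink.experiments import bio_hybrid_stats, make_training_set

rng = np.random.default_rng(0)
pn_stats, io_stats = bio_hybrid_stats(training=True)
data = make_training_set(rng, pn_stats, io_stats)
result, kappa = calibrate_training(data, ModelParams(), CalibrationConstraints())

for s in result.summaries:
    print(f"{s.condition_id:11s}: P = {s.p_bar:7.1f} eligible steps/trial, D = {s.d_bar:.3f} coincidences/trial")
print(f"\nspontaneous IO rate estimate : {data.spont_rate_hz:.2f} Hz")
print(f"eligible time per trial      : {kappa:.3f} s")
print(f"potentiation step delta_p    : {result.delta_p:.3e}  (per eligible 2-ms step)")
print(f"depression step  delta_d     : {result.delta_d:.3e}  (per gated IO coincidence)")
print(f"row residuals                : {np.array2string(result.residuals, precision=5)}")

# Reading: the stability row (weighted 100x) pins delta_d/delta_p to the
# ratio of eligible steps to spontaneous coincidences, so spontaneous IO
# activity leaves the memory weight drift-free; the acquisition/extinction
# rows then set the overall scale so ~0.2 of weight change accumulates over
# ~40 trials.  The magnitudes land near 1.6e-2 / 3.4e-5.
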