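"""Phase entrainment of spiking to amplitude-modulated RF.

Simulates a session with a 20-Hz AM envelope on the RF carrier. One unit's
ON-epoch spiking is von-Mises locked to the envelope peak (kappa = 1), the
other fires independently of envelope phase. The Rayleigh test quantifies
the non-uniformity of spike phases.
"""

import numpy as np

import rfneurostim as rf

protocol = rf.make_protocol(n_trials=150, on_s=2, off_s=3, power_w=37.5,
                            am_hz=20)
spec = rf.PopulationSpec(
    n_units=2, baseline_rates=[4.0, 4.0],
    effect_class=["unaffected", "unaffected"], effect_multiplier=[1.0, 1.0],
    phase_locking_kappa=[1.0, 0.0],
    cell_type_label=["pyramidal", "interneuron"], seed=5)

spikes = rf.generate_spike_trains(protocol, spec)
table = rf.phase_entrainment(spikes, protocol, blank_ms=20)

for _, row in table.iterrows():
    print(f"unit {row.unit_id}: n = {row.n_spikes} ON spikes, "
          f"R = {row.resultant_length_R:.3f}, "
          f"mean phase = {row.mean_phase:.2f} rad, "
          f"Rayleigh p = {row.rayleigh_p:.3g}")
# R is the resultant length of the spike-phase distribution (0 = uniform,
# 1 = perfectly locked); phase 0 is the AM envelope peak. A von-Mises
# concentration kappa = 1 gives an expected R of I1(1)/I0(1) ~ 0.45.
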