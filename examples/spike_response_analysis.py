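"""Per-unit ON/OFF response statistics for an intermittent-RF ephys session.

Simulates a 30-minute recording (300 trials of 3 s RF-ON / 3 s RF-OFF at
37.5 W) from a mixed population — most units unaffected, a minority
suppressed or excited — then epochs spikes with 20-ms artifact blanking and
runs the paired Wilcoxon signed-rank test per unit.
"""

import numpy as np

import rfneurostim as rf

protocol = rf.make_protocol(n_trials=300, on_s=3, off_s=3, power_w=37.5)

n_units = 50
multiplier = np.ones(n_units)
effect = np.array(["unaffected"] * n_units, dtype=object)
multiplier[:10], effect[:10] = 0.5, "suppressed"   # 20% suppressed
multiplier[10:15], effect[10:15] = 1.5, "excited"  # 10% excited
spec = rf.PopulationSpec(
    n_units=n_units, baseline_rates=np.full(n_units, 5.0),
    effect_class=effect, effect_multiplier=multiplier,
    phase_locking_kappa=np.zeros(n_units),
    cell_type_label=np.full(n_units, "pyramidal", dtype=object), seed=1)

spikes = rf.generate_spike_trains(protocol, spec)
epoched = rf.epoch_spikes(spikes, protocol, blank_ms=20)
table = rf.test_unit_response(epoched, alpha=0.05)

n_sup = (table.response_class == "suppressed").sum()
n_exc = (table.response_class == "excited").sum()
print(f"{n_sup + n_exc}/{n_units} units affected "
      f"({n_sup} suppressed, {n_exc} excited) at alpha = 0.05")
print(f"mean MI of true-suppressed units: {table.mi[:10].mean():+.3f} "
      f"(a half-rate unit has expected MI (0.5-1)/(0.5+1) = -1/3)")
print(f"mean MI of true-null units: {table.mi[15:].mean():+.4f} (expected ~0)")
# Each MI is (rate_ON - rate_OFF) / (rate_ON + rate_OFF) from pooled,
# blanking-corrected rates; p-values come from the paired per-trial test.
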