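"""Simulate a mixed population of spontaneously active cells and recover
its calcium transients.

Generates 160 cells across the four activity classes (hyperactive,
moderate, low, silent) sampled every 10 s for 600 s with photobleaching
and noise, then runs bleach correction -> dF/F0 -> peak detection and
compares detected spike counts to the generator's ground truth.
"""

import numpy as np

from fluopop import preset, process_traces, simulate_population

sim = simulate_population(preset("control", n_cells=160, seed=1))
processed = process_traces(sim.traces)

detected = np.array([s.count for s in processed.spike_trains])
truth = np.array([g.true_spike_times.size for g in sim.ground_truth])

print(f"cells: {sim.traces.n_cells}, frames: {sim.traces.n_frames} "
      f"(dt = {sim.traces.frame_interval:.0f} s)")
print(f"mean detected spike count: {detected.mean():.2f} "
      f"(true {truth.mean():.2f})")
print(f"cells with exactly recovered count: {np.mean(detected == truth):.1%}")
print(f"median Ca2+max: {processed.features['ca_max'].median():.2f} dF/F0")

# The exact-recovery fraction shows how peak detection copes with the
# full realistic preset: low-activity cells emit ~0.3 dF/F0 events close
# to the 0.2 detection threshold, so some of their events are (by design)
# below the detector's amplitude floor. On a benchmark population whose
# events are all >= 0.5 ("detection" preset) recovery exceeds 98%.
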