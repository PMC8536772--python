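"""Extract micro-movement spikes (MMS) from a simulated walk.

Simulates a three-minute walk for one body node, detects the angular-speed
peaks, normalizes them into unitless MMS amplitudes, and summarizes the
inter-peak interval timings.
"""

import numpy as np

from mmsgait import GroundTruth, extract_mms, inter_peak_intervals, simulate_subject

truth = GroundTruth(node_names=["pelvis"], cadence_hz=1.0, seed=11)
recording, realized = simulate_subject(truth, duration_s=180.0, rate_hz=100.0)

series = extract_mms(recording.channels["pelvis"],
                     recording.sampling_rate_hz, node_name="pelvis")
intervals, summary = inter_peak_intervals(series)

print(f"detected peaks:           {len(series)}")
print(f"MMS amplitude mean / sd:  {series.values.mean():.4f} / "
      f"{series.values.std():.4f}")
print(f"inter-peak interval mean: {summary['mean_s']:.4f} s "
      f"(cadence {1 / summary['mean_s']:.3f} Hz, planted "
      f"{truth.cadence_hz:.3f} Hz)")
print(f"planted amplitudes recovered to "
      f"{np.max(np.abs(series.values - realized.planted_values['pelvis'])):.2e}")

# The MMS amplitudes are scale-free ratios in (1/2, 1]: the same walk
# recorded on a larger body, or in different units, gives the same series.
# The mean interval is the walker's stride period.
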