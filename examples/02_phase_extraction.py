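"""Detect cardiac peaks and respiratory peaks/troughs, build phases.

The cardiac phase advances 0 -> 2*pi over each pulse-to-pulse interval;
the respiratory phase is 0 at end-expiration and +/-pi at
end-inspiration.  These phases, evaluated at the BOLD frame times, are
the inputs to the RETROICOR regressors.
"""

import numpy as np

from physiofc import (SimParams, cardiac_phase, detect_extrema,
                      generate_physio, physio_quality, respiratory_phase)

params = SimParams(seed=1)
cardiac, resp = generate_physio(params)

peaks = detect_extrema(cardiac)
print(f"cardiac: {len(peaks)} peaks detected over "
      f"{cardiac.duration:.0f} s -> mean rate "
      f"{len(peaks) / cardiac.duration:.2f} Hz")

r_peaks = detect_extrema(resp)
r_troughs = detect_extrema(resp, troughs=True)
print(f"respiratory: {len(r_peaks)} breaths (peaks), "
      f"{len(r_troughs)} troughs")

frame_times = params.retained_frame_times
phi_c = cardiac_phase(peaks, frame_times)
phi_r = respiratory_phase(r_peaks, r_troughs, frame_times)
print(f"cardiac phase range: [{phi_c.phase.min():.3f}, "
      f"{phi_c.phase.max():.3f}) rad  (expected within [0, 2*pi))")
print(f"respiratory phase range: [{phi_r.phase.min():.3f}, "
      f"{phi_r.phase.max():.3f}] rad  (expected within [-pi, pi])")
print(f"quality triage: cardiac={physio_quality(cardiac)}, "
      f"respiratory={physio_quality(resp)}")
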