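"""Extract framewise acoustic features and the 10-value summary.

Features: pitch (F0) with a [0, 1] confidence score (frames below 0.15
are treated as unvoiced), psychoacoustic roughness from spectral-peak
pairs, and the tristimulus energy fractions T1-T3.  Each recording is
summarized by the mean and standard deviation of each feature.
"""

import numpy as np

from meowdecode import MeowSpec, extract_track, synth_meow
from meowdecode.features import aggregate

clip = synth_meow(MeowSpec(f0_start=400, f0_end=550, n_harmonics=6,
                           am_depth=0.4, noise_snr=25, seed=2))
track = extract_track(clip)
print(f"{len(track.f0)} frames, {track.voiced_mask.sum()} voiced "
      f"(confidence >= {track.conf_threshold})")
print(f"median voiced F0: {np.median(track.f0[track.voiced_mask]):.1f} Hz "
      "(true contour runs 400 -> 550 Hz)")
print(f"mean roughness: {track.roughness.mean():.4f}")

vec = aggregate(track)
print("\n10-value feature summary:")
for name, value in vec.as_dict().items():
    print(f"  {name:8s} {value:10.4f}")
# f0_mean should sit near 475 Hz (the contour midpoint); t1..t3 means are
# energy fractions, so their sum is at most 1.
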