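"""Generate a synthetic motor-imagery session and verify the ERD signature.

The generator attenuates the mu rhythm of the class-mapped electrode
(RH -> C3, LH -> C4, F -> Cz) during the imagery interval.  Here we check
that signature directly: mu-band power at C3 during imagery drops for
right-hand trials but not for left-hand trials.
"""

import numpy as np

from mivote import SynthConfig, band_power, generate_session

cfg = SynthConfig(n_trials_per_class=20, erd_depth=0.6, seed=42)
session = generate_session(cfg)
print(f"session: {session.n_trials} trials x {session.n_channels} channels "
      f"x {session.n_samples} samples at {session.fs:g} Hz")

fs = session.fs
c3 = session.channel_index("C3")
rest = slice(0, int(2.5 * fs))                      # pre-cue baseline
mi = slice(int(3.5 * fs), int(5.5 * fs))            # inside the imagery interval

for label in ("RH", "LH"):
    trials = session.data[np.asarray(session.labels) == label]
    p_rest = np.mean([band_power(tr[c3, rest], fs, (9, 12)) for tr in trials])
    p_mi = np.mean([band_power(tr[c3, mi], fs, (9, 12)) for tr in trials])
    print(f"{label}: C3 mu power rest={p_rest:6.2f}  imagery={p_mi:6.2f}  "
          f"ratio={p_mi / p_rest:.2f}")
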