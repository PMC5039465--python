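"""Walk one session through spatial filtering and feature extraction.

The pipeline reduces 15 channels to 3 surrogate channels via the surface
Laplacian, cuts a 2-s analysis window after the cue, and computes 6
spectral features (FFT amplitude/phase per channel) plus 18 AR features
(order-6 Burg coefficients averaged per phase-space dimension, per channel
and mu/beta sub-band).
"""

from mivote import PipelineConfig, SynthConfig, extract_features, generate_session

session = generate_session(SynthConfig(n_trials_per_class=10, erd_depth=0.6, seed=0))
fm = extract_features(session, PipelineConfig())

print(f"feature matrix: {fm.n_trials} trials x {fm.n_features} features")
print("feature names (provenance encoded as channel|band|kind):")
for name in fm.feature_names:
    print(f"  {name}")
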