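"""Per-pair SFFS feature selection followed by one-vs-one voting LDA.

Each of the three class pairs (LH/RH, LH/F, RH/F) gets its own SFFS
feature subset and its own binary LDA; a trial's final label is decided
by the vote table, with disagreements rejected as NONE.
"""

from mivote import (
    PipelineConfig,
    SynthConfig,
    extract_features,
    fit_pipeline,
    generate_session,
)

train = generate_session(SynthConfig(n_trials_per_class=30, erd_depth=0.8, seed=5))
cfg = PipelineConfig()
fitted = fit_pipeline(train, cfg, seed=5)

feature_names = extract_features(train, cfg).feature_names
for pair, sel in fitted.selections.items():
    names = [feature_names[i] for i in sel.selected]
    print(f"{pair[0]}/{pair[1]}: {len(names)} features -> {names}")

test = generate_session(SynthConfig(n_trials_per_class=10, erd_depth=0.8, seed=6))
preds = fitted.predict(test)
correct = sum(p.value == t for p, t in zip(preds, test.labels))
print(f"\nheld-out session: {correct}/{test.n_trials} correct")
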