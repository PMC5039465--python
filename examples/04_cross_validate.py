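"""9-fold stratified cross-validation with accuracy, kappa and ITR.

Selection and classifier fitting happen inside each training fold only;
the reject (NONE) outcomes of the vote table count as errors.
"""

from mivote import PipelineConfig, SynthConfig, generate_session, itr, kfold_cv
from mivote.evaluation import ItrParams

session = generate_session(SynthConfig(n_trials_per_class=24, erd_depth=0.8, seed=9))
report = kfold_cv(session, PipelineConfig(), seed=9)

print(f"fold accuracies: {[f'{a:.1f}' for a in report.fold_accuracies]}")
print(f"mean accuracy: {report.mean_accuracy:.2f}%   kappa: {report.kappa:.3f}")
print("confusion matrix (rows = truth):")
print(report.confusion)

# a 2-s window plus ~1 s of overhead allows ~20 decisions per minute
rate = itr(ItrParams(L=20, p=report.mean_accuracy / 100.0, N_targets=3))
print(f"ITR at 20 decisions/min: {rate:.1f} bits/min")
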