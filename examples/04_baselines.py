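"""Classical classifiers on flattened pixels, under the same protocol.

Evaluates 1/3/5-NN, a linear SVM, LDA and a 100-tree random forest on the
default synthetic dataset over shared holdout splits.  These methods see
the image only as a 1024-vector, so they cannot exploit spatial texture;
on speckle data their errors typically sit well above the CNN's.
"""

from roitone import (
    CurveType,
    STANDARD_BASELINES,
    SplitSpec,
    SyntheticConfig,
    ToneCurve,
    baseline_factory,
    generate_dataset,
    make_splits,
    run_holdout,
)

dataset = generate_dataset(SyntheticConfig(seed=11))
spec = SplitSpec(n_trials=3, base_seed=7)
splits = make_splits(dataset, spec)

for bspec in STANDARD_BASELINES:
    s = run_holdout(dataset, ToneCurve(CurveType.T0), baseline_factory(bspec),
                    spec, splits=splits, method=bspec.label())
    print(f"{s.method:5s} mean error {s.mean_error:5.2f}% +- {s.ci_halfwidth:.2f}")
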