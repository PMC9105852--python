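"""Choose a tone-curve threshold by cross-validation.

The practical recipe for deploying a correction: propose candidate
thresholds, estimate each one's error by stratified 3-fold cross-validation
on the available data, and keep the argmin (ties go to the smaller value).
A fast 1-NN classifier keeps this example quick; swap in
``cnn_factory(CNNConfig(...))`` for the real thing.
"""

from roitone import (
    BaselineMethod,
    BaselineSpec,
    CurveType,
    SyntheticConfig,
    baseline_factory,
    generate_dataset,
    select_parameter,
)

dataset = generate_dataset(SyntheticConfig(seed=11))
knn = baseline_factory(BaselineSpec(BaselineMethod.KNN, k=1))

result = select_parameter([80, 120, 160, 200], dataset, CurveType.T6, knn,
                          n_folds=3, seed=0)
for t, err in sorted(result.scores.items()):
    print(f"t = {t:3d}: cross-validated error {err:5.2f}%")
print(f"selected threshold: t = {result.best}")
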