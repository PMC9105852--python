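"""Holdout harness: split contract, closed-form summaries, paired testing,
sweeps and cross-validated parameter selection."""

import numpy as np
import pytest

from roitone.evaluate import (
    SplitSpec,
    compare_methods,
    curve_for,
    make_splits,
    run_holdout,
    select_parameter,
    split_hash,
    summaries_frame,
    summarize_errors,
    sweep,
)
from roitone.synthdata import LabeledDataset
from roitone.tonecurves import CurveType, ToneCurve

from _oracles import paired_t, t_ci_halfwidth

DEFAULT_SPEC = SplitSpec(base_seed=17)


# ---------------------------------------------------------------------------
# stub classifiers

class ConstantClassifier:
    """Always predicts one class; fit is a no-op."""

    def __init__(self, label: int):
        self.label = label

    def fit(self, images, labels, fmax=255):
        return self

    def predict(self, images):
        return np.full(len(images), self.label, np.int64)


class LookupOracleClassifier:
    """Predicts the true label by recognising each image's pixel bytes."""

    def __init__(self, dataset: LabeledDataset):
        self.table = {
            dataset.images[i].tobytes(): int(dataset.labels[i])
            for i in range(len(dataset))
        }

    def fit(self, images, labels, fmax=255):
        return self

    def predict(self, images):
        return np.array([self.table[img.tobytes()] for img in images])


# ---------------------------------------------------------------------------
# split contract

def test_split_counts_partition_and_stratification(default_dataset):
    splits = make_splits(default_dataset, DEFAULT_SPEC)
    assert len(splits) == 10
    labels = default_dataset.labels
    for train, test in splits:
        assert len(train) == 400 and len(test) == 100
        assert len(np.intersect1d(train, test)) == 0
        assert len(np.union1d(train, test)) == 500
        assert (labels[train] == 0).sum() == 160
        assert (labels[train] == 1).sum() == 240
        assert (labels[test] == 0).sum() == 40
        assert (labels[test] == 1).sum() == 60


def test_splits_deterministic_and_seed_sensitive(default_dataset):
    a = make_splits(default_dataset, DEFAULT_SPEC)
    b = make_splits(default_dataset, DEFAULT_SPEC)
    assert split_hash(a) == split_hash(b)
    for (ta, sa), (tb, sb) in zip(a, b):
        assert np.array_equal(ta, tb) and np.array_equal(sa, sb)
    c = make_splits(default_dataset, SplitSpec(base_seed=18))
    assert split_hash(a) != split_hash(c)


def test_split_count_mismatch_reported(default_dataset):
    bad = SplitSpec(train_normal=100, test_normal=40)  # 140 != 200
    with pytest.raises(ValueError, match="normal"):
        make_splits(default_dataset, bad)


# ---------------------------------------------------------------------------
# closed-form summaries

def test_constant_cirrhosis_stub_gives_exact_forty_percent(default_dataset):
    """Always predicting cirrhosis misclassifies exactly the 40 normal test
    images in every trial: mean 40.00%, CI half-width 0."""
    summary = run_holdout(
        default_dataset,
        ToneCurve(CurveType.T0),
        lambda seed: ConstantClassifier(1),
        DEFAULT_SPEC,
    )
    assert summary.mean_error == pytest.approx(40.0, abs=1e-12)
    assert summary.ci_halfwidth == 0.0
    assert all(t.error_rate == 40.0 for t in summary.per_trial)


def test_oracle_stub_gives_zero_error(default_dataset):
    summary = run_holdout(
        default_dataset,
        ToneCurve(CurveType.T0),
        lambda seed: LookupOracleClassifier(default_dataset),
        DEFAULT_SPEC,
    )
    assert summary.mean_error == 0.0
    assert summary.ci_halfwidth == 0.0


def test_planted_errors_reproduce_student_t_interval():
    errors = [30, 30, 30, 30, 30, 40, 40, 40, 40, 40]
    s = summarize_errors(errors, "planted", "x")
    assert s.mean_error == pytest.approx(35.0, abs=1e-12)
    assert s.ci_halfwidth == pytest.approx(t_ci_halfwidth(errors), abs=1e-9)
    assert s.ci_halfwidth == pytest.approx(3.7702619379970077, abs=1e-9)


def test_error_conservation(default_dataset):
    """Per trial, misclassified + correct = 100 test images, so the stub
    error complements its mirror stub."""
    s1 = run_holdout(default_dataset, ToneCurve(CurveType.T0),
                     lambda seed: ConstantClassifier(1), DEFAULT_SPEC)
    s0 = run_holdout(default_dataset, ToneCurve(CurveType.T0),
                     lambda seed: ConstantClassifier(0), DEFAULT_SPEC)
    for a, b in zip(s1.per_trial, s0.per_trial):
        assert a.error_rate + b.error_rate == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# paired comparison

def _summary(errors, method="m", digest="h"):
    return summarize_errors(errors, method, digest)


def test_identical_summaries_compare_equal():
    a = _summary([30, 32, 35, 31, 38])
    r = compare_methods(a, a)
    assert r.p_value == 1.0 and r.mean_difference == 0.0


def test_constant_nonzero_difference_sentinel():
    a = _summary([32, 34, 37, 33, 40])
    b = _summary([30, 32, 35, 31, 38])
    r = compare_methods(a, b)
    assert r.mean_difference == pytest.approx(2.0)
    assert r.p_value == 0.0
    assert np.isinf(r.t_statistic) and r.t_statistic > 0


def test_paired_t_matches_independent_oracle():
    ea = [30, 32, 35, 31, 38, 40, 36, 33, 30, 41]
    eb = [28, 33, 30, 30, 35, 42, 31, 33, 29, 37]
    r = compare_methods(_summary(ea), _summary(eb))
    t_ref, p_ref = paired_t(ea, eb)
    assert r.t_statistic == pytest.approx(t_ref, abs=1e-9)
    assert r.p_value == pytest.approx(p_ref, abs=1e-9)
    # frozen against an independent R computation of the same test
    assert r.t_statistic == pytest.approx(2.3324447490696723, abs=1e-9)
    assert r.p_value == pytest.approx(0.044568343939717925, abs=1e-9)
    assert r.mean_difference == pytest.approx(1.8)


def test_split_hash_mismatch_refused_unless_unpaired():
    a = _summary([30, 31, 32], digest="aaa")
    b = _summary([29, 30, 31], digest="bbb")
    with pytest.raises(ValueError, match="different splits"):
        compare_methods(a, b)
    r = compare_methods(a, b, allow_unpaired=True)
    assert not r.paired
    assert 0.0 <= r.p_value <= 1.0


# ---------------------------------------------------------------------------
# sweeps

def test_sweep_rows_and_identity_parameter(default_dataset):
    grid = [0, 20, 40]
    summaries = sweep(default_dataset, CurveType.T1, grid,
                      lambda seed: ConstantClassifier(1), DEFAULT_SPEC)
    assert len(summaries) == 3
    assert len({s.split_hash for s in summaries}) == 1  # shared splits
    t0 = run_holdout(default_dataset, ToneCurve(CurveType.T0),
                     lambda seed: ConstantClassifier(1), DEFAULT_SPEC)
    assert summaries[0].errors.tolist() == t0.errors.tolist()
    frame = summaries_frame(summaries)
    assert list(frame.columns) == ["method", "mean_error", "ci_halfwidth",
                                   "n_trials", "split_hash"]
    assert len(frame) == 3


def test_paper_grids_have_eight_points(default_dataset):
    t_grid = list(range(20, 161, 20))
    g_grid = [1 / 10, 1 / 5, 1 / 3, 1 / 2, 1, 2, 3, 5]
    assert len(t_grid) == 8 and len(g_grid) == 8
    s = sweep(default_dataset, CurveType.T3, g_grid,
              lambda seed: ConstantClassifier(1), DEFAULT_SPEC)
    assert len(s) == 8


# ---------------------------------------------------------------------------
# parameter selection with a planted-error stub

def _selection_dataset(n=60):
    """Constant-100 images with a probe ramp (row 1) and an id code (row 0),
    both invisible to thresholds t <= 160 in the id region (values >= 200)."""
    images = np.full((n, 32, 32), 100, np.int64)
    for i in range(n):
        images[i, 0, 0] = 200 + i // 50
        images[i, 0, 1] = 200 + i % 50
        images[i, 1, :16] = np.arange(10, 170, 10)
    labels = np.array([0, 1] * (n // 2), np.int8)
    return LabeledDataset(images, labels, tuple(f"s{i}" for i in range(n)), 255)


class PlantedErrorClassifier:
    """Error rate is a known function of the type-I threshold t.

    The threshold is decoded from the probe ramp (count of zeroed ramp
    pixels), the true labels from the id code, and exactly
    ``f(t)/100 * n_test`` predictions are flipped.
    """

    def __init__(self, dataset, error_of_t):
        self.labels = dataset.labels
        self.error_of_t = error_of_t

    def fit(self, images, labels, fmax=255):
        return self

    def predict(self, images):
        ramp_zeros = int((images[0, 1, :16] == 0).sum())
        t = 10 * ramp_zeros + 10 if ramp_zeros else 0
        ids = (images[:, 0, 0] - 200) * 50 + (images[:, 0, 1] - 200)
        preds = self.labels[ids].astype(np.int64).copy()
        k = round(self.error_of_t(t) / 100.0 * len(images))
        preds[:k] = 1 - preds[:k]
        return preds


@pytest.mark.parametrize("folds", [3, 5])
def test_selection_recovers_planted_argmin(folds):
    ds = _selection_dataset()
    error_of_t = lambda t: abs(t - 100) / 2 + 10  # planted minimum at t=100
    candidates = list(range(20, 161, 20))
    result = select_parameter(
        candidates, ds, CurveType.T1,
        lambda seed: PlantedErrorClassifier(ds, error_of_t),
        n_folds=folds, seed=1,
    )
    assert result.best == 100
    assert result.scores[20] == pytest.approx(50.0)  # k is exact at 50%
    if folds == 3:  # 20 test images per fold make every planted rate exact
        assert result.scores[100] == pytest.approx(10.0)


def test_selection_single_candidate_and_tie_break():
    ds = _selection_dataset()
    flat = lambda t: 25.0
    single = select_parameter([60], ds, CurveType.T1,
                              lambda seed: PlantedErrorClassifier(ds, flat),
                              n_folds=3, seed=0)
    assert single.best == 60
    tie = select_parameter([80, 40], ds, CurveType.T1,
                           lambda seed: PlantedErrorClassifier(ds, flat),
                           n_folds=3, seed=0)
    assert tie.best == 40  # smaller value wins ties


def test_selection_validates_inputs(default_dataset):
    with pytest.raises(ValueError):
        select_parameter([], default_dataset, CurveType.T1,
                         lambda seed: ConstantClassifier(1))
    with pytest.raises(ValueError):
        select_parameter([20], default_dataset, CurveType.T1,
                         lambda seed: ConstantClassifier(1), n_folds=4)


def test_curve_for_builds_each_family():
    assert curve_for(CurveType.T1, 20).t == 20
    assert curve_for(CurveType.T3, 0.5).gamma == 0.5
    assert curve_for(CurveType.T0, None).curve_type is CurveType.T0
    with pytest.raises(ValueError):
        curve_for(CurveType.T0, 10)
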