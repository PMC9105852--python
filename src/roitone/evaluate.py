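"""Repeated stratified holdout evaluation, sweeps and parameter selection.

The error-rate protocol: in each of ``n_trials`` trials the dataset is split
per class without replacement into fixed-size train and test subsets (the
default 200/300-image dataset splits 160+240 train, 40+60 test), the images
are corrected with the tone curve under study, a fresh classifier is trained
on the corrected training images, and the error rate is the percentage of
misclassified corrected test images.  The summary is the arithmetic mean of
the per-trial error rates with a Student-t 95% confidence half-width,
``t_{0.975, n-1} * sd / sqrt(n)``.

Every method in one experiment sees byte-identical splits (a paired design,
enforced by a split hash), so two methods can be compared by a paired
two-sided t-test on their per-trial error differences.  Per-trial classifier
seeds derive from the split spec's base seed, so adding a method never
perturbs existing results.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .synthdata import LabeledDataset
from .tonecurves import (
    CurveType,
    GAMMA_TYPES,
    THRESHOLD_TYPES,
    ToneCurve,
    build_lut,
)

__all__ = [
    "Classifier",
    "SplitSpec",
    "TrialResult",
    "EvalSummary",
    "ComparisonResult",
    "SelectionResult",
    "make_splits",
    "split_hash",
    "trial_seeds",
    "run_holdout",
    "sweep",
    "summaries_frame",
    "select_parameter",
    "compare_methods",
    "curve_for",
]


class Classifier(Protocol):
    """What the harness requires of a classifier: fit on integer image
    stacks (with their grey-level range) and predict 0/1 labels."""

    def fit(self, images: np.ndarray, labels: np.ndarray, fmax: int = 255): ...

    def predict(self, images: np.ndarray) -> np.ndarray: ...


ClassifierFactory = Callable[[int], Classifier]


@dataclass(frozen=True)
class SplitSpec:
    """Stratified holdout layout: per-class train/test counts and trial count.

    Defaults follow the emulated protocol: 10 trials, 160 normal + 240
    cirrhosis training and 40 normal + 60 cirrhosis test images per trial.
    """

    n_trials: int = 10
    train_normal: int = 160
    train_cirrhosis: int = 240
    test_normal: int = 40
    test_cirrhosis: int = 60
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for v in (self.train_normal, self.train_cirrhosis, self.test_normal, self.test_cirrhosis):
            if v < 0:
                raise ValueError("split counts must be >= 0")

    @property
    def n_test(self) -> int:
        return self.test_normal + self.test_cirrhosis


@dataclass(frozen=True)
class TrialResult:
    trial_index: int
    error_rate: float  # percent of test images misclassified

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 100.0:
            raise ValueError(f"error rate {self.error_rate} outside [0, 100]")


@dataclass(frozen=True)
class EvalSummary:
    """Mean error rate (percent), its 95% CI half-width and the trial detail."""

    method: str
    mean_error: float
    ci_halfwidth: float
    per_trial: tuple[TrialResult, ...]
    split_hash: str

    @property
    def errors(self) -> np.ndarray:
        return np.array([t.error_rate for t in self.per_trial])

    @property
    def n_trials(self) -> int:
        return len(self.per_trial)


@dataclass(frozen=True)
class ComparisonResult:
    method_a: str
    method_b: str
    mean_difference: float  # mean(a - b), percentage points
    t_statistic: float
    p_value: float
    paired: bool = True


@dataclass(frozen=True)
class SelectionResult:
    """Cross-validated selection outcome: chosen parameter and the full score
    table (parameter -> mean CV error percent)."""

    best: int | float
    scores: dict


def make_splits(
    dataset: LabeledDataset, spec: SplitSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``n_trials`` stratified (train, test) index pairs.

    Per class, indices are permuted and partitioned into exactly the stated
    counts; train+test must consume the whole class.  Deterministic under
    ``spec.base_seed`` and independent of which methods are later evaluated.
    """
    n_norm, n_cirr = dataset.class_counts
    want = {
        "normal": (spec.train_normal + spec.test_normal, n_norm),
        "cirrhosis": (spec.train_cirrhosis + spec.test_cirrhosis, n_cirr),
    }
    for name, (expected, found) in want.items():
        if expected != found:
            raise ValueError(
                f"{name} class count mismatch: split spec needs {expected}, dataset has {found}"
            )
    idx_by_class = [np.flatnonzero(dataset.labels == c) for c in (0, 1)]
    train_counts = (spec.train_normal, spec.train_cirrhosis)
    seeds = np.random.SeedSequence(spec.base_seed).spawn(spec.n_trials)
    splits = []
    for trial_seed in seeds:
        rng = np.random.default_rng(trial_seed)
        train_parts, test_parts = [], []
        for cls_idx, n_train in zip(idx_by_class, train_counts):
            perm = rng.permutation(cls_idx)
            train_parts.append(perm[:n_train])
            test_parts.append(perm[n_train:])
        train = np.sort(np.concatenate(train_parts))
        test = np.sort(np.concatenate(test_parts))
        splits.append((train, test))
    return splits


def split_hash(splits: Sequence[tuple[np.ndarray, np.ndarray]]) -> str:
    """Digest of the full split sequence, used to enforce the paired design."""
    h = hashlib.sha256()
    for train, test in splits:
        h.update(np.asarray(train, np.int64).tobytes())
        h.update(b"|")
        h.update(np.asarray(test, np.int64).tobytes())
        h.update(b";")
    return h.hexdigest()


def trial_seeds(base_seed: int, n_trials: int) -> list[int]:
    """Per-trial classifier seeds, decoupled from the split stream."""
    ss = np.random.SeedSequence([int(base_seed), 0x5EED])
    return [int(s) for s in ss.generate_state(n_trials) % 2**31]


def _error_percent(pred: np.ndarray, truth: np.ndarray) -> float:
    return 100.0 * float(np.mean(np.asarray(pred) != np.asarray(truth)))


def summarize_errors(
    errors: Sequence[float], method: str, split_digest: str
) -> EvalSummary:
    """Aggregate per-trial error percentages into an :class:`EvalSummary`."""
    errs = np.asarray(errors, dtype=float)
    n = len(errs)
    mean = float(errs.mean())
    if n > 1:
        sd = float(errs.std(ddof=1))
        hw = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)) if sd > 0 else 0.0
    else:
        hw = 0.0
    return EvalSummary(
        method=method,
        mean_error=mean,
        ci_halfwidth=hw,
        per_trial=tuple(TrialResult(i, float(e)) for i, e in enumerate(errs)),
        split_hash=split_digest,
    )


def run_holdout(
    dataset: LabeledDataset,
    curve: ToneCurve,
    classifier_factory: ClassifierFactory,
    split_spec: SplitSpec,
    splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    method: str | None = None,
) -> EvalSummary:
    """Estimate the error rate of one correction + classifier combination.

    Precomputed ``splits`` may be passed to share them across methods;
    otherwise they are drawn from ``split_spec`` (same outcome either way
    for equal specs).
    """
    if dataset.fmax != curve.fmax:
        raise ValueError(f"dataset fmax {dataset.fmax} != curve fmax {curve.fmax}")
    if splits is None:
        splits = make_splits(dataset, split_spec)
    digest = split_hash(splits)
    lut = build_lut(curve)
    corrected = lut(dataset.images)
    labels = dataset.labels.astype(np.int64)
    seeds = trial_seeds(split_spec.base_seed, len(splits))
    errors = []
    for (train, test), seed in zip(splits, seeds):
        clf = classifier_factory(seed)
        clf.fit(corrected[train], labels[train], fmax=dataset.fmax)
        pred = clf.predict(corrected[test])
        errors.append(_error_percent(pred, labels[test]))
    return summarize_errors(errors, method or curve.label(), digest)


def curve_for(curve_type: CurveType | int, parameter, fmax: int = 255) -> ToneCurve:
    """Build a :class:`ToneCurve` from a type id and its free parameter."""
    ct = CurveType(curve_type)
    if ct in THRESHOLD_TYPES:
        return ToneCurve(ct, t=int(parameter), fmax=fmax)
    if ct in GAMMA_TYPES:
        return ToneCurve(ct, gamma=float(parameter), fmax=fmax)
    if parameter is not None:
        raise ValueError(f"type {ct.name} takes no parameter")
    return ToneCurve(ct, fmax=fmax)


def sweep(
    dataset: LabeledDataset,
    curve_type: CurveType | int,
    grid: Iterable,
    classifier_factory: ClassifierFactory,
    split_spec: SplitSpec,
) -> list[EvalSummary]:
    """Run the holdout protocol at every grid parameter under shared splits."""
    grid = list(grid)
    if not grid:
        raise ValueError("parameter grid is empty")
    splits = make_splits(dataset, split_spec)
    return [
        run_holdout(
            dataset,
            curve_for(curve_type, p, dataset.fmax),
            classifier_factory,
            split_spec,
            splits=splits,
        )
        for p in grid
    ]


def summaries_frame(summaries: Sequence[EvalSummary]) -> pd.DataFrame:
    """Long-format results table: one row per method."""
    return pd.DataFrame(
        {
            "method": [s.method for s in summaries],
            "mean_error": [s.mean_error for s in summaries],
            "ci_halfwidth": [s.ci_halfwidth for s in summaries],
            "n_trials": [s.n_trials for s in summaries],
            "split_hash": [s.split_hash for s in summaries],
        }
    )


def select_parameter(
    candidates: Sequence,
    dataset: LabeledDataset,
    curve_type: CurveType | int,
    classifier_factory: ClassifierFactory,
    n_folds: int = 3,
    seed: int = 0,
) -> SelectionResult:
    """Choose the curve parameter by stratified k-fold cross-validation.

    For each candidate, the dataset is corrected with that parameter's curve
    and the mean CV error is computed over shared folds; the candidate with
    the smallest mean error wins, ties going to the smaller parameter value.
    ``n_folds`` must be 3 or 5.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate parameters")
    if n_folds not in (3, 5):
        raise ValueError(f"n_folds must be 3 or 5, got {n_folds}")
    labels = dataset.labels.astype(np.int64)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % 2**31)
    folds = list(skf.split(np.zeros(len(labels)), labels))
    fold_seeds = trial_seeds(seed, n_folds)
    scores: dict = {}
    for p in candidates:
        lut = build_lut(curve_for(curve_type, p, dataset.fmax))
        corrected = lut(dataset.images)
        errs = []
        for (train, test), fs in zip(folds, fold_seeds):
            clf = classifier_factory(fs)
            clf.fit(corrected[train], labels[train], fmax=dataset.fmax)
            errs.append(_error_percent(clf.predict(corrected[test]), labels[test]))
        scores[p] = float(np.mean(errs))
    # argmin; ties broken by the smaller parameter value
    best = min(candidates, key=lambda p: (scores[p], float(p)))
    return SelectionResult(best=best, scores=scores)


def compare_methods(
    a: EvalSummary, b: EvalSummary, allow_unpaired: bool = False
) -> ComparisonResult:
    """Paired two-sided t-test on per-trial error differences.

    Refuses to compare summaries built on different splits unless
    ``allow_unpaired`` is set, in which case a Welch t-test on the two error
    samples is used instead.  With zero-variance differences the p-value is
    reported as exactly 1.0 (all differences zero) or 0.0 (constant nonzero
    difference, below any machine-representable tail probability).
    """
    if a.split_hash != b.split_hash:
        if not allow_unpaired:
            raise ValueError(
                "summaries were built on different splits "
                f"({a.split_hash[:12]} vs {b.split_hash[:12]}); "
                "pass allow_unpaired=True for a Welch test"
            )
        t_stat, p = stats.ttest_ind(a.errors, b.errors, equal_var=False)
        return ComparisonResult(
            a.method, b.method, float(a.mean_error - b.mean_error),
            float(t_stat), float(p), paired=False,
        )
    if a.n_trials != b.n_trials:
        raise ValueError("summaries have different trial counts")
    d = a.errors - b.errors
    mean_diff = float(d.mean())
    if np.allclose(d.std(ddof=1) if len(d) > 1 else 0.0, 0.0):
        if np.allclose(mean_diff, 0.0):
            return ComparisonResult(a.method, b.method, mean_diff, 0.0, 1.0)
        sign = np.sign(mean_diff)
        return ComparisonResult(a.method, b.method, mean_diff, float(sign * np.inf), 0.0)
    t_stat, p = stats.ttest_rel(a.errors, b.errors)
    return ComparisonResult(a.method, b.method, mean_diff, float(t_stat), float(p))
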