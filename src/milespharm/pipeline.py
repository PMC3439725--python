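"""End-to-end MILES workflow on a labelled conformer dataset.

Order of operations: occurrence filtering on the full data set (unsupervised),
SOM-based stratified train/test split, significance analysis fitted on the
training molecules only (it sees labels, so held-out bags must not inform
it), minimum-distance embedding on the significance-selected bits, λ tuning
by replicated cross-validation with a dynamic feature space, a final fit on
the full training set, and held-out evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conformer_id import ConformerReport, contributions
from .data import Dataset
from .evaluation import ConfusionCounts, accuracy, mcc, som_split
from .miles_svm import (
    DEFAULT_LAMBDA_GRID,
    L1SVMModel,
    TuningReport,
    fit_miles,
    predict,
)
from .pharmacophore import occurrence_filter
from .significance import SignificanceResult, select_significant_bits


@dataclass
class PipelineResult:
    model: L1SVMModel
    tuning: TuningReport
    significance: SignificanceResult
    bit_map: dict[int, int]          # original bit -> selected-universe bit
    train_ids: list[str]
    test_ids: list[str]
    train_counts: ConfusionCounts
    test_counts: ConfusionCounts
    selected_dataset: Dataset        # full dataset on the selected universe

    @property
    def train_accuracy(self) -> float:
        return accuracy(self.train_counts)

    @property
    def test_accuracy(self) -> float:
        return accuracy(self.test_counts)

    @property
    def train_mcc(self) -> float:
        return mcc(self.train_counts)

    @property
    def test_mcc(self) -> float:
        return mcc(self.test_counts)

    def conformer_report(self, bag_id: str) -> ConformerReport:
        return contributions(self.selected_dataset.bag(bag_id), self.model)


def run_miles(
    dataset: Dataset,
    metric: str = "manhattan",
    min_occurrence: float = 0.05,
    som_grid: tuple[int, int] = (10, 10),
    som_epochs: int = 500,
    train_ratio: float = 0.75,
    n_perm: int = 500,
    percentile: float = 0.90,
    grid=DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    reps: int = 5,
    seed: int | None = None,
) -> PipelineResult:
    """Run filtering, splitting, significance, tuning, fitting, evaluation."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=3)

    filtered, occ_map = occurrence_filter(dataset, min_occurrence)
    train_ids, test_ids = som_split(
        filtered, grid=som_grid, epochs=som_epochs, ratio=train_ratio,
        seed=int(seeds[0]),
    )
    train_set = filtered.subset(train_ids)
    selected_train, sig, sig_map = select_significant_bits(
        train_set, n_perm=n_perm, percentile=percentile, seed=int(seeds[1])
    )
    # original -> selected-universe bit map (through both reductions)
    bit_map = {
        orig: sig_map[mid]
        for orig, mid in occ_map.items()
        if mid in sig_map
    }
    selected_all = filtered.restrict_bits(sig_map, len(sig_map))

    tuning = tune_lambda_wrapper(
        selected_train.bags, metric, grid, folds, reps, int(seeds[2])
    )
    model, _ = fit_miles(selected_train.bags, metric, tuning.best_lambda)

    test_set = selected_all.subset(test_ids)
    y_train = train_set.labels()
    y_test = test_set.labels()
    pred_train = predict(model, selected_train.bags)
    pred_test = predict(model, test_set.bags)

    return PipelineResult(
        model=model,
        tuning=tuning,
        significance=sig,
        bit_map=bit_map,
        train_ids=train_ids,
        test_ids=test_ids,
        train_counts=ConfusionCounts.from_predictions(y_train, pred_train),
        test_counts=ConfusionCounts.from_predictions(y_test, pred_test),
        selected_dataset=selected_all,
    )


def tune_lambda_wrapper(bags, metric, grid, folds, reps, seed) -> TuningReport:
    from .miles_svm import tune_lambda

    return tune_lambda(bags, metric, grid=grid, folds=folds, reps=reps, seed=seed)
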