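"""Self-contained benchmark recipes at desk scale.

The full-size pipeline (128³ volumes, dozens of training epochs, an
8-iteration hyperparameter search) is far beyond a laptop-minutes budget;
these recipes exercise the identical code path at reduced problem sizes so
the pipeline's behaviour can be measured end to end:

* :func:`scaled_segmentation_benchmark` — 32³ phantoms, 90 training and 20
  held-out volumes, 3-fold subject-disjoint CV with a 2-iteration Bayesian
  search, majority-vote ensemble, and the four evaluation metrics on the
  held-out set.  Because only ~30 gradient updates fit in the budget, the
  search box is scaled alongside the data (f ∈ [8, 12], batch 16, learning
  rate ∈ [1e-3, 1e-2]); the full-size default box remains f ∈ [8, 64],
  batch ∈ [16, 64], lr ∈ [1e-4, 1e-2].
* :func:`toy_search_run` — the search bookkeeping at toy scale (16³, one
  epoch) over the *full* default hyperparameter box: n iterations × k folds
  trained networks.
* :func:`cohort_sex_effect_recovery` and :func:`longitudinal_growth_recovery`
  — simulate a cohort at the default demographic parameters and re-estimate
  the generating sex effects / growth rates with the statistics stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import SegEval, evaluate_segmentation
from .net import NetworkConfig
from .stats import best_scan_per_wave, change_rates, fit_wave_model, welch_t
from .synthetic import CohortSpec, make_annotated_set, simulate_cohort
from .train import (
    EnsembleModel,
    HyperparameterSpace,
    SearchResult,
    bayes_opt_search,
    build_ensemble,
    kfold_split,
)
from .volumes import VolumeGrid, normalize_intensity

__all__ = [
    "SegmentationBenchmark",
    "scaled_segmentation_benchmark",
    "toy_search_run",
    "cohort_sex_effect_recovery",
    "longitudinal_growth_recovery",
]

#: search box used by the scaled-down segmentation benchmark
SCALED_SPACE = HyperparameterSpace(
    f_range=(8, 12), batch_range=(16, 16), lr_range=(1e-3, 1e-2), n_iterations=2
)


@dataclass
class SegmentationBenchmark:
    """Results of one scaled-down end-to-end segmentation run."""

    evals: list[SegEval]
    search: SearchResult
    ensemble: EnsembleModel
    extras: dict = field(default_factory=dict)

    @property
    def mean_dsc(self) -> float:
        return float(np.mean([e.dsc for e in self.evals]))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([e.voxel_accuracy for e in self.evals]))

    @property
    def mean_hd_voxel(self) -> float:
        return float(np.mean([e.hd_voxel for e in self.evals]))


def scaled_segmentation_benchmark(
    seed: int = 0,
    n_train_per_wave: int = 45,
    n_test_per_wave: int = 10,
    grid_size: int = 32,
    budget: int = SCALED_SPACE.n_iterations,
    epochs: int = 10,
    steps_per_epoch: int = 3,
) -> SegmentationBenchmark:
    """Train and evaluate the voting ensemble on synthetic phantoms.

    Defaults give ~90 training and 20 held-out phantoms at 32³ with
    3-fold CV and a 3-iteration search.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    grid = VolumeGrid((grid_size,) * 3, 1.0)
    n_total = n_train_per_wave + n_test_per_wave
    items = make_annotated_set(n_total, seed=int(rng.integers(2**31)), grid=grid)
    by_wave: dict = {"20w": [], "30w": []}
    for v, m, w in items:
        by_wave[w].append((normalize_intensity(v), m))
    train_pairs, test_pairs = [], []
    for w in ("20w", "30w"):
        train_pairs += by_wave[w][:n_train_per_wave]
        test_pairs += by_wave[w][n_train_per_wave:]

    folds_idx = kfold_split(
        train_pairs, 3, list(range(len(train_pairs))), seed=int(rng.integers(2**31))
    )
    folds = [
        ([train_pairs[i] for i in tr], [train_pairs[i] for i in va])
        for tr, va in folds_idx
    ]
    base = NetworkConfig(
        depth=2,
        kernel_sizes=(3, 3),
        input_shape=(grid_size,) * 3,
        epochs=epochs,
        steps_per_epoch=steps_per_epoch,
    )
    result = bayes_opt_search(
        SCALED_SPACE, folds, budget=budget, base_config=base,
        seed=int(rng.integers(2**31)),
    )
    ensemble, winners = build_ensemble(result)
    evals = [evaluate_segmentation(ensemble.predict(v), m) for v, m in test_pairs]
    return SegmentationBenchmark(
        evals=evals,
        search=result,
        ensemble=ensemble,
        extras={"winners": winners, "n_train": len(train_pairs),
                "n_test": len(test_pairs)},
    )


def toy_search_run(
    seed: int = 0,
    n_iterations: int = 8,
    k_folds: int = 3,
    grid_size: int = 16,
    n_per_fold: int = 4,
) -> SearchResult:
    """The full search loop at toy scale over the default hyperparameter box.

    ``n_iterations`` proposals each trained once per fold (one epoch on
    16³ phantoms) — the bookkeeping of the real search at a fraction of the
    cost.
    """
    rng = np.random.default_rng(seed)
    grid = VolumeGrid((grid_size,) * 3, 1.0)
    n_items = k_folds * n_per_fold
    items = make_annotated_set(
        max(1, n_items // 2), seed=int(rng.integers(2**31)), grid=grid
    )
    pairs = [(normalize_intensity(v), m) for v, m, _ in items][:n_items]
    folds_idx = kfold_split(
        pairs, k_folds, list(range(len(pairs))), seed=int(rng.integers(2**31))
    )
    folds = [
        ([pairs[i] for i in tr], [pairs[i] for i in va]) for tr, va in folds_idx
    ]
    base = NetworkConfig(
        depth=2, kernel_sizes=(3, 3), input_shape=(grid_size,) * 3,
        epochs=1, steps_per_epoch=1,
    )
    space = HyperparameterSpace(n_iterations=n_iterations)
    return bayes_opt_search(
        space, folds, budget=n_iterations, base_config=base,
        seed=int(rng.integers(2**31)), keep_networks=False,
    )


def cohort_sex_effect_recovery(wave: str, n_subjects: int, seed: int = 0) -> dict:
    """Simulate a per-wave cohort and re-estimate the sex effect with the
    wave mixed model; returns the estimate, its SE and the generating
    truth."""
    spec = CohortSpec(n_subjects=n_subjects, seed=seed)
    table = simulate_cohort(spec, mode="per_wave")
    fit = fit_wave_model(table, wave)
    return {
        "estimate_ml": fit.coefficients["sex"],
        "se_ml": fit.std_errors["sex"],
        "truth_ml": spec.sex_effect_ml[wave],
        "lrt_p": fit.lrt_p,
        "n_obs": fit.n_obs,
        "n_subjects": fit.n_subjects,
    }


def longitudinal_growth_recovery(n_subjects: int = 849, seed: int = 0) -> dict:
    """Simulate a longitudinal cohort, take the best-QC scan per
    (subject, wave), and summarise daily growth rates by sex."""
    spec = CohortSpec(n_subjects=n_subjects, seed=seed)
    table = simulate_cohort(spec, mode="longitudinal")
    best = best_scan_per_wave(table)
    records = change_rates(best)
    boys = np.array([r.rate_ml_per_day for r in records if r.sex == "boy"])
    girls = np.array([r.rate_ml_per_day for r in records if r.sex == "girl"])
    t, df, p = welch_t(boys, girls)
    def sem(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x)))
    return {
        "n": len(records),
        "mean_rate_boys": float(boys.mean()),
        "mean_rate_girls": float(girls.mean()),
        "rate_difference": float(boys.mean() - girls.mean()),
        "sem_boys": sem(boys),
        "sem_difference": float(np.hypot(sem(boys), sem(girls))),
        "welch_t": t,
        "welch_df": df,
        "welch_p": p,
    }
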