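"""Model selection: subject-aware k-fold CV, Bayesian hyperparameter
search, per-fold winner selection, and the 3-member voting ensemble.

The search jointly explores base filter count f ∈ [8, 64], batch size ∈
[16, 64] and learning rate ∈ [1e-4, 1e-2] (log scale).  Each iteration
proposes one configuration and trains it on every fold, so an 8-iteration
search over 3 folds yields 24 networks.  The first 3 proposals are random;
later ones maximize expected improvement of a Gaussian-process surrogate
(Matern kernel) fitted to mean validation DSC.

The per-fold winner is the candidate with the highest mean validation DSC;
paired two-sided Wilcoxon signed-rank tests of its per-sample DSC against
every other candidate in the fold are reported alongside (they annotate the
selection, they do not veto it).  Ties in mean DSC go to the lower
iteration index.  The three fold winners form a majority-vote ensemble:
a voxel is intracranial iff at least 2 of 3 members say so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .metrics import dsc as dsc_metric
from .metrics import voxel_accuracy
from .net import (
    BATCH_BOUNDS,
    F_BOUNDS,
    LR_BOUNDS,
    NetworkConfig,
    TrainedNetwork,
    predict_mask,
    train_network,
)
from .volumes import BinaryMask, Volume

__all__ = [
    "HyperparameterSpace",
    "SearchEntry",
    "SearchResult",
    "FoldWinner",
    "EnsembleModel",
    "kfold_split",
    "bayes_opt_search",
    "select_fold_winner",
    "majority_vote",
    "build_ensemble",
]


@dataclass(frozen=True)
class HyperparameterSpace:
    """Search box for (f, batch size, learning rate)."""

    f_range: tuple[int, int] = F_BOUNDS
    batch_range: tuple[int, int] = BATCH_BOUNDS
    lr_range: tuple[float, float] = LR_BOUNDS
    n_iterations: int = 8
    n_initial: int = 3

    def __post_init__(self) -> None:
        for lo, hi in (self.f_range, self.batch_range, self.lr_range):
            if hi < lo:
                raise ValueError("ranges must be ordered")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class SearchEntry:
    """One trained (fold, iteration) cell of the search."""

    fold: int
    iteration: int
    config: NetworkConfig
    val_dsc: list[float]
    val_accuracy: list[float]
    network: TrainedNetwork | None = None
    diverged: bool = False

    @property
    def mean_dsc(self) -> float:
        return float(np.mean(self.val_dsc)) if self.val_dsc else float("nan")


@dataclass
class SearchResult:
    """All (fold, iteration) entries plus the proposed configs per
    iteration."""

    entries: list[SearchEntry] = field(default_factory=list)
    n_folds: int = 0
    n_iterations: int = 0

    def fold_entries(self, fold: int) -> list[SearchEntry]:
        return sorted(
            (e for e in self.entries if e.fold == fold), key=lambda e: e.iteration
        )


@dataclass
class FoldWinner:
    """Winner of one fold with the descriptive signed-rank annotation."""

    fold: int
    entry: SearchEntry
    #: iteration index -> two-sided signed-rank p of winner vs candidate
    signed_rank_p: dict = field(default_factory=dict)

    @property
    def network(self) -> TrainedNetwork:
        return self.entry.network


# ---------------------------------------------------------------------------
# K-fold
# ---------------------------------------------------------------------------

def kfold_split(items, k: int, subject_ids, seed: int = 0):
    """Subject-disjoint k-fold partition of item indices.

    All items of a subject land in the same fold (the leakage rule used for
    the train/test split is applied to folds too); fold sizes are balanced
    by item count.  Returns ``k`` pairs of index lists ``(train, val)``.
    """
    items = list(items)
    subject_ids = list(subject_ids)
    if len(items) != len(subject_ids):
        raise ValueError("items and subject_ids must have equal length")
    if k < 2:
        raise ValueError("k must be >= 2")
    subjects = sorted(set(subject_ids))
    if len(subjects) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    by_subject: dict = {s: [] for s in subjects}
    for i, s in enumerate(subject_ids):
        by_subject[s].append(i)
    # greedy balance: assign each subject to the currently smallest fold
    folds: list[list[int]] = [[] for _ in range(k)]
    for s in sorted(order, key=lambda s: -len(by_subject[s])):
        smallest = min(range(k), key=lambda j: (len(folds[j]), j))
        folds[smallest].extend(by_subject[s])
    out = []
    for j in range(k):
        val = sorted(folds[j])
        train = sorted(i for jj in range(k) if jj != j for i in folds[jj])
        out.append((train, val))
    return out


# ---------------------------------------------------------------------------
# Bayesian optimization
# ---------------------------------------------------------------------------

def _to_unit(x, space: HyperparameterSpace) -> np.ndarray:
    f, b, lr = x
    lo_f, hi_f = space.f_range
    lo_b, hi_b = space.batch_range
    lo_l, hi_l = np.log(space.lr_range)
    return np.array(
        [
            (f - lo_f) / max(hi_f - lo_f, 1e-12),
            (b - lo_b) / max(hi_b - lo_b, 1e-12),
            (np.log(lr) - lo_l) / max(hi_l - lo_l, 1e-12),
        ]
    )


def _from_unit(u, space: HyperparameterSpace):
    lo_f, hi_f = space.f_range
    lo_b, hi_b = space.batch_range
    lo_l, hi_l = np.log(space.lr_range)
    f = int(np.rint(lo_f + u[0] * (hi_f - lo_f)))
    b = int(np.rint(lo_b + u[1] * (hi_b - lo_b)))
    lr = float(np.exp(lo_l + u[2] * (hi_l - lo_l)))
    return f, b, lr


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def propose_configs(
    space: HyperparameterSpace, observed_x, observed_y, rng, n_candidates=256
):
    """Next (f, batch, lr) proposal: random during the initial phase, then
    the max-EI point of a GP fit to the observations (in unit coordinates,
    learning rate on log scale)."""
    if len(observed_x) < space.n_initial:
        u = rng.random(3)
        return _from_unit(u, space)
    X = np.array([_to_unit(x, space) for x in observed_x])
    y = np.array(observed_y, dtype=float)
    kernel = ConstantKernel(1.0) * Matern(length_scale=0.3, nu=2.5) + WhiteKernel(
        noise_level=1e-4, noise_level_bounds=(1e-8, 1e-1)
    )
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31))
    )
    with warnings.catch_warnings():
        # kernel hyperparameters hitting their bounds is routine at the
        # handful-of-points stage of the search
        warnings.simplefilter("ignore")
        gp.fit(X, y)
    cand = rng.random((n_candidates, 3))
    mu, sigma = gp.predict(cand, return_std=True)
    ei = _expected_improvement(mu, sigma, y.max())
    return _from_unit(cand[int(np.argmax(ei))], space)


def _evaluate_network(
    config: NetworkConfig,
    train_pairs,
    val_pairs,
    seed: int,
) -> tuple[TrainedNetwork | None, list[float], list[float], bool]:
    try:
        trained = train_network(config, train_pairs, seed=seed)
        if not np.isfinite(trained.history["loss"][-1]):
            raise FloatingPointError("training diverged")
    except FloatingPointError:
        return None, [], [], True
    val_dsc, val_acc = [], []
    for v, m in val_pairs:
        pred = predict_mask(trained, v)
        val_dsc.append(dsc_metric(pred, m))
        val_acc.append(voxel_accuracy(pred, m))
    return trained, val_dsc, val_acc, False


def bayes_opt_search(
    space: HyperparameterSpace,
    folds,
    budget: int | None = None,
    base_config: NetworkConfig | None = None,
    seed: int = 0,
    evaluate=None,
    keep_networks: bool = True,
) -> SearchResult:
    """Run the sequential search over ``folds``.

    ``folds`` is a list of ``(train_pairs, val_pairs)`` of (Volume, mask)
    tuples; ``budget`` overrides ``space.n_iterations``.  ``base_config``
    carries the non-searched settings (input shape, depth, epochs, ...).
    Each iteration's config is trained once per fold; the surrogate is
    fitted to the mean validation DSC across folds.  Training divergence is
    recorded on the entry, never fatal.

    ``evaluate`` may replace the train-and-score step (signature
    ``evaluate(config, fold_index) -> list of per-sample DSC``); this is
    how deterministic objectives are plugged in for search diagnostics.
    """
    budget = space.n_iterations if budget is None else budget
    if budget < 1:
        raise ValueError("budget must be >= 1")
    base = base_config or NetworkConfig()
    rng = np.random.default_rng(seed)
    result = SearchResult(n_folds=len(folds), n_iterations=budget)
    observed_x, observed_y = [], []

    for it in range(budget):
        f, b, lr = propose_configs(space, observed_x, observed_y, rng)
        config = base.with_(base_filters=f, batch_size=b, learning_rate=lr)
        fold_means = []
        for fi, fold in enumerate(folds):
            if evaluate is not None:
                val_dsc = [float(x) for x in evaluate(config, fi)]
                entry = SearchEntry(fi, it, config, val_dsc, [], None, False)
            else:
                train_pairs, val_pairs = fold
                net_seed = int(rng.integers(0, 2**31 - 1))
                trained, val_dsc, val_acc, diverged = _evaluate_network(
                    config, train_pairs, val_pairs, net_seed
                )
                if not keep_networks:
                    trained = None
                entry = SearchEntry(
                    fi, it, config, val_dsc, val_acc, trained, diverged
                )
            result.entries.append(entry)
            if entry.val_dsc:
                fold_means.append(entry.mean_dsc)
        observed_x.append((f, b, lr))
        observed_y.append(float(np.mean(fold_means)) if fold_means else 0.0)
    return result


# ---------------------------------------------------------------------------
# Winner selection and ensembling
# ---------------------------------------------------------------------------

def select_fold_winner(result: SearchResult, fold: int) -> FoldWinner:
    """Best candidate of a fold by mean validation DSC, with descriptive
    signed-rank p-values against every other candidate of that fold."""
    cands = [e for e in result.fold_entries(fold) if not e.diverged]
    if not cands:
        raise ValueError(f"no successful candidates in fold {fold}")
    best = max(cands, key=lambda e: (e.mean_dsc, -e.iteration))
    pvals = {}
    for other in cands:
        if other is best:
            continue
        a = np.asarray(best.val_dsc, dtype=float)
        b = np.asarray(other.val_dsc, dtype=float)
        if len(a) != len(b) or len(a) == 0:
            continue
        if np.allclose(a, b):
            pvals[other.iteration] = 1.0
            continue
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
        pvals[other.iteration] = float(res.pvalue)
    return FoldWinner(fold=fold, entry=best, signed_rank_p=pvals)


def majority_vote(masks) -> BinaryMask:
    """Per-voxel majority over exactly 3 masks (1 iff >= 2 votes)."""
    masks = list(masks)
    if len(masks) != 3:
        raise ValueError(f"majority vote needs exactly 3 masks, got {len(masks)}")
    grid = masks[0].grid
    for m in masks[1:]:
        if tuple(m.shape) != tuple(grid.shape) or not np.isclose(
            m.spacing_mm, grid.spacing_mm
        ):
            raise ValueError("grid mismatch between ensemble member masks")
    votes = sum(m.data.astype(np.int16) for m in masks)
    return BinaryMask((votes >= 2).astype(np.uint8), grid)


@dataclass
class EnsembleModel:
    """Exactly 3 trained member networks combined by majority voting."""

    members: list[TrainedNetwork]

    def __post_init__(self) -> None:
        if len(self.members) != 3:
            raise ValueError("ensemble requires exactly 3 members")

    def predict(self, v: Volume) -> BinaryMask:
        return majority_vote([predict_mask(m, v) for m in self.members])


def build_ensemble(result: SearchResult) -> tuple[EnsembleModel, list[FoldWinner]]:
    """Select each fold's winner and combine them into the voting ensemble."""
    if result.n_folds != 3:
        raise ValueError("the voting ensemble is defined for 3 folds")
    winners = [select_fold_winner(result, f) for f in range(result.n_folds)]
    members = [w.network for w in winners]
    if any(m is None for m in members):
        raise ValueError("search was run without keep_networks; cannot ensemble")
    return EnsembleModel(members=members), winners
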