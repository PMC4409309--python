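"""Model selection and evaluation protocol.

Hyperparameters are chosen by k-fold cross validation (default 5 folds,
averaged over several random re-partitions); generalization is measured
leave-one-patient-out (LOPO): every patient's sites are held out in turn
while normalization statistics, hyperparameter selection and training use
the remaining patients only. Classifier quality is the accuracy rate;
regression quality is the Euclidean distance between actual and estimated
pacing coordinates. Location shifts between distance samples are compared
with a Wilcoxon rank-sum test (exact enumeration for small samples,
tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .features import zscore_apply, zscore_fit
from .learners import HyperGrid, build_grid, fit_any, predict_any, sigma_hat
from .regionalize import halves_to_octant

__all__ = [
    "EvalConfig",
    "kfold_indices",
    "kfold_select",
    "leave_one_patient_out",
    "LopoResult",
    "accuracy",
    "combine_binary",
    "spatial_resolution",
    "WilcoxonResult",
    "wilcoxon_rank_sum",
    "stratify_by_tissue",
]

log = logging.getLogger(__name__)

#: Exact Wilcoxon enumeration is used up to this combined sample size.
WILCOXON_EXACT_MAX_N = 16


@dataclass(frozen=True)
class EvalConfig:
    """Cross-validation and significance settings."""

    k_folds: int = 5
    n_realizations: int = 10
    alpha: float = 0.05
    seed: int = 0
    tissue_strata: tuple = ("both",)
    stratified_folds: bool = False

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be at least 1")


def kfold_indices(
    n: int, k: int, rng: np.random.Generator, labels: np.ndarray | None = None
) -> list[np.ndarray]:
    """Random partition of ``range(n)`` into k near-equal folds.

    With ``labels`` given, folds are stratified by class (optional; random
    unstratified partitions are the default elsewhere).
    """
    if n < k:
        raise ValueError("need at least one instance per fold")
    if labels is None:
        perm = rng.permutation(n)
        return [np.sort(fold) for fold in np.array_split(perm, k)]
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _score(task: str, pred: np.ndarray, truth: np.ndarray) -> float:
    if task == "regression":
        return -float(np.mean(np.linalg.norm(pred - truth, axis=1)))
    return accuracy(pred, truth)


def kfold_select(
    kind: str,
    grid: HyperGrid,
    X: np.ndarray,
    y: np.ndarray,
    config: EvalConfig | None = None,
    task: str = "classification",
    seed: int | None = None,
) -> dict:
    """Pick the grid point with the best mean cross-validated score.

    Every grid point is scored over ``k_folds`` folds x
    ``n_realizations`` random re-partitions; classification maximizes
    accuracy, regression minimizes the mean Euclidean error. Ties resolve
    to the first grid point in documented order.
    """
    config = config or EvalConfig()
    points = grid.points()
    if not points or not grid.params:
        raise ValueError("empty hyperparameter grid")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n = X.shape[0]
    if n < config.k_folds:
        raise ValueError("fewer instances than folds")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fold_sets = []
    for _ in range(config.n_realizations):
        labels = y if (config.stratified_folds and task != "regression") else None
        fold_sets.append(kfold_indices(n, config.k_folds, rng, labels=labels))
    scores = np.zeros(len(points))
    for pi, hyper in enumerate(points):
        vals = []
        for r, folds in enumerate(fold_sets):
            for f, val_idx in enumerate(folds):
                tr_idx = np.setdiff1d(np.arange(n), val_idx)
                if task != "regression" and np.unique(y[tr_idx]).size < 2:
                    continue
                model = fit_any(kind, X[tr_idx], y[tr_idx], hyper, seed=r * 1000 + f)
                vals.append(_score(task, predict_any(model, X[val_idx]), y[val_idx]))
        scores[pi] = np.mean(vals) if vals else -np.inf
    best = int(np.argmax(scores))  # first grid point wins ties
    log.info("kfold_select(%s): chose %s (score %.3f)", kind, points[best], scores[best])
    return points[best]


@dataclass
class LopoResult:
    """Leave-one-patient-out outcome aligned with the input rows."""

    predictions: np.ndarray
    patients: list
    selected: dict = field(default_factory=dict)  # patient -> hyperparameters
    per_patient_score: dict = field(default_factory=dict)


def leave_one_patient_out(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray,
    kind: str,
    grid_or_hyper: HyperGrid | dict | None,
    config: EvalConfig | None = None,
    task: str = "classification",
) -> LopoResult:
    """Patient-independent evaluation: hold out one patient at a time.

    For each patient, z-score statistics, hyperparameter selection (when a
    grid is given) and training all use the other patients' sites only;
    predictions are made on the held-out patient. N patients give N folds.
    ``grid_or_hyper`` may be a :class:`HyperGrid`, a fixed hyperparameter
    dict, or None to build the learner's published default grid inside
    each fold (the KRR width grid is scaled by the training sigma-hat).
    """
    config = config or EvalConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    pid = np.asarray(patient_ids)
    patients = sorted(set(pid.tolist()))
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs at least two patients")
    if task == "regression" and y.ndim != 2:
        raise ValueError("regression targets must be 2-D (n x 3 coordinates)")
    preds: np.ndarray | None = None
    result = LopoResult(predictions=np.empty(0), patients=patients)
    seeds = np.random.SeedSequence(config.seed).generate_state(len(patients))
    for p, fold_seed in zip(patients, seeds):
        test = pid == p
        train = ~test
        if not test.any():
            raise ValueError(f"patient {p!r} has no sites")
        stats = zscore_fit(X[train])
        Xtr, Xte = zscore_apply(stats, X[train]), zscore_apply(stats, X[test])
        grid = grid_or_hyper
        if grid is None:
            sigma = sigma_hat(Xtr) if kind == "krr" else None
            grid = build_grid(kind, sigma=sigma)
        if isinstance(grid, HyperGrid):
            hyper = kfold_select(
                kind, grid, Xtr, y[train], config, task=task,
                seed=int(fold_seed % (2**31)),
            )
        else:
            hyper = dict(grid)
        model = fit_any(kind, Xtr, y[train], hyper, seed=int(fold_seed % (2**31)))
        p_pred = predict_any(model, Xte)
        if preds is None:
            shape = (len(y),) if p_pred.ndim == 1 else (len(y), p_pred.shape[1])
            preds = np.empty(shape, dtype=p_pred.dtype)
        preds[test] = p_pred
        result.selected[p] = hyper
        result.per_patient_score[p] = _score(task, p_pred, y[test])
        log.info("LOPO fold %s: hyper=%s score=%.3f", p, hyper, result.per_patient_score[p])
    result.predictions = preds
    return result


def accuracy(predictions, truth) -> float:
    """Accuracy rate in percent."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal shapes")
    if predictions.size == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.mean(predictions == truth))


def combine_binary(pred_ab, pred_sl, pred_si) -> np.ndarray:
    """Combine three half-predictions into octant codes, instance-wise."""
    pred_ab, pred_sl, pred_si = (np.asarray(p) for p in (pred_ab, pred_sl, pred_si))
    if not (pred_ab.shape == pred_sl.shape == pred_si.shape):
        raise ValueError("the three half-prediction vectors must align")
    return np.array(
        [halves_to_octant(a, s, i).code for a, s, i in zip(pred_ab, pred_sl, pred_si)]
    )


def spatial_resolution(
    pred_coords: np.ndarray, true_coords: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Per-site Euclidean distances plus their mean and sd (cm)."""
    pred = np.atleast_2d(np.asarray(pred_coords, dtype=float))
    true = np.atleast_2d(np.asarray(true_coords, dtype=float))
    if pred.shape != true.shape or pred.shape[1] != 3:
        raise ValueError("coordinate arrays must share an (n, 3) shape")
    d = np.linalg.norm(pred - true, axis=1)
    return d, float(d.mean()), float(d.std(ddof=1)) if d.size > 1 else 0.0


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sv = values[order]
    i = 0
    while i < sv.size:
        j = i
        while j + 1 < sv.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # rank sum of the first sample
    p_value: float
    significant: bool


def wilcoxon_rank_sum(a, b, alpha: float = 0.05) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    The null distribution is enumerated exactly when the combined sample
    size is at most 16; larger samples use the normal approximation with
    the tie-corrected variance.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    w = float(ranks[:na].sum())
    n = na + nb
    if n <= WILCOXON_EXACT_MAX_N:
        sums = np.array(
            [sum(ranks[list(c)]) for c in itertools.combinations(range(n), na)]
        )
        tol = 1e-9
        p_lo = float(np.mean(sums <= w + tol))
        p_hi = float(np.mean(sums >= w - tol))
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    else:
        mu = na * (n + 1) / 2.0
        _, counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        var = na * nb / 12.0 * ((n + 1) - tie_term)
        if var <= 0:  # all values identical
            return WilcoxonResult(w, 1.0, False)
        z = (w - mu) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return WilcoxonResult(w, p, p < alpha)


def stratify_by_tissue(table, stratum: str):
    """Subset a site table (or sequence of sites) by tissue stratum."""
    if stratum not in ("scar", "normal", "both"):
        raise ValueError(f"unknown tissue stratum {stratum!r}")
    if hasattr(table, "loc"):  # DataFrame with a 'tissue' column
        if stratum == "both":
            return table
        return table.loc[table["tissue"] == stratum]
    if stratum == "both":
        return list(table)
    return [s for s in table if s.tissue == stratum]
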