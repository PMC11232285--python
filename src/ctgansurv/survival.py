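"""Survival statistics and the SuperPC benchmark machinery.

Harrell's C-index uses the strict convention: a pair is comparable iff the
shorter observed time belongs to a subject whose event was observed and the
two times differ; risk ties count 1/2. Kaplan-Meier and the two-group
log-rank test are delegated to lifelines. SuperPC (supervised principal
components) screens genes by univariate Cox Wald z, takes the first
principal component of the survivors, and drives a one-covariate Cox model
with it; the screening threshold is chosen by internal K-fold
cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .data import DomainDataset, ExpressionMatrix

logger = logging.getLogger("ctgansurv")

__all__ = [
    "concordance_index",
    "km_curve",
    "logrank_test",
    "SuperPCModel",
    "fit_superpc",
    "predict_partial_hazard",
    "stratify_and_test",
    "BenchmarkResult",
    "run_cv_benchmark",
]


def concordance_index(times, events, risks) -> float:
    """Harrell's C over comparable pairs; 0.5 (with warning) if none exist."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risks = np.asarray(risks, dtype=float)
    if not (len(times) == len(events) == len(risks)):
        raise ValueError("times, events and risks must have equal length")
    if len(times) < 2:
        raise ValueError("need at least 2 subjects")
    # comparable(i, j): t_i < t_j and subject i had the event
    dt = times[:, None] < times[None, :]
    comparable = dt & (events[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        warnings.warn("no comparable pairs; returning C = 0.5")
        return 0.5
    higher = risks[:, None] > risks[None, :]
    tied = risks[:, None] == risks[None, :]
    return float((comparable & higher).sum() + 0.5 * (comparable & tied).sum()) / float(n_comp)


def km_curve(times, events):
    """Product-limit survival estimate; returns (event_times, survival_prob)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(times_1, events_1, times_2, events_2):
    """Two-group log-rank; returns (chi-square statistic, p-value)."""
    t1, e1 = np.asarray(times_1, float), np.asarray(events_1, int)
    t2, e2 = np.asarray(times_2, float), np.asarray(events_2, int)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both groups must be nonempty")
    if e1.sum() + e2.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined, returning p = 1")
        return 0.0, 1.0
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# SuperPC


@dataclass
class SuperPCModel:
    gene_ids: list[str]
    gene_means: np.ndarray
    gene_sds: np.ndarray
    retained_genes: list[str]
    screening_threshold: float
    pc_loadings: np.ndarray  # unit norm, over retained genes
    cox_coefficient: float
    pc_center: float = 0.0

    def __post_init__(self):
        if len(self.retained_genes) == 0:
            raise ValueError("SuperPC retained no genes")


def _standardize(values: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    return (values - means) / np.where(sds > 1e-12, sds, 1.0)


def _fit_at_threshold(x_std: np.ndarray, z_abs: np.ndarray, threshold: float,
                      times: np.ndarray, events: np.ndarray):
    """PC1 of the screened submatrix + univariate Cox on the PC score."""
    from .genes import univariate_cox  # local import: genes imports this module

    keep = z_abs >= threshold
    if not keep.any():
        keep = z_abs == z_abs.max()  # force at least one gene through
    sub = x_std[:, keep]
    # first right singular vector = PC1 loadings; deterministic sign
    sub_c = sub - sub.mean(axis=0)
    _, _, vt = np.linalg.svd(sub_c, full_matrices=False)
    loadings = vt[0]
    j = int(np.argmax(np.abs(loadings)))
    if loadings[j] < 0:
        loadings = -loadings
    score = sub @ loadings
    center = float(score.mean())
    beta, _ = univariate_cox((score - center)[:, None], times, events)
    return keep, loadings, float(beta[0]), center


def fit_superpc(train: DomainDataset, n_folds: int = 3,
                threshold_grid=(0.0, 0.25, 0.5, 0.75, 0.9),
                seed: int = 0, max_refolds: int = 3) -> SuperPCModel:
    """Fit SuperPC with the screening threshold chosen by internal CV.

    ``threshold_grid`` gives quantile levels of the |Wald z| distribution;
    the level maximising mean validation C-index across folds wins (ties to
    the stricter screen).
    """
    from .genes import univariate_cox

    x = train.expression.values
    if x.shape[1] < 2:
        raise ValueError("SuperPC needs at least 2 genes")
    if int(train.events.sum()) < 2:
        raise ValueError("SuperPC needs at least 2 observed events")
    means, sds = x.mean(axis=0), x.std(axis=0)
    x_std = _standardize(x, means, sds)
    _, z = univariate_cox(x_std, train.times, train.events)
    z_abs = np.abs(z)

    n = x.shape[0]
    best_q, best_c = threshold_grid[0], -np.inf
    for attempt in range(max_refolds):
        rng = np.random.default_rng(seed + attempt)
        folds = rng.permutation(n) % n_folds
        if all(train.events[folds != f].sum() >= 2 and (folds == f).sum() >= 2
               for f in range(n_folds)):
            break
    else:
        raise ValueError("could not build folds with events in every training part")

    # per-fold screening statistics are threshold-independent: compute once
    fold_stats = []
    for f in range(n_folds):
        tr = folds != f
        x_tr = x[tr]
        m_f, s_f = x_tr.mean(axis=0), x_tr.std(axis=0)
        xs_tr = _standardize(x_tr, m_f, s_f)
        _, z_f = univariate_cox(xs_tr, train.times[tr], train.events[tr])
        xs_va = _standardize(x[~tr], m_f, s_f)
        fold_stats.append((tr, xs_tr, np.abs(z_f), xs_va))

    for q in sorted(threshold_grid, reverse=True):
        cs = []
        for f, (tr, xs_tr, z_f_abs, xs_va) in enumerate(fold_stats):
            thr = float(np.quantile(z_f_abs, q))
            keep, loadings, beta, center = _fit_at_threshold(
                xs_tr, z_f_abs, thr, train.times[tr], train.events[tr])
            risk = beta * (xs_va[:, keep] @ loadings - center)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cs.append(concordance_index(train.times[~tr], train.events[~tr], risk))
        mean_c = float(np.mean(cs))
        if mean_c > best_c:
            best_c, best_q = mean_c, q

    threshold = float(np.quantile(z_abs, best_q))
    keep, loadings, beta, center = _fit_at_threshold(
        x_std, z_abs, threshold, train.times, train.events)
    return SuperPCModel(
        gene_ids=list(train.expression.gene_ids),
        gene_means=means, gene_sds=sds,
        retained_genes=[g for g, k in zip(train.expression.gene_ids, keep) if k],
        screening_threshold=threshold,
        pc_loadings=loadings,
        cox_coefficient=beta,
        pc_center=center,
    )


def predict_partial_hazard(model: SuperPCModel, data: ExpressionMatrix) -> np.ndarray:
    """exp(beta * PC1 score), using training-derived parameters only."""
    sub = data.subset_genes(model.gene_ids)
    x_std = _standardize(sub.values, model.gene_means, model.gene_sds)
    keep = np.isin(model.gene_ids, model.retained_genes)
    score = x_std[:, keep] @ model.pc_loadings - model.pc_center
    return np.exp(model.cox_coefficient * score)


def stratify_and_test(model: SuperPCModel, train: DomainDataset, test: DomainDataset):
    """Median-train-hazard split of the test set + KM curves + log-rank p."""
    threshold = float(np.median(predict_partial_hazard(model, train.expression)))
    hazards = predict_partial_hazard(model, test.expression)
    high = hazards > threshold
    if high.all() or (~high).all():
        warnings.warn("risk stratification produced one empty group; p = 1")
        km = km_curve(test.times, test.events)
        return {"high": km, "low": km}, 1.0
    curves = {
        "high": km_curve(test.times[high], test.events[high]),
        "low": km_curve(test.times[~high], test.events[~high]),
    }
    _, p = logrank_test(test.times[high], test.events[high],
                        test.times[~high], test.events[~high])
    return curves, p


# ---------------------------------------------------------------------------
# 100-round cross-validation benchmark


@dataclass
class BenchmarkResult:
    conditions: list[str]
    c_index: dict  # condition -> per-round array
    medians: dict
    p_vs_real: dict  # Wilcoxon signed-rank vs the real-only condition
    seeds: list[int] = field(default_factory=list)


def _augmented_train(real_train: DomainDataset, transfer) -> DomainDataset:
    from .transfer import augment
    return augment(real_train, transfer)


def run_cv_benchmark(real_target: DomainDataset, augmentations: dict,
                     n_rounds: int = 100, test_fraction: float = 0.3,
                     seed: int = 0, superpc_kwargs: dict | None = None) -> BenchmarkResult:
    """Repeated random-split benchmark: does augmentation raise the test C?

    Per round the *real* data are split train/test; each condition trains
    SuperPC on the real training fold plus (for augmented conditions) the
    generated samples, and is scored on the untouched real test fold.
    Generated samples never enter a test fold.
    """
    if n_rounds < 2:
        raise ValueError("need at least 2 rounds")
    superpc_kwargs = superpc_kwargs or {}
    conditions = ["real"] + list(augmentations)
    per_round = {c: [] for c in conditions}
    seeds = []
    n = real_target.n_samples
    n_test = max(2, int(round(test_fraction * n)))
    for r in range(n_rounds):
        rng = np.random.default_rng(seed + r)
        seeds.append(seed + r)
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        test = real_target.subset(test_idx)
        train = real_target.subset(train_idx)
        if train.events.sum() < 2 or test.events.sum() < 1:
            perm = rng.permutation(n)  # one refold attempt
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            test, train = real_target.subset(test_idx), real_target.subset(train_idx)
        for cond in conditions:
            if cond == "real":
                fit_data = train
            else:
                fit_data = _augmented_train(train, augmentations[cond])
            assert not any(s.startswith("gen:") for s in test.sample_ids)
            model = fit_superpc(fit_data, seed=seed + r, **superpc_kwargs)
            risks = predict_partial_hazard(model, test.expression)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_round[cond].append(
                    concordance_index(test.times, test.events, risks))
    c_index = {c: np.asarray(v) for c, v in per_round.items()}
    medians = {c: float(np.median(v)) for c, v in c_index.items()}
    p_vs_real = {}
    for cond in conditions[1:]:
        diff = c_index[cond] - c_index["real"]
        if np.allclose(diff, 0):
            p_vs_real[cond] = 1.0
        else:
            p_vs_real[cond] = float(stats.wilcoxon(c_index[cond], c_index["real"]).pvalue)
    return BenchmarkResult(conditions, c_index, medians, p_vs_real, seeds)
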