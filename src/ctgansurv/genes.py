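"""Gene ranking by univariate Cox proportional-hazards concordance.

Each gene is fitted alone in a CoxPH model against the *target* domain's
survival, and genes are ranked by the Harrell C-index of the fitted risk
score on the same data (higher C = expression more predictive of earlier
events). The top-k list is applied unchanged to both source and target
domains so the two share a feature space.

The Newton-Raphson Breslow fit is vectorised across genes: fitting one
scalar coefficient per gene needs only risk-set cumulative sums, so the
whole catalogue is scored in a few passes over the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DomainDataset
from .survival import concordance_index

logger = logging.getLogger("ctgansurv")

__all__ = ["GeneScore", "score_genes", "select_top", "univariate_cox"]


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    c_index: float
    rank: int


def univariate_cox(x: np.ndarray, times: np.ndarray, events: np.ndarray,
                   max_iter: int = 100, tol: float = 1e-9):
    """Fit one single-covariate CoxPH model per column of ``x``.

    Breslow tie handling, no penalisation. Returns ``(beta, z)`` arrays of
    length n_genes; columns that fail to converge or have zero variance get
    beta = 0, z = 0.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, g = x.shape
    order = np.argsort(times, kind="stable")  # ascending: risk set = suffix
    x_s = x[order]
    t_s = times[order]
    e_s = events[order]

    # map each row to the first index of its tie group (Breslow: tied events
    # share the risk-set sums evaluated at their common time)
    first_of_group = np.zeros(n, dtype=int)
    for i in range(1, n):
        first_of_group[i] = first_of_group[i - 1] if t_s[i] == t_s[i - 1] else i
    ev_rows = np.flatnonzero(e_s == 1)
    ev_group = first_of_group[ev_rows]

    sd = x_s.std(axis=0)
    alive = sd > 1e-12
    xs = np.where(alive, x_s, 0.0)

    beta = np.zeros(g)
    active = alive.copy()
    damp = np.ones(g)  # halved on oscillation (Newton overshoot cycles)
    prev_step = np.zeros(g)
    last_step = np.zeros(g)
    for it in range(max_iter):
        if not active.any():
            break
        eb = np.exp(np.clip(beta * xs, -500, 500))  # n x g: exp(beta_j * x_ij)
        s0 = np.cumsum(eb[::-1], axis=0)[::-1]
        s1 = np.cumsum((xs * eb)[::-1], axis=0)[::-1]
        s2 = np.cumsum((xs ** 2 * eb)[::-1], axis=0)[::-1]
        r0, r1, r2 = s0[ev_group], s1[ev_group], s2[ev_group]
        mean = r1 / r0
        score = (xs[ev_rows] - mean).sum(axis=0)
        info = (r2 / r0 - mean ** 2).sum(axis=0)
        step = np.where(info > 1e-12, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0) * damp
        if it:
            flipped = active & (np.sign(step) == -np.sign(prev_step)) \
                & (np.abs(step) >= 0.5 * np.abs(prev_step))
            damp = np.where(flipped, damp * 0.5, damp)
            step = np.where(flipped, step * 0.5, step)
        prev_step = step
        last_step = np.where(active, step, last_step)
        beta = np.where(active, beta + step, beta)
        converged = np.abs(step) < tol
        active &= ~converged
        beta = np.clip(beta, -50, 50)
    # near-converged fits (step below coefficient precision) are accepted
    active &= np.abs(last_step) > 1e-4
    if active.any():
        # monotone partial likelihood (perfect separation) walks beta to the
        # cap; the risk ordering is still meaningful, so keep the boundary fit
        boundary = active & (np.abs(beta) >= 49.0)
        failed = active & ~boundary
        if boundary.any():
            logger.warning("univariate Cox: %d genes hit the coefficient bound "
                           "(monotone likelihood)", int(boundary.sum()))
        if failed.any():
            logger.warning("univariate Cox: %d genes did not converge; scored as null",
                           int(failed.sum()))
            beta = np.where(failed, 0.0, beta)
            alive &= ~failed

    # Wald z at the solution
    eb = np.exp(np.clip(beta * xs, -500, 500))
    s0 = np.cumsum(eb[::-1], axis=0)[::-1]
    s1 = np.cumsum((xs * eb)[::-1], axis=0)[::-1]
    s2 = np.cumsum((xs ** 2 * eb)[::-1], axis=0)[::-1]
    r0, r1, r2 = s0[ev_group], s1[ev_group], s2[ev_group]
    info = (r2 / r0 - (r1 / r0) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(alive & (info > 1e-12), beta * np.sqrt(np.maximum(info, 0.0)), 0.0)
    beta = np.where(alive, beta, 0.0)
    return beta, z


def score_genes(dataset: DomainDataset) -> list[GeneScore]:
    """Per-gene univariate CoxPH C-index on the dataset's own survival."""
    if int(dataset.events.sum()) < 2:
        raise ValueError("need at least 2 observed events to score genes")
    x = dataset.expression.values
    beta, _ = univariate_cox(x, dataset.times, dataset.events)
    sd = x.std(axis=0)
    cs = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        if sd[j] <= 1e-12 or beta[j] == 0.0:
            # constant gene or failed fit carries no ordering information
            cs[j] = 0.5
            if sd[j] <= 1e-12:
                logger.warning("gene %s is constant; C-index set to 0.5",
                               dataset.expression.gene_ids[j])
            continue
        cs[j] = concordance_index(dataset.times, dataset.events, beta[j] * x[:, j])
    order = sorted(range(len(cs)),
                   key=lambda j: (-cs[j], dataset.expression.gene_ids[j]))
    ranks = np.empty(len(cs), dtype=int)
    ranks[order] = np.arange(1, len(cs) + 1)
    return [GeneScore(g, float(c), int(r))
            for g, c, r in zip(dataset.expression.gene_ids, cs, ranks)]


def select_top(scores: list[GeneScore], k: int = 300) -> list[str]:
    """The k highest-C genes, descending; C ties broken by gene ID."""
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)}-gene catalogue")
    ranked = sorted(scores, key=lambda s: (-s.c_index, s.gene_id))
    return [s.gene_id for s in ranked[:k]]


def write_scores(scores: list[GeneScore], path) -> None:
    pd.DataFrame({"gene_id": [s.gene_id for s in scores],
                  "c_index": [s.c_index for s in scores]}).to_csv(path, sep="\t", index=False)


def write_gene_list(gene_ids: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(gene_ids) + "\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
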