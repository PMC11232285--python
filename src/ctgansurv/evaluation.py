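"""Distribution-level validation of generated and reconstructed data.

The question: do generated samples land inside the target domain's cloud?
Points (selected-gene expression vectors) are labelled by domain style;
KNN purity reads separation directly, a two-component Gaussian mixture
provides cluster assignments for NMI/ARI (against the domain labels) and
silhouette/Dunn (internal quality), and reconstruction fidelity is scored
by MSE and R^2 against the original samples (expression + time feature).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.mixture import GaussianMixture

from .data import DomainDataset

logger = logging.getLogger("ctgansurv")

__all__ = [
    "EvalReport",
    "knn_purity",
    "cluster_gmm",
    "nmi",
    "ari",
    "silhouette",
    "dunn_index",
    "reconstruction_error",
    "evaluate_condition",
]


@dataclass
class EvalReport:
    condition: str  # 'none' or 'model'
    knn_purity: float
    nmi: float
    ari: float
    silhouette: float
    dunn: float
    mse: float | None = None  # absent for the real-data-only condition
    r2: float | None = None

    def as_row(self) -> dict:
        row = {"condition": self.condition, "knn_purity": self.knn_purity,
               "nmi": self.nmi, "ari": self.ari, "silhouette": self.silhouette,
               "dunn": self.dunn}
        row["mse"] = "NA" if self.mse is None else self.mse
        row["r2"] = "NA" if self.r2 is None else self.r2
        return row


def knn_purity(points: np.ndarray, labels, k: int = 10) -> float:
    """Mean fraction of each point's k nearest neighbours sharing its label."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = points.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    # stable argsort: distance ties break by index order
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    return float((labels[nn] == labels[:, None]).mean())


def cluster_gmm(points: np.ndarray, n_components: int = 2, seed: int = 0) -> np.ndarray:
    """Hard assignments from a full-covariance Gaussian mixture (n_init=5)."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] <= n_components:
        raise ValueError("need more points than mixture components")
    # canonical pre-sort: the fit sees a row order independent of input order,
    # and prediction is pointwise, so assignments are permutation-invariant
    canon = points[np.lexsort(points.T[::-1])]
    kwargs = dict(n_components=n_components, covariance_type="full",
                  n_init=5, random_state=seed)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            gm = GaussianMixture(**kwargs).fit(canon)
    except Exception:
        logger.warning("GMM needed covariance regularisation (ridge 1e-6)")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = GaussianMixture(**kwargs, reg_covar=1e-6).fit(canon)
    return gm.predict(points)


def nmi(labels_true, labels_pred) -> float:
    """Mutual information normalised by the arithmetic mean of entropies."""
    labels_true, labels_pred = np.asarray(labels_true), np.asarray(labels_pred)
    if len(labels_true) != len(labels_pred):
        raise ValueError("label vectors must have equal length")
    if len(set(labels_true)) == 1 and len(set(labels_pred)) == 1:
        warnings.warn("single class in both labelings; NMI = 1 by convention")
        return 1.0
    return float(normalized_mutual_info_score(labels_true, labels_pred,
                                              average_method="arithmetic"))


def ari(labels_true, labels_pred) -> float:
    """Hubert-Arabie adjusted Rand index."""
    labels_true, labels_pred = np.asarray(labels_true), np.asarray(labels_pred)
    if len(labels_true) != len(labels_pred):
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(labels_true, labels_pred))


def silhouette(points: np.ndarray, assignments) -> float:
    """Mean silhouette width; singletons contribute 0, as does a = b = 0."""
    points = np.asarray(points, dtype=float)
    assignments = np.asarray(assignments)
    clusters = np.unique(assignments)
    if len(clusters) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    d = squareform(pdist(points))
    s = np.zeros(points.shape[0])
    for i in range(points.shape[0]):
        own = assignments == assignments[i]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton: s(i) = 0
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, assignments == c].mean() for c in clusters if c != assignments[i])
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return float(s.mean())


def dunn_index(points: np.ndarray, assignments) -> float:
    """Min single-linkage inter-cluster distance over max intra-cluster diameter."""
    points = np.asarray(points, dtype=float)
    assignments = np.asarray(assignments)
    clusters = np.unique(assignments)
    if len(clusters) < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    d = squareform(pdist(points))
    diameters = []
    for c in clusters:
        idx = np.flatnonzero(assignments == c)
        if len(idx) < 2:
            raise ValueError("Dunn index needs every cluster to have >= 2 points")
        diameters.append(d[np.ix_(idx, idx)].max())
    max_diam = max(diameters)
    if max_diam == 0:
        raise ValueError("degenerate clustering: zero maximum intra-cluster diameter")
    min_inter = min(
        d[np.ix_(assignments == c1, assignments == c2)].min()
        for i, c1 in enumerate(clusters) for c2 in clusters[i + 1:]
    )
    return float(min_inter / max_diam)


def reconstruction_error(real: np.ndarray, reconstructed: np.ndarray):
    """Entry-wise (MSE, R^2); R^2 is taken about the pooled mean of the real data."""
    real = np.asarray(real, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if real.shape != reconstructed.shape:
        raise ValueError(f"shape mismatch {real.shape} vs {reconstructed.shape}")
    err = real - reconstructed
    mse = float(np.mean(err ** 2))
    ss_tot = float(np.mean((real - real.mean()) ** 2))
    r2 = 1.0 - mse / ss_tot if ss_tot > 0 else (1.0 if mse == 0 else -np.inf)
    return mse, float(r2)


def evaluate_condition(real_a: DomainDataset, real_b: DomainDataset,
                       generated=None, reconstructed=None,
                       k: int = 10, seed: int = 0) -> EvalReport:
    """Score one condition of the two-domain clustering comparison.

    With no generated data ('none' condition) the points are the real A and
    real B expression vectors labelled by domain, and MSE/R^2 are absent.
    With ``generated`` (a dict of TransferResults keyed by target style,
    e.g. ``{"A": ..., "B": ...}``) generated points join the cloud carrying
    their *target* domain's label. ``reconstructed`` is a dict
    ``{domain_name: (ExpressionMatrix, days)}`` paired against the real
    domain of the same name for MSE/R^2 on expression + log-time.
    """
    blocks = [real_a.expression.values, real_b.expression.values]
    labels = [np.repeat("A", real_a.n_samples), np.repeat("B", real_b.n_samples)]
    condition = "none" if (generated is None and reconstructed is None) else "model"
    if generated is not None:
        for style, tr in generated.items():
            blocks.append(tr.generated_expression.values)
            labels.append(np.repeat(style, tr.generated_expression.shape[0]))
    points = np.vstack(blocks)
    domain_labels = np.concatenate(labels)

    purity = knn_purity(points, domain_labels, k=k)
    assignments = cluster_gmm(points, n_components=2, seed=seed)
    report = EvalReport(
        condition=condition,
        knn_purity=purity,
        nmi=nmi(domain_labels, assignments),
        ari=ari(domain_labels, assignments),
        silhouette=silhouette(points, assignments),
        dunn=dunn_index(points, assignments),
    )
    if reconstructed is not None:
        reals, recs = [], []
        by_name = {real_a.name: real_a, real_b.name: real_b}
        for name, (expr, days) in reconstructed.items():
            real = by_name[name]
            reals.append(np.column_stack([real.expression.values,
                                          np.log2(real.times + 1.0)]))
            recs.append(np.column_stack([expr.values, np.log2(days + 1.0)]))
        report.mse, report.r2 = reconstruction_error(np.vstack(reals), np.vstack(recs))
    return report
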