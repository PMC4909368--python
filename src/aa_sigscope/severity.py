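"""PCA severity terrain and the bounded 0-10 consensus severity score.

Samples are projected onto the first two principal components of the
analysis probes; each clinical group (NC, AAP, AT/AU) gets a maximum-
likelihood bivariate Gaussian on that plane. A sample's consensus severity
is the posterior-weighted group severity,

    score(x) = 10 * sum_g w_g P(g | x),   w = {NC: 0, AAP: 0.5, ATAU: 1},

bounded in [0, 10] by construction: 0 reads as a fully control-like
molecular state, 10 as maximal-severity (AT/AU-like) risk. An alternative
mapping — normalized projection onto the NC->AT/AU centroid axis — is
available behind ``method="axis"`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix, ValidationError
from .diffexp import bh_adjust, kruskal_wallis, mann_whitney_u

GROUP_WEIGHTS = {"NC": 0.0, "AAP": 0.5, "ATAU": 1.0}


@dataclass
class PCAProjection:
    """Probe centering + loadings; projects any matrix with these probes."""

    probes: pd.Index
    center: np.ndarray  # per-probe mean on the fitting data
    loadings: np.ndarray  # probe x component
    variance_explained: np.ndarray

    def transform(self, expr: ExpressionMatrix) -> pd.DataFrame:
        sub = expr.subset_probes(self.probes)
        Y = sub.values.to_numpy(dtype=float).T - self.center
        coords = Y @ self.loadings
        return pd.DataFrame(
            coords, index=sub.samples, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
        )


def project_pca(
    expr: ExpressionMatrix, probes=None, n_components: int = 2
) -> tuple[PCAProjection, pd.DataFrame]:
    """Probe-centered PCA via SVD with a deterministic sign convention.

    Per component, the largest-magnitude loading is made positive. Variance
    explained is reported as eigenvalues of the sample covariance (ddof=1).
    """
    if probes is not None:
        expr = expr.subset_probes(probes)
    n_samples = len(expr.samples)
    if n_samples <= n_components:
        raise ValidationError(f"need more than {n_components} samples for PCA")
    Y = expr.values.to_numpy(dtype=float).T  # sample x probe
    center = Y.mean(axis=0)
    Yc = Y - center
    U, S, Vt = np.linalg.svd(Yc, full_matrices=False)
    loadings = Vt[:n_components].T  # probe x comp
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    var_exp = (S[:n_components] ** 2) / (n_samples - 1)
    proj = PCAProjection(
        probes=expr.probes, center=center, loadings=loadings, variance_explained=var_exp
    )
    return proj, proj.transform(expr)


@dataclass
class TerrainModel:
    """Per-group bivariate Gaussians on (PC1, PC2) plus the projection."""

    projection: PCAProjection
    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    weights: dict[str, float] = field(default_factory=lambda: dict(GROUP_WEIGHTS))
    priors: dict[str, float] | None = None  # default: equal

    def __post_init__(self) -> None:
        if self.priors is None:
            g = list(self.means)
            self.priors = {k: 1.0 / len(g) for k in g}
        total = sum(self.priors.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("group priors must sum to 1")

    def log_densities(self, xy: np.ndarray) -> dict[str, np.ndarray]:
        return {
            g: stats.multivariate_normal(self.means[g], self.covariances[g]).logpdf(xy)
            for g in self.means
        }


def fit_terrain(
    coords: pd.DataFrame, meta: pd.DataFrame, projection: PCAProjection, ridge: float = 1e-6
) -> TerrainModel:
    """ML bivariate Gaussian per group (covariance denominator n, + ridge)."""
    meta = meta.loc[coords.index]
    means, covs = {}, {}
    for g, sub in coords.groupby(meta["group"], observed=True):
        if len(sub) < 3:
            raise ValidationError(f"group {g} has fewer than 3 samples; cannot fit covariance")
        X = sub.to_numpy(dtype=float)[:, :2]
        means[g] = X.mean(axis=0)
        covs[g] = np.cov(X.T, ddof=0) + ridge * np.eye(2)
    return TerrainModel(projection=projection, means=means, covariances=covs)


def consensus_score(model: TerrainModel, coords: pd.DataFrame, method: str = "posterior") -> pd.DataFrame:
    """Per-sample posteriors and 0-10 consensus severity.

    Posteriors are computed from log-densities with a max shift, so points
    far from every group density still score without over/underflow. The
    ``axis`` method instead maps the normalized projection onto the
    NC->AT/AU centroid segment, clipped to [0, 10].
    """
    xy = coords.to_numpy(dtype=float)[:, :2]
    groups = list(model.means)
    if method == "axis":
        v = model.means["ATAU"] - model.means["NC"]
        t = (xy - model.means["NC"]) @ v / (v @ v)
        score = np.clip(10.0 * t, 0.0, 10.0)
        post = pd.DataFrame(np.nan, index=coords.index, columns=[f"P_{g}" for g in groups])
        out = post
        out["score"] = score
    elif method == "posterior":
        logd = model.log_densities(xy)
        L = np.column_stack([logd[g] + np.log(model.priors[g]) for g in groups])
        L = np.atleast_2d(L)
        L -= L.max(axis=1, keepdims=True)
        P = np.exp(L)
        P /= P.sum(axis=1, keepdims=True)
        w = np.array([model.weights[g] for g in groups])
        out = pd.DataFrame(P, index=coords.index, columns=[f"P_{g}" for g in groups])
        out["score"] = 10.0 * P @ w
    else:
        raise ValidationError(f"unknown scoring method {method!r}")
    out.insert(0, "PC2", xy[:, 1])
    out.insert(0, "PC1", xy[:, 0])
    return out


def score_samples(
    model: TerrainModel, expr: ExpressionMatrix, method: str = "posterior"
) -> pd.DataFrame:
    """Project (discovery centering/loadings only) and score; no leakage."""
    coords = model.projection.transform(expr)
    return consensus_score(model, coords, method=method)


def compare_score_groups(scores: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis omnibus plus the three pairwise Mann-Whitney tests.

    Returns a tidy report with group medians and raw + BH-adjusted p-values;
    the omnibus row carries the H statistic.
    """
    meta = meta.loc[scores.index]
    by_group = {g: scores.loc[meta["group"] == g, "score"].to_numpy() for g in meta["group"].unique()}
    groups = [g for g in ("NC", "AAP", "ATAU") if g in by_group and by_group[g].size >= 2]
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups with >= 2 samples")
    H, p_omni = kruskal_wallis([by_group[g] for g in groups])
    rows = [
        {
            "comparison": "omnibus",
            "statistic": H,
            "p": p_omni,
            "median_a": np.nan,
            "median_b": np.nan,
        }
    ]
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    for a, b in pairs:
        U, p = mann_whitney_u(by_group[a], by_group[b])
        rows.append(
            {
                "comparison": f"{a}_vs_{b}",
                "statistic": U,
                "p": p,
                "median_a": float(np.median(by_group[a])),
                "median_b": float(np.median(by_group[b])),
            }
        )
    report = pd.DataFrame(rows).set_index("comparison")
    pair_mask = report.index != "omnibus"
    report["q"] = np.nan
    report.loc[pair_mask, "q"] = bh_adjust(report.loc[pair_mask, "p"].to_numpy())
    return report


def validate_clustering(
    expr_validation: ExpressionMatrix, signature_probes, meta_validation: pd.DataFrame
) -> tuple[np.ndarray, pd.Series, float]:
    """Correlation-distance average-linkage clustering of validation samples.

    Distance = 1 - Pearson correlation over the signature probes; the tree
    is cut into two clusters and the agreement rate is the best two-way
    matching accuracy of cluster labels against AA (AAP or AT/AU) vs NC.
    Returns (linkage matrix, cluster labels, agreement rate).
    """
    sub = expr_validation.subset_probes(signature_probes)
    if len(sub.samples) < 2:
        raise ValidationError("need >= 2 validation samples")
    X = sub.values.to_numpy(dtype=float).T  # sample x probe
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = pd.Series(
        hierarchy.fcluster(Z, t=2, criterion="maxclust"), index=sub.samples, name="cluster"
    )
    truth = (meta_validation.loc[sub.samples, "group"] != "NC").to_numpy()  # True = AA
    assign = labels.to_numpy() == 1
    acc = max(np.mean(assign == truth), np.mean(assign == ~truth))
    return Z, labels, float(acc)
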