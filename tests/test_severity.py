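"""PCA projection, per-group bivariate terrain, the 0-10 consensus score
and validation-set clustering."""

import numpy as np
import pandas as pd
import pytest

from aa_sigscope import severity as sev
from aa_sigscope.datatypes import ExpressionMatrix, ValidationError


def _expr(arr, prefix="p"):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"{prefix}{i}" for i in range(arr.shape[0])],
            columns=[f"s{i}" for i in range(arr.shape[1])],
        )
    )


def _meta(groups):
    return pd.DataFrame(
        {"group": groups, "gender": ["F"] * len(groups), "batch": ["B1"] * len(groups)},
        index=pd.Index([f"s{i}" for i in range(len(groups))], name="sample_id"),
    )


# --- PCA --------------------------------------------------------------------


def test_pca_loadings_orthonormal_and_variance_matches_eigh():
    rng = np.random.default_rng(0)
    expr = _expr(rng.normal(8, 1, (40, 15)))
    proj, coords = sev.project_pca(expr)
    np.testing.assert_allclose(proj.loadings.T @ proj.loadings, np.eye(2), atol=1e-8)
    # independent oracle: eigenvalues of the sample covariance of samples
    Y = expr.values.to_numpy().T
    cov = np.cov(Y.T, ddof=1)  # probe x probe
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    np.testing.assert_allclose(proj.variance_explained, eigvals[:2], rtol=1e-8)


def test_pca_degenerate_single_probe_direction():
    rng = np.random.default_rng(1)
    arr = np.full((10, 8), 5.0)
    arr[0] = rng.normal(0, 3, 8)  # variance concentrated in probe 0
    proj, coords = sev.project_pca(_expr(arr))
    assert abs(proj.loadings[0, 0]) > 0.999
    assert proj.variance_explained[1] < 1e-12


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(2)
    expr = _expr(rng.normal(8, 1, (30, 12)))
    p1, c1 = sev.project_pca(expr)
    p2, c2 = sev.project_pca(expr)
    np.testing.assert_array_equal(p1.loadings, p2.loadings)
    for k in range(2):
        j = np.argmax(np.abs(p1.loadings[:, k]))
        assert p1.loadings[j, k] > 0


def test_pca_too_few_samples():
    with pytest.raises(ValidationError):
        sev.project_pca(_expr(np.random.default_rng(0).normal(size=(5, 2))))


# --- terrain fit ------------------------------------------------------------


def _toy_model(sep=6.0):
    """Three unit-variance groups at x = 0, sep/2, sep on the PC1 axis."""
    proj = sev.PCAProjection(
        probes=pd.Index(["p0", "p1"]), center=np.zeros(2), loadings=np.eye(2),
        variance_explained=np.ones(2),
    )
    means = {"NC": np.array([0.0, 0.0]), "AAP": np.array([sep / 2, 0.0]),
             "ATAU": np.array([sep, 0.0])}
    covs = {g: np.eye(2) for g in means}
    return sev.TerrainModel(projection=proj, means=means, covariances=covs)


def test_fit_terrain_means_and_density_normalization():
    rng = np.random.default_rng(3)
    coords = pd.DataFrame(
        rng.normal(0, 1, (30, 2)), columns=["PC1", "PC2"],
        index=[f"s{i}" for i in range(30)],
    )
    meta = _meta(["NC"] * 10 + ["AAP"] * 10 + ["ATAU"] * 10)
    model = sev.fit_terrain(coords, meta, _toy_model().projection)
    for g in ("NC", "AAP", "ATAU"):
        sub = coords[(meta["group"] == g).to_numpy()]
        np.testing.assert_allclose(model.means[g], sub.mean(axis=0), atol=1e-12)
    # quadrature check: each fitted density integrates to ~1 on a wide grid
    xs = np.linspace(-8, 8, 201)
    X, Y = np.meshgrid(xs, xs)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    for g, ld in model.log_densities(pts).items():
        integral = np.exp(ld).sum() * (xs[1] - xs[0]) ** 2
        assert abs(integral - 1.0) < 1e-3, g


def test_fit_terrain_recovers_known_gaussian():
    rng = np.random.default_rng(4)
    mean = np.array([1.0, -2.0])
    cov = np.array([[2.0, 0.6], [0.6, 1.0]])
    n = 200
    draws = rng.multivariate_normal(mean, cov, size=3 * n)
    coords = pd.DataFrame(draws, columns=["PC1", "PC2"],
                          index=[f"s{i}" for i in range(3 * n)])
    meta = pd.DataFrame(
        {"group": ["NC"] * n + ["AAP"] * n + ["ATAU"] * n,
         "gender": "F", "batch": "B1"}, index=coords.index)
    model = sev.fit_terrain(coords, meta, _toy_model().projection)
    se_mean = np.sqrt(np.diag(cov) / n)
    for g in model.means:
        assert np.all(np.abs(model.means[g] - mean) < 3 * se_mean)
        assert np.all(np.abs(model.covariances[g] - cov) < 0.5)


def test_fit_terrain_small_group_rejected():
    coords = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)),
                          columns=["PC1", "PC2"], index=[f"s{i}" for i in range(5)])
    meta = _meta(["NC", "NC", "NC", "AAP", "AAP"])
    with pytest.raises(ValidationError, match="AAP"):
        sev.fit_terrain(coords, meta, _toy_model().projection)


# --- consensus score --------------------------------------------------------


def _score_point(model, x, y, method="posterior"):
    coords = pd.DataFrame([[x, y]], columns=["PC1", "PC2"], index=["q"])
    return sev.consensus_score(model, coords, method=method)["score"].iloc[0]


def test_score_equal_densities_is_five():
    """Where all three group densities are equal (equal priors) the score is
    exactly 10 * (0 + 0.5 + 1)/3 = 5; identical group Gaussians make the
    densities equal everywhere."""
    model = _toy_model(sep=0.0)  # all three groups coincide
    for x, y in [(0.0, 0.0), (2.5, -1.0), (-7.0, 3.0)]:
        assert _score_point(model, x, y) == pytest.approx(5.0, abs=1e-12)
    # NC/ATAU-symmetric point of a separated model also scores exactly 5
    assert _score_point(_toy_model(sep=6.0), 3.0, 0.0) == pytest.approx(5.0, abs=1e-12)


def test_score_boundaries():
    model = _toy_model(sep=20.0)
    assert _score_point(model, -10.0, 0.0) == pytest.approx(0.0, abs=1e-9)
    assert _score_point(model, 30.0, 0.0) == pytest.approx(10.0, abs=1e-9)


def test_score_finite_far_from_all_densities():
    """Log-density arithmetic keeps the posterior defined where every raw
    density underflows to zero."""
    model = _toy_model(sep=6.0)
    s = _score_point(model, 500.0, 500.0)
    assert np.isfinite(s) and 0.0 <= s <= 10.0


def test_score_invariant_to_common_density_rescaling():
    """Posterior normalization: multiplying every group's density by the
    same factor (e.g. shrinking all covariances jointly) cannot change the
    score where the densities stay proportional."""
    m1 = _toy_model(sep=6.0)
    xs = np.linspace(-2, 8, 21)
    for x in xs:
        log_d1 = {g: ld for g, ld in m1.log_densities(np.array([[x, 0.0]])).items()}
        shifted = {g: ld + 7.3 for g, ld in log_d1.items()}  # x const multiplier
        p1 = np.exp(np.array(list(log_d1.values())) - max(log_d1.values()))
        p2 = np.exp(np.array(list(shifted.values())) - max(shifted.values()))
        np.testing.assert_allclose(p1 / p1.sum(), p2 / p2.sum(), atol=1e-12)


def test_score_monotone_along_centroid_segment():
    model = _toy_model(sep=8.0)
    ts = np.linspace(0, 1, 50)
    scores = [_score_point(model, 8.0 * t, 0.0) for t in ts]
    assert np.all(np.diff(scores) > -1e-9)


def test_axis_method_bounded_and_monotone():
    model = _toy_model(sep=8.0)
    scores = [_score_point(model, x, 0.0, method="axis") for x in np.linspace(-5, 15, 30)]
    assert min(scores) == 0.0 and max(scores) == 10.0
    assert np.all(np.diff(scores) >= -1e-9)


def test_heldout_scoring_no_leakage(corrected_cohort):
    """A duplicated discovery sample scores identically when pushed through
    the fitted model as held-out data (discovery centering/loadings only)."""
    corr, meta, annot, sigs, truth = corrected_cohort
    proj, coords = sev.project_pca(corr)
    model = sev.fit_terrain(coords, meta, proj)
    disc = sev.consensus_score(model, coords)
    dup = corr.subset_samples([corr.samples[0]])
    held = sev.score_samples(model, dup)
    assert held["score"].iloc[0] == pytest.approx(disc["score"].iloc[0], abs=1e-12)


def test_group_comparison_trivial_and_errors():
    scores = pd.DataFrame({"score": [5.0] * 9}, index=[f"s{i}" for i in range(9)])
    meta = _meta(["NC"] * 3 + ["AAP"] * 3 + ["ATAU"] * 3)
    report = sev.compare_score_groups(scores, meta)
    assert report.loc["omnibus", "statistic"] == 0.0


# --- validation clustering --------------------------------------------------


def test_validation_clustering_separates_planted_groups():
    rng = np.random.default_rng(9)
    n_probe, n_per = 60, 12
    base = rng.normal(8, 1, (n_probe, 1))
    nc = base + rng.normal(0, 0.25, (n_probe, n_per))
    aa = base + 2.0 + rng.normal(0, 0.25, (n_probe, n_per))
    # shift only half the probes so correlation structure differs
    aa[: n_probe // 2] -= 2.0
    expr = _expr(np.hstack([nc, aa]))
    meta = _meta(["NC"] * n_per + ["ATAU"] * n_per)
    Z, labels, acc = sev.validate_clustering(expr, expr.probes, meta)
    assert acc == 1.0


def test_validation_clustering_perfect_correlation_merges_first():
    rng = np.random.default_rng(10)
    col = rng.normal(8, 1, 30)
    arr = np.column_stack([col, col * 1.0, rng.normal(8, 1, 30), rng.normal(8, 1, 30)])
    expr = _expr(arr)
    meta = _meta(["NC", "NC", "ATAU", "ATAU"])
    Z, labels, acc = sev.validate_clustering(expr, expr.probes, meta)
    # first merge joins the two perfectly correlated samples at distance ~0
    assert set(Z[0, :2].astype(int)) == {0, 1}
    assert Z[0, 2] < 1e-10
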