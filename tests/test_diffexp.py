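"""Moderated two-group model, BH adjustment, signature selection and the
shared nonparametric tests, each checked against an independent route."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aa_sigscope import diffexp as de
from aa_sigscope import synthetic as syn
from aa_sigscope.datatypes import ExpressionMatrix, ValidationError

from conftest import null_config


def _expr_from_array(arr, samples=None):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])], columns=samples)
    )


def _meta(groups, genders=None):
    n = len(groups)
    genders = genders or ["F", "M"] * (n // 2) + ["F"] * (n % 2)
    return pd.DataFrame(
        {"group": groups, "gender": genders, "batch": ["B1"] * n},
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )


# --- linear model -----------------------------------------------------------


def test_noiseless_recovery_is_exact():
    """With zero noise a planted 0.585 log2 difference (linear FC 1.5) is
    recovered exactly by the model coefficient."""
    groups = ["NC"] * 4 + ["AAP"] * 4
    base = np.full((5, 8), 8.0)
    base[:, 4:] += 0.585
    fit = de.fit_two_group_model(_expr_from_array(base), _meta(groups), de.ContrastSpec("AAP", "NC"))
    np.testing.assert_allclose(fit["effect"], 0.585, atol=1e-12)


def test_unmoderated_matches_scipy_ttest():
    """moderated=False reduces to the ordinary equal-variance t-test when no
    covariates are included."""
    from scipy import stats

    rng = np.random.default_rng(4)
    groups = ["NC"] * 10 + ["AAP"] * 12
    arr = rng.normal(8, 1, (30, 22))
    fit = de.fit_two_group_model(
        _expr_from_array(arr), _meta(groups), de.ContrastSpec("AAP", "NC", covariates=()),
        moderated=False,
    )
    t_ref, p_ref = stats.ttest_ind(arr[:, 10:], arr[:, :10], axis=1, equal_var=True)
    np.testing.assert_allclose(fit["t"], t_ref, atol=1e-10)
    np.testing.assert_allclose(fit["p"], p_ref, atol=1e-10)


def test_moderated_limits():
    """The moderated t tends to the ordinary t as d0 -> 0 and to a pooled
    z-like statistic as d0 -> inf (checked numerically on one fixture)."""
    rng = np.random.default_rng(5)
    s2 = rng.chisquare(8, 200) / 8
    df = 8.0
    eff = rng.normal(0, 1, 200)
    unscaled = 0.3

    s2_tiny = (1e-9 * 1.0 + df * s2) / (1e-9 + df)  # d0 -> 0 limit
    np.testing.assert_allclose(s2_tiny, s2, rtol=1e-8)
    t_ord = eff / (unscaled * np.sqrt(s2))
    np.testing.assert_allclose(eff / (unscaled * np.sqrt(s2_tiny)), t_ord, rtol=1e-7)

    s2_post, d0, s0 = de.squeeze_variances(s2, df)
    assert np.all((s2_post - s2) * (s0 - s2) >= -1e-12)  # shrinks toward the prior
    big = (1e12 * s0 + df * s2) / (1e12 + df)  # d0 -> inf limit: constant variance
    np.testing.assert_allclose(big, s0, rtol=1e-6)


def test_gender_covariate_unbiased(default_refs):
    """A gender effect planted orthogonally to group leaves the group effect
    unbiased within 3 Monte-Carlo SE."""
    effects = []
    for seed in range(6):
        cfg = null_config(
            seed,
            signature_effects={"CTL": (0.5, 0.5), "IFN": (0.0, 0.0), "KRT": (0.0, 0.0)},
            gender_effect_sd=0.5,
            noise_sd=0.3,
        )
        expr, meta, annot, sigs, truth = syn.simulate_cohort(cfg, default_refs)
        fit = de.fit_two_group_model(expr, meta, de.ContrastSpec("AAP", "NC"))
        ctl_probes = annot.index[
            annot["gene_symbol"].isin(truth.signature_genes["CTL"]).to_numpy()
        ]
        effects.append(fit.loc[fit.index.intersection(ctl_probes), "effect"].mean())
    arr = np.array(effects)
    se = arr.std(ddof=1) / np.sqrt(len(arr))
    assert abs(arr.mean() - 0.5) < 3 * max(se, 5e-3)


def test_design_errors():
    groups = ["NC"] * 4 + ["AAP"] * 4
    arr = np.random.default_rng(0).normal(8, 1, (5, 8))
    meta = _meta(groups, genders=["F"] * 4 + ["M"] * 4)  # gender == group
    with pytest.raises(ValidationError, match="rank"):
        de.fit_two_group_model(_expr_from_array(arr), meta, de.ContrastSpec("AAP", "NC"))
    with pytest.raises(ValidationError):
        de.ContrastSpec("NC", "NC")
    with pytest.raises(ValidationError, match="2 samples"):
        de.fit_two_group_model(
            _expr_from_array(arr[:, :5], [f"s{i}" for i in range(5)]),
            _meta(["NC"] * 4 + ["AAP"]),
            de.ContrastSpec("AAP", "NC"),
        )


# --- BH adjustment ----------------------------------------------------------


def brute_force_bh(p):
    """Literal step-up definition: q_i = min_{j >= i} p_(j) * n / j, capped."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ],
)
def test_bh_known_values(p, expected):
    np.testing.assert_allclose(de.bh_adjust(p), expected, atol=1e-12)


def test_bh_matches_brute_force_oracle():
    rng = np.random.default_rng(6)
    for _ in range(300):
        n = rng.integers(1, 60)
        p = rng.random(n) ** rng.uniform(0.5, 3)
        np.testing.assert_allclose(de.bh_adjust(p), brute_force_bh(p), atol=1e-12)


def test_bh_rejects_invalid():
    with pytest.raises(ValidationError):
        de.bh_adjust([0.5, 1.2])
    with pytest.raises(ValidationError):
        de.bh_adjust([-0.1])


# --- signature selection ----------------------------------------------------


def _results(effects, qs, ps=None):
    n = len(effects)
    return pd.DataFrame(
        {
            "effect": effects,
            "p": ps if ps is not None else qs,
            "q": qs,
        },
        index=[f"p{i}" for i in range(n)],
    )


def test_select_signature_rules():
    lfc16, lfc14, lfc30 = np.log2(1.6), np.log2(1.4), np.log2(3.0)
    res = _results([lfc16, lfc14, lfc30, -lfc16], [0.04, 0.04, 0.06, 0.01])
    up, down = de.select_signature(res)
    assert up == ["p0"]  # q .04, FC 1.6 -> in; FC 1.4 -> out; q .06 -> out
    assert down == ["p3"]


def test_select_signature_sorted_by_p_with_id_tiebreak():
    lfc = np.log2(2.0)
    res = _results([lfc, lfc, lfc], [0.01, 0.01, 0.01], ps=[0.002, 0.001, 0.002])
    up, _ = de.select_signature(res)
    assert up == ["p1", "p0", "p2"]


@given(
    fc=st.floats(min_value=1.0, max_value=3.0),
    fdr=st.floats(min_value=0.001, max_value=0.3),
)
@settings(max_examples=50, deadline=None)
def test_select_signature_monotone_in_thresholds(fc, fdr):
    """Relaxing either threshold never shrinks the selection."""
    rng = np.random.default_rng(42)
    res = _results(rng.normal(0, 1, 80), rng.random(80), ps=rng.random(80))
    up, down = de.select_signature(res, fc, fdr)
    up2, down2 = de.select_signature(res, max(1.0, fc - 0.2), min(1.0, fdr + 0.1))
    assert set(up) <= set(up2) and set(down) <= set(down2)


def test_signature_overlap_counts():
    assert de.signature_overlap([1, 2, 3], [2, 3, 4]) == (1, 2, 1)
    assert de.signature_overlap([1, 2], [1, 2]) == (0, 2, 0)
    assert de.signature_overlap([1, 2], [3]) == (2, 0, 1)


def test_contrast_nesting_on_default_cohort(corrected_cohort):
    """AAP-vs-NC probes are (qualitatively) nested inside AT/AU-vs-NC: the
    containment of AAP in AT/AU exceeds the reverse containment."""
    corr, meta, *_ = corrected_cohort
    tables = de.run_contrasts(corr, meta)
    sel = {}
    for name in ("AAP_vs_NC", "ATAU_vs_NC"):
        up, down = de.select_signature(tables[name])
        sel[name] = set(up) | set(down)
    aap, atau = sel["AAP_vs_NC"], sel["ATAU_vs_NC"]
    assert len(aap) > 0 and len(atau) > len(aap)
    assert len(aap & atau) / len(aap) > len(aap & atau) / len(atau)


# --- nonparametric tests ----------------------------------------------------


def permutation_mwu_p(a, b):
    """Exact two-sided p by enumerating all group assignments of the pooled
    ranks (tie-free inputs only)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    mu = n_a * len(b) / 2.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        r = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2.0
        total += 1
        if abs(r - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def test_mwu_hand_example():
    U, p = de.mann_whitney_u([1, 2], [3, 4])
    assert U == 0.0
    assert p == pytest.approx(1 / 3)


def test_mwu_degenerate_ties():
    U, p = de.mann_whitney_u([5, 5, 5], [5, 5])
    assert p == 1.0


def test_mwu_empty_group_rejected():
    with pytest.raises(ValidationError):
        de.mann_whitney_u([], [1.0])


def test_mwu_matches_permutation_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(40):
        n_a = int(rng.integers(2, 7))
        n_b = int(rng.integers(2, 13 - n_a))
        vals = rng.permutation(100)[: n_a + n_b].astype(float)  # distinct -> tie-free
        a, b = vals[:n_a], vals[n_a:]
        _, p = de.mann_whitney_u(a, b)
        assert p == pytest.approx(permutation_mwu_p(a, b), abs=1e-9)


def test_kruskal_wallis_basics():
    assert de.kruskal_wallis([[2, 2], [2, 2, 2]]) == (0.0, 1.0)
    with pytest.raises(ValidationError):
        de.kruskal_wallis([[1.0, 2.0]])
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 20), rng.normal(2, 1, 20)
    _, p_kw = de.kruskal_wallis([a, b])
    _, p_mw = de.mann_whitney_u(a, b)
    assert (p_kw < 0.05) == (p_mw < 0.05) == True  # noqa: E712


def test_kruskal_wallis_power_three_shifted_groups():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        groups = [rng.normal(2 * k, 1, 20) for k in range(3)]
        _, p = de.kruskal_wallis(groups)
        hits += p < 0.05
    assert hits >= 19
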