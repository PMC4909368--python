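"""Two-group differential expression with moderated variance, BH control,
fold-change/FDR signature selection, and the shared nonparametric tests.

The per-probe model is ordinary least squares of log2 expression on group +
additive covariates (gender by default). Residual variances are shrunk
across probes toward a scaled inverse-chi-square prior fitted by the method
of moments on log-variances; the moderated t uses the shrunken variance and
augmented degrees of freedom. A ``moderated=False`` switch falls back to the
ordinary t for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, ValidationError

#: pseudo-group understood by contrasts: the union of both disease groups
AA_UNION = "AA"


@dataclass
class ContrastSpec:
    """A two-group contrast; ``case='AA'`` pools AAP and ATAU."""

    case: str
    control: str
    covariates: tuple[str, ...] = ("gender",)

    def __post_init__(self) -> None:
        if self.case == self.control:
            raise ValidationError("case and control groups must differ")


def _group_mask(meta: pd.DataFrame, label: str) -> pd.Series:
    if label == AA_UNION:
        return meta["group"].isin(["AAP", "ATAU"])
    return meta["group"] == label


def _trigamma_inverse(x: float, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration on 1/y (monotone, stable)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior.

    Works on z = log(s2): E[z] and Var[z] under the model involve digamma /
    trigamma terms, which are matched to the empirical moments. Returns
    (prior df d0, prior variance s0^2); d0 = inf when the observed spread of
    log-variances is no larger than the chi-square sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:  # degenerate (e.g. noiseless) input: no shrinkage
        return 0.0, float(s2.mean())
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # log-variances no more dispersed than chi-square sampling noise:
        # infinite prior df, common variance = arithmetic mean
        d0 = np.inf
        s0_sq = float(s2[ok].mean())
    return d0, s0_sq


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-probe residual variances toward the fitted prior."""
    d0, s0_sq = fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(np.asarray(s2, dtype=float), s0_sq)
    elif d0 == 0:
        s2_post = np.asarray(s2, dtype=float)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return s2_post, d0, s0_sq


def fit_two_group_model(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    contrast: ContrastSpec,
    moderated: bool = True,
) -> pd.DataFrame:
    """Per-probe (effect, se, t, p) for case - control with covariates.

    The effect is the group coefficient on the log2 scale (a log2 fold
    change). With ``moderated=True`` the residual variance is empirically
    shrunk across probes and the t degrees of freedom augmented accordingly.
    """
    meta = meta.loc[expr.samples]
    case_mask = _group_mask(meta, contrast.case)
    ctrl_mask = _group_mask(meta, contrast.control)
    if case_mask.sum() < 2 or ctrl_mask.sum() < 2:
        raise ValidationError("need >= 2 samples in each group")
    sel = case_mask | ctrl_mask
    sub = expr.subset_samples(meta.index[sel])
    meta = meta.loc[sub.samples]

    cols = [np.ones(sel.sum()), _group_mask(meta, contrast.case).to_numpy(dtype=float)]
    names = ["intercept", f"group[{contrast.case}]"]
    for cov in contrast.covariates:
        dummies = pd.get_dummies(meta[cov].astype(str), drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(f"{cov}[{c}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"rank-deficient design; columns: {names}")
    n, p = X.shape
    df_resid = n - p
    if df_resid <= 0:
        raise ValidationError("zero residual degrees of freedom")

    Y = sub.values.to_numpy(dtype=float).T  # sample x probe
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    s2 = (resid**2).sum(axis=0) / df_resid
    unscaled = np.sqrt(XtX_inv[1, 1])
    effect = beta[1]

    if moderated:
        s2_post, d0, _ = squeeze_variances(s2, df_resid)
        df_total = df_resid + d0 if np.isfinite(d0) else np.inf
    else:
        s2_post, df_total = s2, df_resid
    se = unscaled * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {"effect": effect, "se": se, "t": t, "p": pvals},
        index=sub.probes,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(fit: pd.DataFrame, fc_threshold: float = 1.5, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Full DE result table: effect, t, p, q and an up/down/ns direction."""
    out = fit.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    lfc = np.log2(fc_threshold)
    direction = np.where(
        (out["q"] < fdr_threshold) & (out["effect"] >= lfc),
        "up",
        np.where((out["q"] < fdr_threshold) & (out["effect"] <= -lfc), "down", "ns"),
    )
    out["direction"] = direction
    return out


def select_signature(
    results: pd.DataFrame, fc_threshold: float = 1.5, fdr_threshold: float = 0.05
) -> tuple[list[str], list[str]]:
    """Probes passing both thresholds, split by sign, sorted by p (ties by id)."""
    if "q" not in results.columns:
        results = de_table(results, fc_threshold, fdr_threshold)
    lfc = np.log2(fc_threshold)
    sig = results[results["q"] < fdr_threshold]
    order = sig.assign(_id=sig.index.astype(str)).sort_values(["p", "_id"])
    up = order.index[order["effect"] >= lfc].tolist()
    down = order.index[order["effect"] <= -lfc].tolist()
    return up, down


def signature_overlap(list_a, list_b) -> tuple[int, int, int]:
    """(|a only|, |shared|, |b only|) set arithmetic."""
    a, b = set(list_a), set(list_b)
    return len(a - b), len(a & b), len(b - a)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U with mid-rank ties; exact p for small tie-free inputs.

    Exact enumeration is used when n_a + n_b <= 12 and there are no ties;
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Rank-based omnibus H with tie correction and chi-square p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def run_contrasts(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    contrasts: list[ContrastSpec] | None = None,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    moderated: bool = True,
) -> dict[str, pd.DataFrame]:
    """Run the study's standard contrasts (AA, AAP, AT/AU each vs NC)."""
    if contrasts is None:
        contrasts = [
            ContrastSpec("AA", "NC"),
            ContrastSpec("AAP", "NC"),
            ContrastSpec("ATAU", "NC"),
        ]
    out = {}
    for c in contrasts:
        fit = fit_two_group_model(expr, meta, c, moderated=moderated)
        out[f"{c.case}_vs_{c.control}"] = de_table(fit, fc_threshold, fdr_threshold)
    return out
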