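"""Probe filtering and empirical-Bayes location/scale batch correction.

Filtering removes sex-chromosome probes, vendor control probes, probes with
no gene-symbol annotation and (when detection calls are available) probes
never called present. Batch correction is the standard parametric
empirical-Bayes location/scale adjustment: probes are standardized under a
model containing batch indicators and protected biological covariates,
per-batch per-probe location and scale estimates are shrunk toward a common
prior (normal for location, inverse-gamma for scale), and the shrunken batch
parameters are removed while covariate effects are retained.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


class BatchDesignError(ValueError):
    pass


def filter_probes(expr: ExpressionMatrix, annot: pd.DataFrame) -> ExpressionMatrix:
    """Apply the annotation filters, then the present-call filter.

    Removes, in order: probes on chromosome X or Y, control probes, probes
    without a gene symbol; then, if calls are available, probes not called
    present on at least one array. Probe order is preserved; idempotent.
    """
    missing = expr.probes.difference(annot.index)
    if len(missing):
        raise AnnotationError(f"probes without annotation: {sorted(missing)[:10]}")
    ann = annot.loc[expr.probes]
    symbol = ann["gene_symbol"].fillna("").astype(str)
    keep = (
        ~ann["chromosome"].astype(str).str.upper().isin(("X", "Y"))
        & ~ann["is_control"].astype(bool)
        & (symbol.str.len() > 0)
    )
    kept = expr.probes[keep.to_numpy()]
    out = expr.subset_probes(kept)
    if out.calls is not None:
        present_any = (out.calls == "P").any(axis=1)
        out = out.subset_probes(out.probes[present_any.to_numpy()])
    return out


def _design_matrix(meta: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Intercept + treatment-coded covariate columns, full-rank checked."""
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for cov in covariates:
        dummies = pd.get_dummies(meta[cov].astype(str), drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(f"{cov}[{c}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise BatchDesignError(f"covariate design is rank deficient: columns {names}")
    return X


def batch_correct(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    covariates: list[str] = ("group", "gender"),
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ExpressionMatrix:
    """Remove batch location/scale effects while protecting covariates.

    Parametric empirical-Bayes adjustment. With a single batch the input is
    returned unchanged. Probes with zero variance within any batch are
    location-adjusted only (their scale step is skipped, logged as a count).
    """
    covariates = list(covariates)
    meta = meta.loc[expr.samples]
    batches = meta["batch"].astype(str)
    batch_labels = sorted(batches.unique())
    if len(batch_labels) == 1:
        return ExpressionMatrix(expr.values.copy(), expr.calls)
    counts = batches.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise BatchDesignError(f"batches with fewer than 2 samples: {sorted(small.index)}")
    if len(batch_labels) == len(expr.samples):
        raise BatchDesignError("every sample is its own batch; nothing can be estimated")

    Y = expr.values.to_numpy(dtype=float)  # probe x sample
    n_probe, n = Y.shape
    B = np.column_stack(
        [(batches == b).to_numpy(dtype=float) for b in batch_labels]
    )  # n x n_batch, one-hot
    X_cov = _design_matrix(meta, covariates)[:, 1:]  # drop intercept; batch dummies span it
    X = np.hstack([B, X_cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise BatchDesignError("batch and covariates are confounded (rank-deficient design)")

    # OLS fit per probe: Y' = X beta
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (n_batch + p_cov) x n_probe
    n_batches = len(batch_labels)
    batch_sizes = B.sum(axis=0)
    grand_mean = (batch_sizes / n) @ beta[:n_batches]  # weighted batch intercepts
    stand_mean = grand_mean[None, :].T @ np.ones((1, n))  # probe x sample
    if X_cov.shape[1]:
        stand_mean += (X_cov @ beta[n_batches:]).T

    resid = Y - (X @ beta).T
    var_pooled = (resid**2).mean(axis=1)  # probe-wise, ML denominator n
    zero_var = var_pooled <= 0
    if zero_var.any():
        logger.warning("%d probes have zero pooled variance; location-only adjustment", zero_var.sum())
        var_pooled = np.where(zero_var, 1.0, var_pooled)
    s = np.sqrt(var_pooled)
    Z = (Y - stand_mean) / s[:, None]

    adjusted = Z.copy()
    n_scale_skipped = 0
    for bi, b in enumerate(batch_labels):
        mask = B[:, bi].astype(bool)
        nb = int(batch_sizes[bi])
        Zb = Z[:, mask]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)

        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        # inverse-gamma moment-matched prior on the scale parameters
        m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        a_prior = (2 * s2 + m**2) / s2 if s2 > 0 else np.inf
        b_prior = (m * s2 + m**3) / s2 if s2 > 0 else np.inf

        # fixed-point iteration for the posterior location/scale per probe
        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        if tau2 > 0 and np.isfinite(a_prior):
            d_old = delta_hat.copy()
            g_old = gamma_hat.copy()
            for _ in range(max_iter):
                g_new = (tau2 * nb * gamma_hat + d_old * gamma_bar) / (tau2 * nb + d_old)
                sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (0.5 * sum2 + b_prior) / (nb / 2 + a_prior - 1)
                change = max(
                    np.abs(g_new - g_old).max(initial=0), np.abs(d_new - d_old).max(initial=0)
                )
                g_old, d_old = g_new, d_new
                if change < tol:
                    break
            gamma_star, delta_star = g_old, d_old

        degenerate = delta_hat <= 0
        n_scale_skipped += int(degenerate.sum())
        scale = np.sqrt(np.where(degenerate, 1.0, delta_star))
        adjusted[:, mask] = (Z[:, mask] - gamma_star[:, None]) / scale[:, None]

    if n_scale_skipped:
        logger.warning(
            "%d (probe, batch) cells had zero within-batch variance; scale step skipped",
            n_scale_skipped,
        )
    out = adjusted * s[:, None] + stand_mean
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.probes, columns=expr.samples), expr.calls
    )


def collapse_probes_mean(expr: ExpressionMatrix, annot: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample log2 matrix: unweighted mean of each gene's probes.

    Used where downstream analysis needs gene-level expression values (e.g.
    linear-scale mixture fitting); signature scoring instead collapses on the
    z scale (see the aladin module).
    """
    symbol = annot.loc[expr.probes, "gene_symbol"].fillna("").astype(str)
    if (symbol == "").any():
        raise ValidationError("collapse requires a gene symbol for every probe")
    return expr.values.groupby(symbol).mean()
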