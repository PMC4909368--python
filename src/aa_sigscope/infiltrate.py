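"""Immune-infiltrate quantitation from immune gene signatures (IGS).

Two estimators serve two different questions:

* ranking / separation — the per-cell-type IGS score is the mean
  control-referenced gene-level z over the cell type's marker genes (the
  same machinery as the ALADIN axes), which needs no reference profiles and
  is used for CD8 ranking and group separation tests;
* absolute burden — non-negative least squares of each sample's
  linear-scale gene expression on [skin background, cell type 1..k]
  reference profiles with coefficients normalized to the simplex; the
  infiltrate burden is 1 minus the skin coefficient.

The Th1:Th2 polarization statistic is the per-sample log2 ratio of mean
linear-scale Th1-marker to Th2-marker signal, compared AA vs NC by
Mann-Whitney U; positive values indicate Th1 skew.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .aladin import signature_scores
from .datatypes import SignatureSet, ValidationError
from .diffexp import mann_whitney_u
from .synthetic import ReferenceProfiles


def igs_score(gene_z_matrix: pd.DataFrame, signatures: SignatureSet) -> pd.DataFrame:
    """Sample x cell-type IGS score table (mean gene-level z per signature)."""
    igs_names = [
        n
        for n, r in signatures.roles.items()
        if r in ("igs_celltype", "igs_th_subset")
    ] or list(signatures.sets)
    return signature_scores(gene_z_matrix, signatures, names=igs_names)


def rank_separation(scores: pd.Series, meta: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Rank samples by one cell type's score and test group separation.

    Ranks are mid-rank-tied, 1 = highest infiltration. Pairwise Mann-Whitney
    across NC / AAP / ATAU on the ranks, with per-group median ranks.
    """
    meta = meta.loc[scores.index]
    ranks = pd.Series(
        stats.rankdata(-scores.to_numpy(), method="average"), index=scores.index, name="rank"
    )
    groups = [g for g in ("NC", "AAP", "ATAU") if (meta["group"] == g).sum() >= 2]
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups with samples to compare")
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            ra = ranks[(meta["group"] == a).to_numpy()]
            rb = ranks[(meta["group"] == b).to_numpy()]
            U, p = mann_whitney_u(ra, rb)
            rows.append(
                {
                    "comparison": f"{a}_vs_{b}",
                    "U": U,
                    "p": p,
                    "median_rank_a": float(np.median(ra)),
                    "median_rank_b": float(np.median(rb)),
                }
            )
    return ranks, pd.DataFrame(rows).set_index("comparison")


def estimate_fractions(
    expr_linear: pd.DataFrame, refs: ReferenceProfiles, min_shared_genes: int = 100
) -> pd.DataFrame:
    """Per-sample simplex-constrained mixture fit against reference profiles.

    ``expr_linear`` is a linear-scale gene x sample matrix. Each sample is
    regressed (NNLS) on the skin + cell-type profiles over the shared gene
    space; coefficients are normalized to sum to 1. Columns: one fraction
    per cell type, ``burden`` (1 - skin coefficient) and per-type
    ``share_*`` of the total burden (0 when the burden is 0).
    """
    cell_types = refs.cell_types
    shared = expr_linear.index.intersection(refs.profiles.columns)
    if len(shared) < min_shared_genes:
        raise ValidationError(
            f"only {len(shared)} genes shared with the reference profiles "
            f"(need >= {min_shared_genes})"
        )
    basis = refs.profiles[shared].loc[["skin", *cell_types]].to_numpy().T  # gene x (1+k)
    if np.linalg.matrix_rank(basis) < basis.shape[1]:
        raise ValidationError("reference basis is rank deficient")
    Y = expr_linear.loc[shared].to_numpy(dtype=float)
    rows = []
    for j in range(Y.shape[1]):
        coef, _ = nnls(basis, Y[:, j])
        total = coef.sum()
        coef = coef / total if total > 0 else coef
        burden = 1.0 - coef[0]
        shares = coef[1:] / burden if burden > 0 else np.zeros(len(cell_types))
        rows.append([*coef[1:], burden, *shares])
    cols = [*cell_types, "burden", *[f"share_{c}" for c in cell_types]]
    return pd.DataFrame(rows, index=expr_linear.columns, columns=cols)


def th_ratio(
    expr_linear: pd.DataFrame, signatures: SignatureSet, meta: pd.DataFrame
) -> tuple[pd.Series, dict]:
    """Per-sample log2(Th1 / Th2 mean marker signal) and the AA-vs-NC U-test."""
    for name in ("Th1", "Th2"):
        if name not in signatures:
            raise ValidationError(f"signature set lacks {name!r}")
    meta = meta.loc[expr_linear.columns]

    def _mean_signal(name: str) -> pd.Series:
        genes = [g for g in signatures.genes(name) if g in expr_linear.index]
        if not genes:
            raise ValidationError(f"no {name} marker genes in the matrix")
        block = expr_linear.loc[genes]
        if (block <= 0).to_numpy().any():
            raise ValidationError(
                f"non-positive {name} marker signal; input must be linear scale"
            )
        return block.mean(axis=0)

    th1, th2 = _mean_signal("Th1"), _mean_signal("Th2")
    ratio = np.log2(th1 / th2).rename("th1_th2_log_ratio")
    aa = ratio[meta["group"].isin(["AAP", "ATAU"]).to_numpy()]
    nc = ratio[(meta["group"] == "NC").to_numpy()]
    U, p = mann_whitney_u(aa, nc)
    report = {
        "U": U,
        "p": p,
        "median_AA": float(np.median(aa)),
        "median_NC": float(np.median(nc)),
        "n_AA": int(aa.size),
        "n_NC": int(nc.size),
    }
    return ratio, report
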