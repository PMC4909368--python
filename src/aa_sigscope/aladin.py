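"""Control-referenced signature z-scores (the ALADIN CTL / IFN / KRT axes).

Scoring is a three-level average: per probe, z against the mean and standard
deviation of the normal-control samples; per gene, the mean of its probes'
z-scores; per signature, the mean of its genes' z-scores. The control
reference is always built on a designated NC cohort (normally the discovery
set) and can be serialized and reused to score held-out samples without
touching their own statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SignatureSet, ValidationError
from .diffexp import mann_whitney_u

logger = logging.getLogger(__name__)


@dataclass
class ControlReference:
    """Per-probe NC mean/sd (log2 units) plus bookkeeping for reuse."""

    mean: pd.Series
    sd: pd.Series  # n-1 denominator
    nc_samples: list[str]
    dropped_probes: list[str]  # zero NC variance; excluded downstream

    def to_json_dict(self) -> dict:
        return {
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "nc_samples": self.nc_samples,
            "dropped_probes": self.dropped_probes,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ControlReference":
        return cls(
            mean=pd.Series(d["mean"], dtype=float),
            sd=pd.Series(d["sd"], dtype=float),
            nc_samples=list(d["nc_samples"]),
            dropped_probes=list(d["dropped_probes"]),
        )


def build_reference(expr: ExpressionMatrix, nc_samples) -> ControlReference:
    """Per-probe NC mean and sd; zero-variance probes are dropped, not inflated."""
    nc_samples = list(nc_samples)
    if len(nc_samples) < 3:
        raise ValidationError("need >= 3 normal-control samples for a reference")
    missing = set(nc_samples) - set(expr.samples)
    if missing:
        raise ValidationError(f"NC samples absent from matrix: {sorted(missing)}")
    nc = expr.values[nc_samples]
    mean = nc.mean(axis=1)
    sd = nc.std(axis=1, ddof=1)
    dropped = sd.index[sd <= 0].tolist()
    if dropped:
        logger.warning("%d probes dropped for zero NC variance", len(dropped))
    keep = sd.index[sd > 0]
    return ControlReference(
        mean=mean.loc[keep], sd=sd.loc[keep], nc_samples=nc_samples, dropped_probes=dropped
    )


def probe_z(expr: ExpressionMatrix, ref: ControlReference) -> pd.DataFrame:
    """z = (value - NC mean) / NC sd per probe per sample; dropped probes absent."""
    missing = ref.mean.index.difference(expr.probes)
    if len(missing):
        raise ValidationError(f"reference probes absent from matrix: {list(missing[:5])}")
    vals = expr.values.loc[ref.mean.index]
    return vals.sub(ref.mean, axis=0).div(ref.sd, axis=0)


def gene_z(z: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample z: unweighted mean over each gene's probes."""
    symbol = annot.loc[z.index, "gene_symbol"].fillna("").astype(str)
    if (symbol == "").any():
        raise ValidationError("every probe must map to exactly one gene symbol")
    return z.groupby(symbol).mean()


def signature_scores(
    gene_z_matrix: pd.DataFrame, signatures: SignatureSet, names=None, min_coverage: float = 0.5
) -> pd.DataFrame:
    """Sample x signature table: mean gene-level z over each signature's genes.

    Shared machinery for ALADIN and IGS scoring. Genes absent from the matrix
    are skipped with a warning; a signature below ``min_coverage`` available
    genes raises, and one with no genes at all always raises.
    """
    names = list(names) if names is not None else list(signatures.sets)
    out = {}
    for name in names:
        genes = signatures.genes(name)
        avail = [g for g in genes if g in gene_z_matrix.index]
        if not avail:
            raise ValidationError(f"signature {name!r} has no genes in the matrix")
        if len(avail) < min_coverage * len(genes):
            raise ValidationError(
                f"signature {name!r}: only {len(avail)}/{len(genes)} genes available"
            )
        if len(avail) < len(genes):
            logger.warning(
                "signature %s: %d/%d genes missing from matrix",
                name,
                len(genes) - len(avail),
                len(genes),
            )
        out[name] = gene_z_matrix.loc[avail].mean(axis=0)
    return pd.DataFrame(out)


def aladin_scores(
    gene_z_matrix: pd.DataFrame, signatures: SignatureSet, meta: pd.DataFrame | None = None
) -> pd.DataFrame:
    """The three-axis CTL / IFN / KRT table, one row per sample.

    Signature names are resolved by role tag when present (aladin_ctl /
    aladin_ifn / aladin_krt), falling back to literal CTL / IFN / KRT names.
    Group and disease-duration columns are attached when metadata is given.
    """
    name_by_role = {}
    for role, fallback in (("aladin_ctl", "CTL"), ("aladin_ifn", "IFN"), ("aladin_krt", "KRT")):
        tagged = list(signatures.by_role(role))
        if tagged:
            name_by_role[fallback] = tagged[0]
        elif fallback in signatures:
            name_by_role[fallback] = fallback
        else:
            raise ValidationError(f"no signature found for role {role}")
    scores = signature_scores(gene_z_matrix, signatures, names=list(name_by_role.values()))
    scores.columns = list(name_by_role.keys())
    if meta is not None:
        scores = scores.join(meta[["group"]], how="left")
        if "duration_years" in meta.columns:
            scores = scores.join(meta[["duration_years"]], how="left")
    return scores


def duration_comparison(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    threshold_years: float = 5.0,
    group: str = "ATAU",
) -> pd.DataFrame:
    """Long- vs short-duration comparison of the ALADIN axes within a group.

    Samples with duration >= threshold are 'long' (a duration of exactly the
    threshold counts as long). Mann-Whitney on IFN and CTL (primary) and KRT
    (secondary), with per-stratum medians.
    """
    meta = meta.loc[scores.index]
    in_group = meta["group"] == group
    dur = meta.loc[in_group, "duration_years"]
    if dur.isna().any():
        raise ValidationError(f"missing disease duration for samples in group {group}")
    long_mask = dur >= threshold_years
    if long_mask.sum() == 0 or (~long_mask).sum() == 0:
        empty = "long" if long_mask.sum() == 0 else "short"
        raise ValidationError(f"empty {empty!r} duration stratum in group {group}")
    rows = []
    for axis, secondary in (("IFN", False), ("CTL", False), ("KRT", True)):
        x = scores.loc[in_group, axis]
        long_v, short_v = x[long_mask.to_numpy()], x[~long_mask.to_numpy()]
        U, p = mann_whitney_u(long_v, short_v)
        rows.append(
            {
                "axis": axis,
                "secondary": secondary,
                "n_long": int(long_mask.sum()),
                "n_short": int((~long_mask).sum()),
                "median_long": float(np.median(long_v)),
                "median_short": float(np.median(short_v)),
                "U": U,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("axis")
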