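"""Core in-memory containers shared by every pipeline stage.

All matrices are pandas DataFrames: expression is probes x samples on the
log2 scale, annotation and metadata are row-per-probe / row-per-sample
tables. The thin dataclass wrappers exist to carry validated invariants
(aligned calls, closed vocabularies) rather than to hide pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("NC", "AAP", "ATAU")
GENDERS = ("F", "M")

#: role tags for gene signatures
ALADIN_ROLES = ("aladin_ctl", "aladin_ifn", "aladin_krt")
IGS_ROLES = ("igs_celltype", "igs_th_subset")


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


@dataclass
class ExpressionMatrix:
    """Log2 probe x sample expression with optional present/absent calls.

    ``values``: DataFrame indexed by probe id, columns = sample ids.
    ``calls``: optional DataFrame of 'P'/'A' flags, identically indexed.
    """

    values: pd.DataFrame
    calls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate probe ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.calls is not None:
            if not self.calls.index.equals(self.values.index) or not self.calls.columns.equals(
                self.values.columns
            ):
                raise ValidationError("present/absent calls do not align with values")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probes) -> "ExpressionMatrix":
        probes = pd.Index(probes)
        missing = probes.difference(self.values.index)
        if len(missing):
            raise ValidationError(f"probes absent from matrix: {list(missing[:5])}...")
        calls = self.calls.loc[probes] if self.calls is not None else None
        return ExpressionMatrix(self.values.loc[probes], calls)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        calls = self.calls[samples] if self.calls is not None else None
        return ExpressionMatrix(self.values[samples], calls)


def validate_probe_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Check the probe annotation table (index = probe id).

    Required columns: ``gene_symbol`` (empty string / NaN = unannotated),
    ``chromosome``, ``is_control`` (bool).
    """
    if annot.index.has_duplicates:
        raise ValidationError("duplicate probe ids in annotation")
    for col in ("gene_symbol", "chromosome", "is_control"):
        if col not in annot.columns:
            raise ValidationError(f"annotation missing column {col!r}")
    return annot


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the sample metadata table (index = sample id).

    Required columns: ``group`` in {NC, AAP, ATAU}, ``gender`` in {F, M},
    ``batch``; optional ``duration_years`` (NaN allowed for NC).
    """
    if meta.index.has_duplicates:
        raise ValidationError("duplicate sample ids in metadata")
    bad_groups = set(meta["group"]) - set(GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown groups: {sorted(bad_groups)}")
    bad_genders = set(meta["gender"]) - set(GENDERS)
    if bad_genders:
        raise ValidationError(f"unknown genders: {sorted(bad_genders)}")
    if "duration_years" in meta.columns:
        dur = meta["duration_years"].dropna()
        if (dur < 0).any():
            raise ValidationError("negative disease duration")
    return meta


@dataclass
class SignatureSet:
    """Named gene sets with role tags.

    ``sets`` maps signature name -> gene symbol list; ``roles`` maps name ->
    one of the ALADIN roles (ctl/ifn/krt), 'igs_celltype' or 'igs_th_subset'.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"signature {name!r} has an empty gene list")

    def genes(self, name: str) -> list[str]:
        return self.sets[name]

    def by_role(self, role: str) -> dict[str, list[str]]:
        return {n: g for n, g in self.sets.items() if self.roles.get(n) == role}

    def __contains__(self, name: str) -> bool:
        return name in self.sets
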