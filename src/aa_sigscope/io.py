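"""Readers and writers for the pipeline's tab-delimited interchange files.

Formats:
  expr.tsv    probes x samples, first column 'probe_id', header = sample ids
  calls.tsv   'P'/'A' flags, same shape as expr.tsv
  probes.tsv  probe_id, gene_symbol, chromosome, is_control
  samples.tsv sample_id, group, gender, batch, duration_years
  *.gmt       one gene set per line: name<TAB>description<TAB>gene1<TAB>...
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    SignatureSet,
    validate_probe_annotation,
    validate_sample_metadata,
)


def read_expression(expr_path, calls_path=None) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index.name = "probe_id"
    values.columns.name = "sample_id"
    calls = None
    if calls_path is not None and Path(calls_path).exists():
        calls = pd.read_csv(calls_path, sep="\t", index_col=0)
        calls.index.name = "probe_id"
        calls.columns.name = "sample_id"
    return ExpressionMatrix(values, calls)


def write_expression(expr: ExpressionMatrix, expr_path, calls_path=None) -> None:
    # default float formatting is shortest-repr, so float64 round-trips exactly
    expr.values.to_csv(expr_path, sep="\t", index_label="probe_id")
    if expr.calls is not None and calls_path is not None:
        expr.calls.to_csv(calls_path, sep="\t", index_label="probe_id")


def read_probe_annotation(path) -> pd.DataFrame:
    annot = pd.read_csv(
        path, sep="\t", index_col=0, dtype={"chromosome": str}, keep_default_na=False
    )
    annot.index.name = "probe_id"
    annot["is_control"] = annot["is_control"].astype(str).str.lower().isin(("true", "1"))
    return validate_probe_annotation(annot)


def write_probe_annotation(annot: pd.DataFrame, path) -> None:
    validate_probe_annotation(annot).to_csv(path, sep="\t", index_label="probe_id")


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={"batch": str})
    meta.index.name = "sample_id"
    return validate_sample_metadata(meta)


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    validate_sample_metadata(meta).to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path, roles: dict[str, str] | None = None) -> SignatureSet:
    """Parse a GMT file; role tags are read from the description field when
    it starts with 'role=', else taken from the ``roles`` mapping."""
    sets: dict[str, list[str]] = {}
    parsed_roles: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (needs name, description, >=1 gene): {line!r}")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            sets[name] = genes
            if desc.startswith("role="):
                parsed_roles[name] = desc[len("role="):]
    if roles:
        parsed_roles.update(roles)
    return SignatureSet(sets=sets, roles=parsed_roles)


def write_gmt(signatures: SignatureSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in signatures.sets.items():
            desc = f"role={signatures.roles[name]}" if name in signatures.roles else "na"
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
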