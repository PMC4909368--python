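"""End-to-end orchestration: simulate -> preprocess -> DE -> severity ->
ALADIN -> infiltrate, with every intermediate kept for inspection.

This is the single entry point the analysis drivers and the acceptance
script share; given one :class:`~aa_sigscope.synthetic.SimulationConfig`
the whole run is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import aladin as al
from . import diffexp as de
from . import infiltrate as inf
from . import preprocess as pp
from . import severity as sev
from . import synthetic as syn
from .datatypes import ExpressionMatrix, SignatureSet


@dataclass
class PipelineResult:
    expr_raw: ExpressionMatrix
    expr: ExpressionMatrix  # filtered + batch-corrected
    meta: pd.DataFrame
    annot: pd.DataFrame
    signatures: SignatureSet
    truth: syn.GroundTruth
    de_tables: dict[str, pd.DataFrame]
    signature_probes: list[str]  # up + down of the AA-vs-NC contrast
    terrain: sev.TerrainModel
    severity_scores: pd.DataFrame
    severity_report: pd.DataFrame
    aladin_scores: pd.DataFrame
    igs_scores: pd.DataFrame
    cd8_report: pd.DataFrame
    fractions: pd.DataFrame
    th_ratio: pd.Series
    th_report: dict


def run_pipeline(
    config: syn.SimulationConfig,
    refs: syn.ReferenceProfiles | None = None,
    batch_correct: bool = True,
) -> PipelineResult:
    if refs is None:
        refs = syn.generate_reference_profiles(n_genes=config.n_genes, seed=config.seed)
    expr_raw, meta, annot, sigs, truth = syn.simulate_cohort(config, refs)

    expr = pp.filter_probes(expr_raw, annot)
    if batch_correct:
        expr = pp.batch_correct(expr, meta)

    de_tables = de.run_contrasts(expr, meta)
    up, down = de.select_signature(de_tables["AA_vs_NC"])
    signature_probes = up + down

    proj, coords = sev.project_pca(expr, signature_probes or None)
    terrain = sev.fit_terrain(coords, meta, proj)
    severity_scores = sev.consensus_score(terrain, coords)
    severity_report = sev.compare_score_groups(severity_scores, meta)

    nc = list(meta.index[meta["group"] == "NC"])
    ref = al.build_reference(expr, nc)
    gz = al.gene_z(al.probe_z(expr, ref), annot)
    aladin_scores = al.aladin_scores(gz, sigs, meta)
    igs = inf.igs_score(gz, sigs)
    _, cd8_report = inf.rank_separation(igs["CD8T"], meta)

    gene_linear = 2.0 ** pp.collapse_probes_mean(expr, annot)
    fractions = inf.estimate_fractions(gene_linear, refs)
    ratio, th_report = inf.th_ratio(gene_linear, sigs, meta)

    return PipelineResult(
        expr_raw=expr_raw,
        expr=expr,
        meta=meta,
        annot=annot,
        signatures=sigs,
        truth=truth,
        de_tables=de_tables,
        signature_probes=signature_probes,
        terrain=terrain,
        severity_scores=severity_scores,
        severity_report=severity_report,
        aladin_scores=aladin_scores,
        igs_scores=igs,
        cd8_report=cd8_report,
        fractions=fractions,
        th_ratio=ratio,
        th_report=th_report,
    )
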