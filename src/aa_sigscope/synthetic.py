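"""Synthetic microarray-like cohort generator with full ground-truth bookkeeping.

The generator emulates a three-group scalp-biopsy cohort (NC / AAP / AT-AU)
on an Affymetrix-like probe structure: multiple probes per gene with fixed
probe offsets, control probes, sex-chromosome probes, present/absent calls.
Biology is planted at three levels:

* immune-cell admixture — per sample, linear-scale expression is a convex
  mixture of a skin background profile and immune-cell reference profiles at
  small fractions (order 0.5-2% total), so marker signal dilutes the way a
  sparse infiltrate does in a bulk biopsy;
* disease signature shifts — additive log2 shifts on designated CTL / IFN /
  KRT signature genes, graded by group (AT/AU stronger than AAP) and
  optionally attenuated in long-duration AT/AU disease;
* nuisance structure — additive batch and gender effects plus i.i.d.
  Gaussian log2 noise.

Everything drawn is recorded in :class:`GroundTruth` so downstream stages
can be scored as parameter-recovery problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .datatypes import ExpressionMatrix, SignatureSet

DEFAULT_CELL_TYPES = ("CD8T", "NK", "Th1", "Th2")

#: default planted infiltrate fractions; totals 0.2% (NC), 0.8% (AAP) and
#: 1.45% (AT/AU), CD8-dominated in disease, Th1 skewed 2:1 over Th2 in AA.
DEFAULT_FRACTIONS = {
    "NC": {"CD8T": 0.0, "NK": 0.0005, "Th1": 0.0005, "Th2": 0.0005},
    "AAP": {"CD8T": 0.0055, "NK": 0.001, "Th1": 0.001, "Th2": 0.0005},
    "ATAU": {"CD8T": 0.0105, "NK": 0.001, "Th1": 0.002, "Th2": 0.001},
}

DEFAULT_SIGNATURE_EFFECTS = {
    "CTL": (0.6, 1.2),
    "IFN": (0.5, 1.0),
    "KRT": (-0.5, -1.0),
}


class GenerationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort; the seed fully determines output.

    Signature effects are (delta_AAP, delta_ATAU) log2 shifts; CTL/IFN rise
    and KRT falls with disease, AT/AU shifts exceed AAP shifts in magnitude.
    Fractions are unitless mixture weights per immune cell type.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"NC": 23, "AAP": 20, "ATAU": 20}
    )
    n_genes: int = 2000
    probes_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
    )
    n_control_probes: int = 20
    n_sexchrom_probes: int = 40
    signature_sizes: dict[str, int] = field(
        default_factory=lambda: {"CTL": 25, "IFN": 25, "KRT": 25}
    )
    signature_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURE_EFFECTS)
    )
    infiltrate_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_FRACTIONS.items()}
    )
    fraction_cv: float = 0.2
    n_batches: int = 2
    batch_mean_shift: dict[str, float] | None = None
    batch_shift_sd: float = 0.2
    gender_effect_sd: float = 0.1
    probe_offset_sd: float = 0.3
    noise_sd: float = 0.4
    absent_rate: float = 0.01
    duration_range: tuple[float, float] = (0.0, 12.0)
    #: multiplier applied to CTL and IFN shifts for AT/AU samples with
    #: duration >= 5 years (None = no duration dependence)
    long_duration_attenuation: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_per_group.values()):
            raise GenerationError("all group sizes must be positive")
        if self.n_genes <= 0 or self.n_control_probes < 0 or self.n_sexchrom_probes < 0:
            raise GenerationError("counts must be positive")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")
        if not set(self.probes_per_gene) <= {1, 2, 3, 4}:
            raise GenerationError("probes_per_gene support must be within 1..4")
        for g, fr in self.infiltrate_fractions.items():
            total = sum(fr.values())
            if total >= 1 or any(f < 0 or f > 0.05 for f in fr.values()):
                raise GenerationError(f"invalid fractions for group {g}")
        for sig, (d_aap, d_atau) in self.signature_effects.items():
            if abs(d_atau) < abs(d_aap):
                raise GenerationError(f"|delta_ATAU| must be >= |delta_AAP| for {sig}")


@dataclass
class ReferenceProfiles:
    """Linear-scale mean expression of immune cell types plus skin background.

    ``profiles``: DataFrame rows = cell types + 'skin', columns = genes.
    ``markers``: cell type -> genes strongly expressed in exactly that type.
    ``dominance``: guaranteed minimum ratio of a marker's expression in its
    own type to its expression in any other profile.
    """

    profiles: pd.DataFrame
    markers: dict[str, list[str]]
    dominance: float = 4.0

    @property
    def cell_types(self) -> list[str]:
        return [c for c in self.profiles.index if c != "skin"]

    @property
    def skin(self) -> pd.Series:
        return self.profiles.loc["skin"]


@dataclass
class GroundTruth:
    """Everything the generator drew, for parameter-recovery scoring."""

    fractions: pd.DataFrame  # sample x cell type
    signature_genes: dict[str, list[str]]
    signature_deltas: dict[str, dict[str, float]]  # signature -> group -> log2 shift
    signature_scale: pd.Series  # per-sample multiplier on CTL/IFN shifts (duration decay)
    batch_effects: pd.DataFrame  # batch x probe additive log2 shifts
    gender_effects: pd.Series  # per-gene additive log2 shift for gender M
    probe_offsets: pd.Series  # per-probe fixed log2 offset
    de_genes: list[str]  # truly differential genes (union of signature genes)

    def to_json_dict(self) -> dict:
        return {
            "fractions": {s: row.to_dict() for s, row in self.fractions.iterrows()},
            "signature_genes": self.signature_genes,
            "signature_deltas": self.signature_deltas,
            "signature_scale": self.signature_scale.to_dict(),
            "batch_effects": {b: row.to_dict() for b, row in self.batch_effects.iterrows()},
            "gender_effects": self.gender_effects.to_dict(),
            "probe_offsets": self.probe_offsets.to_dict(),
            "de_genes": self.de_genes,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            fractions=pd.DataFrame.from_dict(d["fractions"], orient="index"),
            signature_genes={k: list(v) for k, v in d["signature_genes"].items()},
            signature_deltas={
                k: {g: float(x) for g, x in v.items()} for k, v in d["signature_deltas"].items()
            },
            signature_scale=pd.Series(d["signature_scale"], dtype=float),
            batch_effects=pd.DataFrame.from_dict(d["batch_effects"], orient="index"),
            gender_effects=pd.Series(d["gender_effects"], dtype=float),
            probe_offsets=pd.Series(d["probe_offsets"], dtype=float),
            de_genes=list(d["de_genes"]),
        )

    def equals(self, other: "GroundTruth", tol: float = 1e-9) -> bool:
        """Value equality up to row/column ordering (JSON round-trips sort keys)."""
        try:
            for mine, theirs in (
                (self.fractions, other.fractions),
                (self.batch_effects, other.batch_effects),
            ):
                pd.testing.assert_frame_equal(
                    mine,
                    theirs.reindex(index=mine.index, columns=mine.columns),
                    atol=tol,
                    check_names=False,
                )
            for mine, theirs in (
                (self.signature_scale, other.signature_scale),
                (self.gender_effects, other.gender_effects),
                (self.probe_offsets, other.probe_offsets),
            ):
                pd.testing.assert_series_equal(
                    mine, theirs.reindex(mine.index), atol=tol, check_names=False
                )
        except AssertionError:
            return False
        return (
            self.signature_genes == other.signature_genes
            and self.signature_deltas == other.signature_deltas
            and self.de_genes == other.de_genes
        )


def generate_reference_profiles(
    cell_types=DEFAULT_CELL_TYPES,
    n_genes: int = 2000,
    markers_per_type: int = 6,
    seed: int = 0,
    dominance: float = 8.0,
) -> ReferenceProfiles:
    """Build linear-scale reference profiles with dominant marker genes.

    Markers are nearly silent in skin and in the other immune profiles
    (log2 level ~3-5) and strongly expressed in their own type (log2 ~12-14),
    emulating how e.g. CD8A behaves in a scalp biopsy; non-marker genes track
    the skin background so identifiability rests on the markers.
    """
    cell_types = list(cell_types)
    if markers_per_type * len(cell_types) > n_genes:
        raise GenerationError(
            f"{markers_per_type} markers x {len(cell_types)} cell types exceeds {n_genes} genes"
        )
    if dominance < 4.0:
        raise GenerationError("marker dominance factor must be >= 4")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    skin_log2 = rng.uniform(5.0, 10.0, size=n_genes)
    profiles = {"skin": 2.0 ** skin_log2}
    for ct in cell_types:
        profiles[ct] = 2.0 ** (skin_log2 + rng.normal(0.0, 0.5, size=n_genes))
    prof = pd.DataFrame(profiles, index=genes).T

    marker_pool = rng.permutation(n_genes)[: markers_per_type * len(cell_types)]
    markers: dict[str, list[str]] = {}
    for i, ct in enumerate(cell_types):
        idx = marker_pool[i * markers_per_type : (i + 1) * markers_per_type]
        mg = [genes[j] for j in sorted(idx)]
        markers[ct] = mg
        # silence the marker everywhere, then overexpress in the owning type
        prof.loc[:, mg] = 2.0 ** rng.uniform(3.0, 5.0, size=(len(prof), len(mg)))
        own = 2.0 ** rng.uniform(12.0, 14.0, size=len(mg))
        floor = dominance * prof.drop(index=ct).loc[:, mg].max(axis=0).to_numpy()
        prof.loc[ct, mg] = np.maximum(own, floor)
    return ReferenceProfiles(profiles=prof, markers=markers, dominance=dominance)


def _sample_ids(n_per_group: dict[str, int]) -> tuple[list[str], list[str]]:
    ids, groups = [], []
    for g in ("NC", "AAP", "ATAU"):
        for i in range(n_per_group.get(g, 0)):
            ids.append(f"{g}{i + 1:02d}")
            groups.append(g)
    return ids, groups


def simulate_cohort(
    config: SimulationConfig, refs: ReferenceProfiles
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SignatureSet, GroundTruth]:
    """Draw one cohort under the planted generative model.

    Per sample: linear mixture of skin + immune profiles at the planted
    fractions, log2, additive signature / batch / gender effects, probe
    expansion with fixed offsets, Gaussian noise, present/absent calls.
    """
    config.validate()
    for g, fr in config.infiltrate_fractions.items():
        missing = set(fr) - set(refs.cell_types)
        if missing:
            raise GenerationError(f"reference profiles missing cell types: {sorted(missing)}")
    if len(refs.profiles.columns) != config.n_genes:
        raise GenerationError("reference profiles do not match config.n_genes")

    rng = np.random.default_rng(config.seed)
    genes = list(refs.profiles.columns)
    cell_types = refs.cell_types
    sample_ids, sample_groups = _sample_ids(config.n_per_group)
    n_samples = len(sample_ids)

    # --- metadata ---------------------------------------------------------
    genders = rng.choice(["F", "M"], size=n_samples)
    batches = []
    counter: dict[str, int] = {}
    for g in sample_groups:  # round-robin within group keeps batches balanced
        k = counter.get(g, 0)
        batches.append(f"B{k % config.n_batches + 1}")
        counter[g] = k + 1
    durations = np.where(
        np.array(sample_groups) == "NC",
        np.nan,
        np.round(rng.uniform(*config.duration_range, size=n_samples), 2),
    )
    meta = pd.DataFrame(
        {
            "group": sample_groups,
            "gender": genders,
            "batch": batches,
            "duration_years": durations,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- admixture fractions ---------------------------------------------
    frac = np.zeros((n_samples, len(cell_types)))
    for i, (sid, g) in enumerate(zip(sample_ids, sample_groups)):
        for j, ct in enumerate(cell_types):
            mean = config.infiltrate_fractions.get(g, {}).get(ct, 0.0)
            frac[i, j] = max(0.0, rng.normal(mean, config.fraction_cv * mean)) if mean > 0 else 0.0
        if frac[i].sum() >= 1:
            raise GenerationError(f"planted fractions sum to >= 1 for sample {sid}")
    fractions = pd.DataFrame(frac, index=meta.index, columns=cell_types)

    # --- linear mixing, then log2 ----------------------------------------
    ref_mat = refs.profiles.loc[cell_types].to_numpy()  # celltype x gene
    skin = refs.skin.to_numpy()
    linear = (1.0 - frac.sum(axis=1))[:, None] * skin[None, :] + frac @ ref_mat
    gene_log2 = np.log2(linear).T  # gene x sample

    # --- signature genes and planted shifts -------------------------------
    marker_genes = {g for mg in refs.markers.values() for g in mg}
    free = [g for g in genes if g not in marker_genes]
    order = rng.permutation(len(free))
    signature_genes: dict[str, list[str]] = {}
    pos = 0
    for sig, size in config.signature_sizes.items():
        chosen = sorted(free[k] for k in order[pos : pos + size])
        if len(chosen) < size:
            raise GenerationError("not enough non-marker genes for signatures")
        signature_genes[sig] = chosen
        pos += size

    signature_deltas = {
        sig: {"NC": 0.0, "AAP": float(d[0]), "ATAU": float(d[1])}
        for sig, d in config.signature_effects.items()
    }
    scale = pd.Series(1.0, index=meta.index)
    if config.long_duration_attenuation is not None:
        long_atau = (meta["group"] == "ATAU") & (meta["duration_years"] >= 5.0)
        scale[long_atau] = config.long_duration_attenuation

    gene_index = pd.Index(genes)
    for sig, by_group in signature_deltas.items():
        rows = gene_index.get_indexer(signature_genes[sig])
        deltas = np.array([by_group[g] for g in sample_groups])
        if sig in ("CTL", "IFN"):
            deltas = deltas * scale.to_numpy()
        gene_log2[np.ix_(rows, np.arange(n_samples))] += deltas[None, :]

    # --- gender effect (additive on gene level, reference level F) --------
    gender_eff = pd.Series(
        rng.normal(0.0, config.gender_effect_sd, size=len(genes)) if config.gender_effect_sd > 0
        else np.zeros(len(genes)),
        index=gene_index,
    )
    gene_log2 += np.outer(gender_eff.to_numpy(), (genders == "M").astype(float))

    # --- probe expansion ---------------------------------------------------
    supp = sorted(config.probes_per_gene)
    probs = np.array([config.probes_per_gene[k] for k in supp], dtype=float)
    probs /= probs.sum()
    n_probes_per_gene = rng.choice(supp, size=len(genes), p=probs)

    probe_ids, probe_gene_rows, probe_gene, probe_chrom, probe_ctrl = [], [], [], [], []
    autosomes = rng.integers(1, 23, size=len(genes))
    for gi, g in enumerate(genes):
        for k in range(n_probes_per_gene[gi]):
            probe_ids.append(f"{g}_{k}_at")
            probe_gene_rows.append(gi)
            probe_gene.append(g)
            probe_chrom.append(str(autosomes[gi]))
            probe_ctrl.append(False)
    n_gene_probes = len(probe_ids)
    values = gene_log2[probe_gene_rows, :].copy()

    offsets = rng.normal(0.0, config.probe_offset_sd, size=n_gene_probes)
    values += offsets[:, None]

    # sex-chromosome probes: one probe per pseudo-gene, strong gender signal
    sex_vals = rng.normal(7.0, 1.0, size=config.n_sexchrom_probes)[:, None] + np.zeros(
        (1, n_samples)
    )
    # sex-linked dimorphic signal; disabled with the rest of the gender
    # structure when gender_effect_sd = 0 (null generator)
    sex_shift = rng.normal(1.0, 0.3, size=config.n_sexchrom_probes)
    if config.gender_effect_sd > 0:
        sex_vals += np.outer(sex_shift, (genders == "M").astype(float))
    for i in range(config.n_sexchrom_probes):
        probe_ids.append(f"SX{i:03d}_at")
        probe_gene.append(f"SXG{i:03d}")
        probe_chrom.append("X" if i % 2 == 0 else "Y")
        probe_ctrl.append(False)

    ctrl_vals = rng.normal(8.0, 0.5, size=config.n_control_probes)[:, None] + np.zeros(
        (1, n_samples)
    )
    for i in range(config.n_control_probes):
        probe_ids.append(f"AFFX-CTRL{i:03d}_at")
        probe_gene.append("")
        probe_chrom.append("na")
        probe_ctrl.append(True)

    values = np.vstack([values, sex_vals, ctrl_vals])
    all_offsets = np.concatenate(
        [offsets, np.zeros(config.n_sexchrom_probes + config.n_control_probes)]
    )

    # --- batch effects (per probe, per batch) ------------------------------
    batch_labels = sorted(set(batches))
    mean_shift = config.batch_mean_shift or {}
    batch_eff = pd.DataFrame(
        {
            b: rng.normal(mean_shift.get(b, 0.0), config.batch_shift_sd, size=len(probe_ids))
            if config.batch_shift_sd > 0
            else np.full(len(probe_ids), mean_shift.get(b, 0.0))
            for b in batch_labels
        },
        index=pd.Index(probe_ids, name="probe_id"),
    ).T
    for j, b in enumerate(batches):
        values[:, j] += batch_eff.loc[b].to_numpy()

    # --- noise and calls ----------------------------------------------------
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)
    calls = np.where(rng.random(values.shape) < config.absent_rate, "A", "P")

    probe_index = pd.Index(probe_ids, name="probe_id")
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=probe_index, columns=meta.index),
        pd.DataFrame(calls, index=probe_index, columns=meta.index),
    )
    annot = pd.DataFrame(
        {"gene_symbol": probe_gene, "chromosome": probe_chrom, "is_control": probe_ctrl},
        index=probe_index,
    )

    sets = dict(signature_genes)
    roles = {"CTL": "aladin_ctl", "IFN": "aladin_ifn", "KRT": "aladin_krt"}
    for ct, mg in refs.markers.items():
        sets[ct] = list(mg)
        roles[ct] = "igs_th_subset" if ct in ("Th1", "Th2") else "igs_celltype"
    signatures = SignatureSet(sets=sets, roles=roles)

    truth = GroundTruth(
        fractions=fractions,
        signature_genes=signature_genes,
        signature_deltas=signature_deltas,
        signature_scale=scale,
        batch_effects=batch_eff,
        gender_effects=gender_eff,
        probe_offsets=pd.Series(all_offsets, index=probe_index),
        de_genes=sorted({g for gl in signature_genes.values() for g in gl}),
    )
    return expr, meta, annot, signatures, truth


def write_fixture(dataset, directory) -> dict[str, Path]:
    """Write a simulated cohort to tab-delimited / GMT / JSON files.

    ``dataset`` is the 5-tuple returned by :func:`simulate_cohort`. Files
    round-trip losslessly through this module's readers.
    """
    expr, meta, annot, signatures, truth = dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": directory / "expr.tsv",
        "calls": directory / "calls.tsv",
        "samples": directory / "samples.tsv",
        "probes": directory / "probes.tsv",
        "signatures": directory / "signatures.gmt",
        "truth": directory / "truth.json",
    }
    sio.write_expression(expr, paths["expr"], paths["calls"])
    sio.write_sample_metadata(meta, paths["samples"])
    sio.write_probe_annotation(annot, paths["probes"])
    sio.write_gmt(signatures, paths["signatures"])
    sio.write_json(truth.to_json_dict(), paths["truth"])
    return paths


def read_fixture(directory):
    """Load a cohort previously written by :func:`write_fixture`."""
    directory = Path(directory)
    expr = sio.read_expression(directory / "expr.tsv", directory / "calls.tsv")
    meta = sio.read_sample_metadata(directory / "samples.tsv")
    annot = sio.read_probe_annotation(directory / "probes.tsv")
    signatures = sio.read_gmt(directory / "signatures.gmt")
    truth = GroundTruth.from_json_dict(sio.read_json(directory / "truth.json"))
    return expr, meta, annot, signatures, truth
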