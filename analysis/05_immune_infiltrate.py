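"""Immune infiltrate quantitation: IGS scores, CD8 ranking, mixture-based
burden, and the Th1:Th2 polarization test.

Per-cell-type IGS scores (mean NC-referenced gene z over marker panels)
rank patients by CD8 infiltration and test group separation; non-negative
least squares against the reference profiles turns linear-scale gene
expression into absolute per-cell-type fractions and a total burden, which
is compared against the generator's planted truth; the per-sample
log2(Th1/Th2) marker-signal ratio is tested AA vs NC.

Run after 02:  python analysis/05_immune_infiltrate.py [--out results]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from aa_sigscope import aladin as al
from aa_sigscope import infiltrate as inf
from aa_sigscope import io as sio
from aa_sigscope import preprocess as pp
from aa_sigscope import synthetic as syn


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.out / "data"

    expr = sio.read_expression(data / "discovery" / "expr_corrected.tsv")
    _, meta, annot, sigs, truth = syn.read_fixture(data / "discovery")
    profiles = pd.read_csv(data / "refs.tsv", sep="\t", index_col=0).T
    markers = {n: g for n, g in sigs.sets.items() if sigs.roles.get(n, "").startswith("igs")}
    refs = syn.ReferenceProfiles(profiles=profiles, markers=markers)

    nc = list(meta.index[meta["group"] == "NC"])
    gz = al.gene_z(al.probe_z(expr, al.build_reference(expr, nc)), annot)
    igs = inf.igs_score(gz, sigs)
    igs.to_csv(args.out / "igs_scores.tsv", sep="\t", index_label="sample_id")

    ranks, cd8_report = inf.rank_separation(igs["CD8T"], meta)
    cd8_report.to_csv(args.out / "cd8_rank_tests.tsv", sep="\t")
    print("CD8 rank separation:")
    print(cd8_report.to_string())

    gene_linear = 2.0 ** pp.collapse_probes_mean(expr, annot)
    fractions = inf.estimate_fractions(gene_linear, refs)
    fractions.to_csv(args.out / "infiltrate_fractions.tsv", sep="\t", index_label="sample_id")
    est = 100 * fractions["burden"].groupby(meta["group"]).mean()
    true = 100 * truth.fractions.sum(axis=1).groupby(meta["group"]).mean()
    mae = (fractions["burden"] - truth.fractions.sum(axis=1)).abs().mean()
    print(f"estimated total burden (%): NC {est['NC']:.2f}, AAP {est['AAP']:.2f}, "
          f"AT/AU {est['ATAU']:.2f} (planted {true['NC']:.2f} / {true['AAP']:.2f} / "
          f"{true['ATAU']:.2f}; MAE {100 * mae:.3f} points)")
    cd8_share = 100 * fractions["share_CD8T"].groupby(meta["group"]).mean()
    print(f"CD8 share of infiltrate (%): AAP {cd8_share['AAP']:.1f}, AT/AU {cd8_share['ATAU']:.1f}")

    ratio, th_report = inf.th_ratio(gene_linear, sigs, meta)
    ratio.to_frame().to_csv(args.out / "th1_th2_ratio.tsv", sep="\t", index_label="sample_id")
    print(f"Th1:Th2 log-ratio, AA vs NC: {json.dumps(th_report)}")


if __name__ == "__main__":
    main()
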