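"""ALADIN: the three-axis CTL / IFN / KRT control-referenced z-scores,
the 3-D representation, and the duration-stratified comparison.

Scores are computed against the discovery NC reference (probe z -> gene z ->
signature mean) for every sample, the group gradient is summarized, a 3-D
scatter of the three axes is written, and the long- vs short-duration
comparison (>= 5 years) is run twice: on the duration cohort with a planted
long-duration attenuation of CTL/IFN (expected significant in AT/AU) and on
its AAP samples where nothing was planted (expected non-significant).

Run after 02:  python analysis/06_aladin_scores.py [--out results]
"""

import argparse
from pathlib import Path

from aa_sigscope import aladin as al
from aa_sigscope import io as sio
from aa_sigscope import synthetic as syn


def _scores(data_dir, out_dir, name):
    expr = sio.read_expression(data_dir / name / "expr_corrected.tsv")
    _, meta, annot, sigs, _ = syn.read_fixture(data_dir / name)
    nc = list(meta.index[meta["group"] == "NC"])
    ref = al.build_reference(expr, nc)
    sio.write_json(ref.to_json_dict(), out_dir / f"aladin_reference_{name}.json")
    gz = al.gene_z(al.probe_z(expr, ref), annot)
    scores = al.aladin_scores(gz, sigs, meta)
    scores.to_csv(out_dir / f"aladin_scores_{name}.tsv", sep="\t", index_label="sample_id")
    return scores, meta


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.out / "data"

    scores, meta = _scores(data, args.out, "discovery")
    med = scores.groupby("group", observed=True)[["CTL", "IFN", "KRT"]].median()
    print("median ALADIN scores (discovery):")
    print(med.to_string())

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        for g, color in (("NC", "0.6"), ("AAP", "tab:blue"), ("ATAU", "tab:red")):
            sub = scores[scores["group"] == g]
            ax.scatter(sub["CTL"], sub["IFN"], sub["KRT"], label=g, color=color, s=18)
        ax.set_xlabel("CTL"); ax.set_ylabel("IFN"); ax.set_zlabel("KRT")
        ax.legend()
        fig_dir = args.out / "figures"
        fig_dir.mkdir(parents=True, exist_ok=True)
        fig.savefig(fig_dir / "aladin_3d.png", dpi=120)
        print(f"3-D scatter -> {fig_dir / 'aladin_3d.png'}")
    except ImportError:
        print("matplotlib unavailable; skipping the 3-D scatter")

    scores_dur, meta_dur = _scores(data, args.out, "duration")
    for group, expectation in (("ATAU", "planted decay"), ("AAP", "no decay planted")):
        rep = al.duration_comparison(scores_dur, meta_dur, group=group)
        rep.to_csv(args.out / f"aladin_duration_{group}.tsv", sep="\t")
        print(f"duration >= 5y vs < 5y in {group} ({expectation}):")
        print(rep[["n_long", "n_short", "median_long", "median_short", "p"]].to_string())


if __name__ == "__main__":
    main()
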