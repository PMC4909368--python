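"""Differential expression: the three disease-vs-control contrasts.

Moderated-t fits (log2 expression ~ group + gender) for AA vs NC, AAP vs NC
and AT/AU vs NC, BH-adjusted, with the disease signature selected at
|FC| > 1.5 and FDR < 0.05. Writes the per-contrast DE tables, the AA-vs-NC
signature probe list (used by the severity terrain) and the pairwise overlap
counts between the AAP and AT/AU selections.

Run after 02:  python analysis/03_differential_expression.py [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd

from aa_sigscope import diffexp as de
from aa_sigscope import io as sio
from aa_sigscope import synthetic as syn


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.out / "data"

    expr = sio.read_expression(data / "discovery" / "expr_corrected.tsv")
    meta = sio.read_sample_metadata(data / "discovery" / "samples.tsv")
    tables = de.run_contrasts(expr, meta)
    selections = {}
    for name, table in tables.items():
        table.to_csv(args.out / f"de_{name}.tsv", sep="\t", index_label="probe_id")
        up, down = de.select_signature(table)
        selections[name] = (up, down)
        print(f"{name}: {len(up)} up / {len(down)} down at |FC|>1.5, FDR<0.05")

    up, down = selections["AA_vs_NC"]
    (args.out / "signature_probes.txt").write_text("\n".join(up + down) + "\n")
    print(f"AA-vs-NC disease signature: {len(up) + len(down)} probes -> signature_probes.txt")

    aap = set().union(*selections["AAP_vs_NC"])
    atau = set().union(*selections["ATAU_vs_NC"])
    only_a, shared, only_b = de.signature_overlap(aap, atau)
    pd.DataFrame(
        [{"aap_only": only_a, "shared": shared, "atau_only": only_b}]
    ).to_csv(args.out / "de_overlap_aap_atau.tsv", sep="\t", index=False)
    print(f"AAP/AT-AU selection overlap: {only_a} AAP-only, {shared} shared, {only_b} AT/AU-only "
          f"(AAP containment {shared / max(len(aap), 1):.2f} vs AT/AU {shared / max(len(atau), 1):.2f})")


if __name__ == "__main__":
    main()
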