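"""Filter probes and remove batch effects from the simulated cohorts.

Discovery and duration cohorts: annotation filters (sex chromosomes, control
probes, missing gene symbols), present-call filter, then the empirical-Bayes
location/scale batch correction protecting group and gender. The validation
cohort is single-batch and is only filtered.

Run after 01:  python analysis/02_preprocess.py [--out results]
"""

import argparse
from pathlib import Path

from aa_sigscope import io as sio
from aa_sigscope import preprocess as pp
from aa_sigscope import synthetic as syn


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.out / "data"

    for name in ("discovery", "duration", "validation"):
        expr, meta, annot, sigs, truth = syn.read_fixture(data / name)
        filtered = pp.filter_probes(expr, annot)
        n_batches = meta["batch"].nunique()
        if n_batches > 1:
            corrected = pp.batch_correct(filtered, meta)
            note = f"batch-corrected across {n_batches} batches"
        else:
            corrected = filtered
            note = "single batch, no correction applied"
        sio.write_expression(corrected, data / name / "expr_corrected.tsv")
        print(f"{name}: kept {len(filtered.probes)}/{len(expr.probes)} probes; {note}")


if __name__ == "__main__":
    main()
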