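"""Severity terrain: PCA of the disease signature, per-group bivariate
densities, the bounded 0-10 consensus severity score, and validation-set
hierarchical clustering.

Samples are projected onto the first two principal components of the
AA-vs-NC signature probes; each group gets a bivariate Gaussian and every
sample a posterior-weighted severity score (NC-like -> 0, AT/AU-like -> 10).
Group medians and nonparametric comparisons are reported, and the signature
is checked for its ability to split the held-out validation cohort into
AA vs NC by correlation-distance average-linkage clustering.

Run after 03:  python analysis/04_severity_terrain.py [--out results]
"""

import argparse
from pathlib import Path

from aa_sigscope import io as sio
from aa_sigscope import severity as sev


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.out / "data"

    expr = sio.read_expression(data / "discovery" / "expr_corrected.tsv")
    meta = sio.read_sample_metadata(data / "discovery" / "samples.tsv")
    probes = (args.out / "signature_probes.txt").read_text().split()

    proj, coords = sev.project_pca(expr, probes)
    print(f"PCA on {len(probes)} signature probes: variance explained "
          f"{proj.variance_explained[0]:.1f} / {proj.variance_explained[1]:.1f}")
    model = sev.fit_terrain(coords, meta, proj)
    scores = sev.consensus_score(model, coords)
    scores.to_csv(args.out / "severity_scores.tsv", sep="\t", index_label="sample_id")
    med = scores.groupby(meta["group"])["score"].median()
    print(f"median severity: NC {med['NC']:.2f}, AAP {med['AAP']:.2f}, AT/AU {med['ATAU']:.2f}")
    report = sev.compare_score_groups(scores, meta)
    report.to_csv(args.out / "severity_group_tests.tsv", sep="\t")
    print(report.to_string())

    expr_v = sio.read_expression(data / "validation" / "expr_corrected.tsv")
    meta_v = sio.read_sample_metadata(data / "validation" / "samples.tsv")
    avail = [p for p in probes if p in set(expr_v.probes)]
    _, labels, agreement = sev.validate_clustering(expr_v, avail, meta_v)
    print(f"validation clustering: {len(avail)} signature probes, "
          f"two-cluster agreement with AA/NC labels = {agreement:.2f}")


if __name__ == "__main__":
    main()
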