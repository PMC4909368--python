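"""Generate the synthetic study cohorts and write them as plain-text fixtures.

Three cohorts are produced under results/data/:
  discovery/  23 NC / 20 AAP / 20 AT-AU, two batches, graded signature
              effects and CD8-dominated immune admixture (0.8% AAP, ~1.4%
              AT/AU total burden, Th1 skewed 2:1 in disease)
  validation/ 13 NC / 8 AAP / 12 AT-AU, single batch (no correction needed)
  duration/   as discovery but with CTL/IFN effects halved in AT-AU samples
              with >= 5 years of disease, for the duration-stratified analysis

Run:  python analysis/01_simulate_cohorts.py [--seed 1] [--out results]
"""

import argparse
from pathlib import Path

from aa_sigscope import synthetic as syn


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    refs = syn.generate_reference_profiles(n_genes=2000, seed=args.seed)
    data = args.out / "data"
    configs = {
        "discovery": syn.SimulationConfig(seed=args.seed),
        "validation": syn.SimulationConfig(
            seed=args.seed + 1, n_per_group={"NC": 13, "AAP": 8, "ATAU": 12}, n_batches=1
        ),
        "duration": syn.SimulationConfig(seed=args.seed + 2, long_duration_attenuation=0.5),
    }
    for name, cfg in configs.items():
        dataset = syn.simulate_cohort(cfg, refs)
        paths = syn.write_fixture(dataset, data / name)
        expr, meta = dataset[0], dataset[1]
        print(f"{name}: {expr.values.shape[0]} probes x {len(meta)} samples "
              f"({dict(meta['group'].value_counts())}) -> {data / name}")
    refs.profiles.T.to_csv(data / "refs.tsv", sep="\t", index_label="gene")
    print(f"reference profiles ({len(refs.cell_types)} cell types + skin) -> {data / 'refs.tsv'}")


if __name__ == "__main__":
    main()
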