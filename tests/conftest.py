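import numpy as np
import pandas as pd
import pytest

from aa_sigscope import preprocess as pp
from aa_sigscope import synthetic as syn


@pytest.fixture(scope="session")
def default_refs():
    return syn.generate_reference_profiles(n_genes=2000, seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_refs):
    """The study-emulating cohort: 23/20/20, graded signature effects,
    CD8-dominated admixture, two balanced batches."""
    cfg = syn.SimulationConfig(seed=1)
    return cfg, syn.simulate_cohort(cfg, default_refs)


@pytest.fixture(scope="session")
def corrected_cohort(default_cohort):
    """Default cohort after probe filtering and batch correction."""
    _, (expr, meta, annot, sigs, truth) = default_cohort
    filt = pp.filter_probes(expr, annot)
    corr = pp.batch_correct(filt, meta)
    return corr, meta, annot, sigs, truth


def null_config(seed: int, **kw) -> syn.SimulationConfig:
    """A cohort with no planted biology: no effects, no admixture."""
    base = dict(
        signature_effects={"CTL": (0.0, 0.0), "IFN": (0.0, 0.0), "KRT": (0.0, 0.0)},
        infiltrate_fractions={g: {} for g in ("NC", "AAP", "ATAU")},
        batch_shift_sd=0.0,
        gender_effect_sd=0.0,
        seed=seed,
    )
    base.update(kw)
    return syn.SimulationConfig(**base)
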