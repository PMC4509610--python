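import numpy as np
import pandas as pd
import pytest

import pedgwas as pg
from pedgwas.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def small_dataset():
    """A small pedigreed herd with one planted additive+dominance causal SNP."""
    cfg = SimulationConfig(
        seed=42,
        n_founders=60,
        n_generations=2,
        n_offspring_per_generation=220,
        n_cows=160,
        n_snps=120,
        n_chromosomes=3,
        chrom_length_bp=30_000_000,
        causal_additive=((7, 0.6, 0.3),),
    )
    return pg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_scan_inputs(small_dataset):
    """Pre-corrected response, relationship matrix and REML components."""
    ds = small_dataset
    model = pg.fit_fixed_effects(ds.phenotypes)
    resp = pg.residualize(ds.phenotypes, model, genotyped_ids=ds.panel.animal_ids)
    A = pg.build_A(pg.prune_to_ancestors(ds.pedigree, ds.panel.animal_ids))
    vc = pg.reml_null(resp, A)
    stats = pg.allele_stats(ds.panel)
    return ds, resp, A, vc, stats


def make_response(y, animals):
    return pd.DataFrame({"animal": animals, "residual": np.asarray(y, float)})
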