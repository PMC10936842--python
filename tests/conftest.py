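import numpy as np
import pandas as pd
import pytest

from psiqtl import phenotype, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared by read-only tests."""
    config = synthetic.SimConfig(n_samples=120, n_genes=4, seed=11)
    geno, cov, jc, exons, truth = synthetic.sim_cohort(config)
    return {
        "config": config,
        "geno": geno,
        "cov": cov,
        "jc": jc,
        "exons": exons,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def mapped_phenotype(small_cohort):
    p = phenotype.compute_psi(small_cohort["jc"], small_cohort["exons"])
    p = phenotype.filter_exons(p)
    return phenotype.inverse_normal_transform(p, seed=7)
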