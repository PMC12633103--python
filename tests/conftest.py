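import warnings

import numpy as np
import pandas as pd
import pytest

from svomics.simulate import (
    SimulationConfig,
    simulate_genotypes,
    simulate_phenotypes,
)
from svomics.variants import VariantCallSet, VariantRecord


@pytest.fixture(autouse=True)
def _quiet_runtime_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def small_cohort():
    """300-sample cohort with LD pairs and planted protein QTLs."""
    cfg = SimulationConfig(
        n_samples=300,
        n_svs=60,
        n_snvs=120,
        seed=42,
        ld_targets=[("sv_1", "snv_1", 1.0), ("sv_2", "snv_2", 0.8),
                    ("sv_3", "snv_3", 0.0)],
        qtl_effects=[("sv_5", "prot_1", 0.6), ("sv_7", "prot_3", 0.4)],
        maf_overrides={"sv_5": 0.3, "sv_7": 0.2},
        n_genes=80,
        n_proteins=80,
    )
    svs, snvs = simulate_genotypes(cfg)
    expr, prot, cov, truth = simulate_phenotypes(svs, cfg)
    return {"config": cfg, "svs": svs, "snvs": snvs, "expr": expr,
            "prot": prot, "cov": cov, "truth": truth}


def make_callset(records, genotypes, sample_ids=None):
    genotypes = np.asarray(genotypes)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(genotypes.shape[0])]
    return VariantCallSet(records=records, genotypes=genotypes,
                          sample_ids=sample_ids)


def del_record(vid, chrom, start, end):
    return VariantRecord(id=vid, chrom=chrom, start=start, end=end,
                         vtype="DEL")
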