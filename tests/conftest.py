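import numpy as np
import pandas as pd
import pytest

from enrichprs import GenotypeMatrix, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort with planted training signal."""
    cfg = SimConfig(
        n_individuals=200,
        n_training_genes=10,
        n_candidate_genes=40,
        n_control_genes=150,
        variants_per_gene=(2, 5),
        effect_variants=(("training", 8, 0.8),),
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no genetic or CASI effect on the outcome."""
    cfg = SimConfig(
        n_individuals=200,
        n_training_genes=10,
        n_candidate_genes=20,
        n_control_genes=100,
        variants_per_gene=3,
        effect_variants=(),
        casi_effect=0.0,
        missing_rate=0.0,
        seed=7,
    )
    return simulate_cohort(cfg)


def make_genotypes(calls, individual_ids=None, variant_ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        individual_ids or [f"S{i}" for i in range(n)],
        variant_ids or [f"v{j}" for j in range(m)],
        calls,
    )


def make_annotation(variant_ids, genes=None, mafs=None, chroms=None, positions=None):
    m = len(variant_ids)
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chroms or ["1"] * m,
            "pos": positions or list(range(1000, 1000 + m)),
            "major_allele": ["A"] * m,
            "minor_allele": ["G"] * m,
            "gene": genes or ["GENE1"] * m,
            "maf": mafs if mafs is not None else [0.3] * m,
        }
    )
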