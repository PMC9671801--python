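import numpy as np
import pandas as pd
import pytest

from metabotyper.synthetic_data import (StudyConfig, TruthTable, CausalEntry,
                                        VariantSpec, simulate_genotypes,
                                        simulate_study)


@pytest.fixture(scope="session")
def small_study():
    """A quick two-region study used by several pipeline-level tests."""
    cfg = StudyConfig(cohort_sizes=(1500, 1200, 1000), n_regions=2,
                      variance_explained=0.04, n_phecodes=2)
    return simulate_study(cfg, seed=7)


@pytest.fixture(scope="session")
def single_locus():
    """One causal variant with LD proxies and two affected metabolites."""
    variants = [VariantSpec("1", 1_000_000, maf_target=0.3)]
    for off in (4_000, 9_000, 15_000, 22_000):
        variants.append(VariantSpec("1", 1_000_000 + off, maf_target=0.3))
    variants.sort(key=lambda v: v.pos)
    dosages = simulate_genotypes(variants, 6000, ld_decay=1e-5, seed=5)
    truth = TruthTable(causal_entries=[
        CausalEntry("1:1000000:A:G", "M1", 0.25, 0.25**2 * 2 * 0.3 * 0.7),
        CausalEntry("1:1000000:A:G", "M2", -0.25, 0.25**2 * 2 * 0.3 * 0.7),
    ])
    return variants, dosages, truth


def metabolite_partition_labels(groups, metabolites):
    """Component label per metabolite (-1 when unassigned), for ARI scoring."""
    label = {}
    for k, mets in enumerate(groups):
        for m in mets:
            label[m] = k
    return [label.get(m, -1) for m in metabolites]
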