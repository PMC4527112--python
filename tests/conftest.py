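import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from psoriomics.integration import match_pairs
from psoriomics.proteome_de import filter_detected_proteins, normalize_spc, paired_lm_de
from psoriomics.rnaseq_de import CountMatrix, detect_expressed_genes, nb_paired_de, tmm_factors
from psoriomics.synthetic import CohortSpec, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort shared by integration-level tests."""
    spec = CohortSpec(
        seed=42, n_genes=500, n_proteins_mapped=200, translation_block_size=20
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_results(small_cohort):
    """Both DE arms and the matched pair table for the shared cohort."""
    sim = small_cohort
    detected = detect_expressed_genes(sim.counts, sim.fpkm)
    cm = CountMatrix(sim.counts.counts.loc[detected])
    mrna_de = nb_paired_de(cm, sim.design, tmm_factors(cm))
    spc = filter_detected_proteins(sim.spc)
    protein_de = paired_lm_de(normalize_spc(spc), sim.design)
    pairs, unmatched = match_pairs(mrna_de, protein_de, sim.id_map)
    return {
        "sim": sim,
        "mrna_de": mrna_de,
        "protein_de": protein_de,
        "pairs": pairs,
        "unmatched": unmatched,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
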