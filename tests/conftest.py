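"""Shared fixtures.

The expensive simulation-based computations (full null permutation run,
power run, default end-to-end pipeline) are session-scoped so the
calibration checks and the property checks that interrogate the same
run share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from nichecompare.diff_abundance import differential_abundance
from nichecompare.diversity_ordination import (
    diversity_lmm,
    multigroup_pca,
    shannon_per_sample,
)
from nichecompare.io_model import to_proportions
from nichecompare.niche_sets import core_microbiota
from nichecompare.preprocess import exclude_low_count_samples, group_rare_taxa
from nichecompare.synthetic_data import (
    SimConfig,
    null_dataset,
    power_config,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_sim():
    """One dataset under the default study design (251 collected samples)."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Default dataset taken through QC, rare grouping, diversity, PCA, core."""
    ct, samples, taxa, truth = default_sim
    ct_qc, qc_report = exclude_low_count_samples(ct, samples)
    ct_units, taxa_units, rare_report = group_rare_taxa(ct_qc, samples, taxa=taxa)
    pt = to_proportions(ct_units)
    h = shannon_per_sample(pt)
    diversity = diversity_lmm(h, samples)
    pca = multigroup_pca(pt, samples)
    core = core_microbiota(pt, samples)
    return {
        "ct": ct,
        "samples": samples,
        "taxa": taxa,
        "truth": truth,
        "ct_qc": ct_qc,
        "qc_report": qc_report,
        "ct_units": ct_units,
        "taxa_units": taxa_units,
        "rare_report": rare_report,
        "pt": pt,
        "shannon": h,
        "diversity": diversity,
        "pca": pca,
        "core": core,
    }


@pytest.fixture(scope="session")
def null_perm_results():
    """Full differential pipeline on a 224-unit null dataset, n_perm=99.

    Used both for the type-I-error calibration and for the uniformity
    of the permutation p-value distribution.
    """
    ct, samples, taxa, truth = null_dataset(SimConfig(seed=11))
    ct_qc, _ = exclude_low_count_samples(ct, samples)
    ct_units, _, _ = group_rare_taxa(ct_qc, samples, taxa=taxa)
    assert ct_units.n_otus >= 200
    df = differential_abundance(ct_units, samples, n_perm=99, seed=5)
    return df


@pytest.fixture(scope="session")
def power_run():
    """Differential pipeline on data with 10 planted OR=4 effects, n_perm=199."""
    cfg = power_config(n_otus=60, n_effects=10, log_odds=np.log(4.0), seed=7)
    ct, samples, taxa, truth = simulate_dataset(cfg)
    ct_qc, _ = exclude_low_count_samples(ct, samples)
    ct_units, _, _ = group_rare_taxa(ct_qc, samples, taxa=taxa)
    df = differential_abundance(ct_units, samples, n_perm=199, seed=13)
    return df, truth
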