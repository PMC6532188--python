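import numpy as np
import pytest

import densprs as dp
from densprs.density import make_adjusted_phenotypes
from densprs.genotypes import apply_hwe_filter, build_prs_vector, impute_missing_mcmc
from densprs.pipeline import analysis_frame


def run_stages(subjects, genotypes, weights, seed=1):
    """Score construction + density adjustment + merged analysis frame."""
    genotypes, exclusions = apply_hwe_filter(
        genotypes, subjects["study"], subjects["status"]
    )
    genotypes = impute_missing_mcmc(
        genotypes, subjects["age_years"], subjects["bmi"], seed=seed
    )
    prs = build_prs_vector(genotypes, weights, subjects["status"])
    adjusted = make_adjusted_phenotypes(subjects)
    frame = analysis_frame(subjects, adjusted, prs)
    return frame, prs, adjusted, exclusions


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated 800/800 dataset with all stages run, shared read-only."""
    cfg = dp.scaled_config(800, 800, seed=7)
    subjects, genotypes, weights, truth = dp.generate_population(cfg)
    frame, prs, adjusted, exclusions = run_stages(subjects, genotypes, weights)
    return {
        "config": cfg,
        "subjects": subjects,
        "genotypes": genotypes,
        "weights": weights,
        "truth": truth,
        "frame": frame,
        "prs": prs,
        "adjusted": adjusted,
        "exclusions": exclusions,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
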