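import numpy as np
import pandas as pd
import pytest

from gwgi.simulate import SimScenario, StudyCohort, simulate_collection


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_cohort(study_id, n, info_scores, seed=0):
    """Minimal hand-built cohort for filter/bookkeeping tests."""
    rng = np.random.default_rng(seed)
    m = len(info_scores)
    samples = pd.DataFrame(
        {
            "sample_id": [f"{study_id}_s{i}" for i in range(n)],
            "study": study_id,
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "smoking": np.where(rng.random(n) < 0.8, "ever", "never"),
            "disease": np.where(rng.random(n) < 0.5, "case", "control"),
        }
    )
    for k in range(1, 6):
        samples[f"pc{k}"] = rng.standard_normal(n)
    variants = pd.DataFrame(
        {
            "snp_id": [f"1:{1000 + j}:A:G" for j in range(m)],
            "chrom": "1",
            "pos": 1000 + np.arange(m),
            "ref": "A",
            "alt": "G",
            "info_score": np.asarray(info_scores, dtype=float),
        }
    )
    dosages = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    return StudyCohort(study_id, samples, dosages, variants)


@pytest.fixture(scope="session")
def small_collection():
    """A cheap 2-study null collection reused by scan/io tests."""
    scenario = SimScenario(
        n_cases_per_study=(250, 150),
        n_controls_per_study=(250, 150),
        n_snps=8,
        maf_range=(0.1, 0.4),
        baseline_prevalence=0.2,
        info_noise_sd=0.2,
        seed=42,
    )
    return scenario, simulate_collection(scenario)
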