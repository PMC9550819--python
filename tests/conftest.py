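import numpy as np
import pytest

from sestrat import CohortConfig, generate_cohort

TF_PANEL = [f"TF{i + 1:02d}" for i in range(20)]


@pytest.fixture(scope="session")
def cohort300():
    """Default study-condition cohort: k=3, n=300, effect 2 SD."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def truth_labels300(cohort300):
    return np.array(
        [cohort300.truth["labels"][s] for s in cohort300.se_rna.sample_ids]
    )


@pytest.fixture(scope="session")
def cohort150():
    """Smaller cohort for the clustering-recovery conditions (n=150, 500 SEs)."""
    return generate_cohort(CohortConfig(seed=1, n_samples=150))


@pytest.fixture(scope="session")
def null_cohort():
    """No planted activation and equal hazards: exchangeable across clusters."""
    return generate_cohort(
        CohortConfig(
            seed=7,
            n_samples=90,
            n_se=100,
            se_activation_effect=0.0,
            signature_effect=0.0,
            baseline_hazard=(0.05, 0.05, 0.05),
        )
    )
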