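import numpy as np
import pytest

from neurofuse.cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but full-featured cohort shared by read-only tests."""
    cfg = CohortConfig(
        n_subjects=40,
        volume_shape=(16, 16, 16),
        n_components=10,
        n_snps=30,
        fnc_effect=[(3, 0.6), (17, 0.6)],
        snp_effect=[(5, 1.0)],
        volume_effect=[(((4, 10), (4, 10), (4, 10)), 0.15)],
        seed=11,
    )
    return simulate_cohort(cfg)


def planted_fnc_config(seed, shift, n_subjects=400, n_planted=20):
    """Standard FNC-recovery cohort: ``n_planted`` connections shifted by
    ``shift`` (Fisher-z units) in cases, everything else null."""
    planted = np.random.default_rng(seed + 77).choice(1378, n_planted, replace=False)
    return (
        CohortConfig(
            n_subjects=n_subjects,
            n_snps=10,
            volume_shape=(8, 8, 8),
            fnc_effect=[(int(i), float(shift)) for i in planted],
            seed=seed,
        ),
        [int(i) for i in planted],
    )


def multimodal_config(seed, n_subjects=400):
    """Standard fusion-evaluation cohort: complementary moderate planted
    effects in all three modalities, none at ceiling."""
    rng = np.random.default_rng(seed + 500)
    fnc_idx = rng.choice(1378, 20, replace=False)
    snp_idx = rng.choice(300, 15, replace=False)
    return CohortConfig(
        n_subjects=n_subjects,
        volume_shape=(32, 40, 32),
        n_snps=300,
        fnc_effect=[(int(i), 0.35) for i in fnc_idx],
        snp_effect=[(int(i), 1.2) for i in snp_idx],
        volume_effect=[(((8, 18), (10, 20), (8, 18)), 0.12)],
        seed=seed,
    )
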