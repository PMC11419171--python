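import numpy as np
import pytest

from endosubtypes import SimConfig, VariantSpec, block_prevalence, simulate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Small strongly-separated 5-subtype cohort with a genotyped panel:
    variant rs0 carries a global effect, rs1 a subtype-0-specific effect,
    the rest are null; rs_tag tags rs0."""
    p_jk, p_j0 = block_prevalence(17, 5, 0.8, 0.05)
    specs = [
        VariantSpec("rs0", "1", 10_000_000, 0.3, tuple([np.log(1.5)] * 5)),
        VariantSpec("rs1", "2", 10_000_000, 0.3, (np.log(1.8), 0, 0, 0, 0)),
        VariantSpec("rs_tag", "1", 10_100_000, 0.3, (0.0,) * 5,
                    tag_of="rs0", tag_flip=0.1),
    ] + [
        VariantSpec(f"rs{i}", str(i % 22 + 1), 20_000_000, 0.2 + 0.01 * i,
                    (0.0,) * 5)
        for i in range(2, 12)
    ]
    cfg = SimConfig(
        n_controls=600,
        n_cases_per_subtype=[120] * 5,
        feature_prevalence=p_jk,
        control_feature_prevalence=p_j0,
        variant_specs=specs,
        strata=[("EUR", 0.7), ("AFR", 0.3)],
        seed=20_240_901,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
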