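import pytest
from hypothesis import HealthCheck, settings

from homburden import synthetic_data as sd

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_cohort() -> sd.Cohort:
    """Small cohort with one inflated gene-set context, a null context, an
    inflated region-set context, and two planted carrier genes."""
    cfg = sd.SimConfig(
        seed=2024,
        n_variants=2000,
        contexts=[
            sd.PlantedContext("inflammatory", "NDD", 0.05, n_genes=20),
            sd.PlantedContext("chromatin", "NDD", 0.0, n_genes=20),
            sd.PlantedContext("cnv_regions", "ASD", 0.05, n_genes=15, kind="regionset"),
        ],
        planted_qv_genes=[
            sd.PlantedQvGene("GENE_NDD3", "NDD", 3),
            sd.PlantedQvGene("GENE_ASD2", "ASD", 2),
        ],
    )
    return sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort() -> sd.Cohort:
    """Cohort with no planted effects at all."""
    return sd.generate_cohort(sd.SimConfig(seed=7, n_variants=1500))
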