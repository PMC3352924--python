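import pytest
from hypothesis import HealthCheck, settings

from nbsarch.pipeline import run_survey
from nbsarch.simulate import (
    SyntheticFamilySpec,
    combine_families,
    make_family,
    bryophyte_survey_specs,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mixed_survey():
    """Four-class genome with survey-table form proportions, divergence 0.2.

    Shared by the recovery and channel-accuracy checks; the seed is part of
    the fixture definition so every test sees the same genome.
    """
    specs = bryophyte_survey_specs(divergence=0.2, seed=7, n_decoy_genes=5)
    family = combine_families([make_family(s) for s in specs])
    result = run_survey(family.genome, family.genes, seed=7)
    return family, result


@pytest.fixture(scope="session")
def zero_divergence_families():
    """One small zero-divergence family per class, with signature introns."""
    out = {}
    for i, cls in enumerate(("TNL", "PNL", "CNL", "HNL")):
        spec = SyntheticFamilySpec(
            cls, {cls: 3}, divergence=0.0, seed=50 + i
        )
        out[cls] = make_family(spec)
    return out
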