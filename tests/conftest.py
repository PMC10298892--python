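import pytest
from hypothesis import HealthCheck, settings

from dualscreen.io_model import ChemicalTargetMap
from dualscreen.synthetic import SyntheticSpec

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_target_map():
    """hits {A,B,C,D}; T1 hit by A,B,C; T2 by A,B; T3 by D."""
    return ChemicalTargetMap.from_pairs(
        [
            ("A", "T1"), ("B", "T1"), ("C", "T1"),
            ("A", "T2"), ("B", "T2"),
            ("D", "T3"),
        ]
    )


@pytest.fixture
def small_spec():
    """Desk-scale synthetic conditions: 100 chemicals, 50 patients.

    Thresholds implied by the defaults: k=3 chemicals and
    ceil(0.10 * 50) = 5 patients; the planted symbol clears both with
    margin (5 chemicals, 12 patients) while the background stays
    strictly below.
    """
    return SyntheticSpec(
        seed=0,
        n_chemicals=100,
        hit_rate=0.10,
        n_targets=60,
        targets_per_chemical=(1, 5),
        planted_target_chemicals=5,
        n_patients=50,
        n_genes=300,
        n_chromosomes=4,
        planted_gene_patients=12,
        n_categories=20,
        n_shared_categories=4,
    )
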