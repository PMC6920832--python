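import pytest
from hypothesis import HealthCheck, settings

from myxotax.core import SequenceRecord
from myxotax.simulate import SimSpec, generate_community

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_record(seq_id: str, residues: str, **kwargs) -> SequenceRecord:
    return SequenceRecord(id=seq_id, residues=residues, **kwargs)


@pytest.fixture(scope="session")
def small_community():
    """24 sequences: 2 suborders x 1 family x 2 genera x 2 species x 3."""
    spec = SimSpec(
        suborders=2,
        families_per_suborder=1,
        genera_per_family=2,
        species_per_genus=2,
        sequences_per_species=3,
        seed=11,
    )
    return generate_community(spec)


@pytest.fixture(scope="session")
def default_community():
    """The default synthetic community (224 sequences, 4/8/16/32 taxa)."""
    return generate_community(SimSpec(seed=42))
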