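import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromqc import synthetic

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


ALTERNATING_TELOMERE = dict(
    monomer="TTTAGGG", alternate_monomer="TTGAGGG", copies=100,
    per_base_mutation_rate=0.01,
)


@pytest.fixture(scope="session")
def planted_scaffold_spec():
    """One 60 kb chromosome-like scaffold: telomeres both ends, interior
    centromere of the 181 bp monomer, one unknown-size gap."""
    return synthetic.ScaffoldSpec(
        name="chrT",
        length=60_000,
        telomere_5p=synthetic.RepeatUnitSpec(**ALTERNATING_TELOMERE),
        telomere_3p=synthetic.RepeatUnitSpec(**ALTERNATING_TELOMERE),
        centromere=(
            synthetic.RepeatUnitSpec(
                monomer=synthetic.CENTROMERE_MONOMER_181,
                copies=50,
                per_base_mutation_rate=0.02,
            ),
            0.5,
        ),
        gaps=(synthetic.GapSpec(position=5_000),),
    )


@pytest.fixture(scope="session")
def planted_assembly(planted_scaffold_spec):
    return synthetic.build_assembly([planted_scaffold_spec], seed=11)


@pytest.fixture(scope="session")
def fused_assembly():
    spec = synthetic.fused_preset(seed=5, component_length=40_000)
    return synthetic.build_assembly([spec], seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(n: int, seed: int) -> str:
    gen = np.random.default_rng(seed)
    return "".join(gen.choice(list("ACGT"), size=n))
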