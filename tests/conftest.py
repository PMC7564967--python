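import pytest
from hypothesis import settings

from famscan.synthetic import DuplicateSpec, SynthConfig, generate_bundle

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def small_config() -> SynthConfig:
    """A compact genome: 8 family members over 3 chromosomes, one planted
    tandem pair and one dispersed pair."""
    return SynthConfig(
        n_chromosomes=3,
        members_per_chromosome=(3, 2, 3),
        subfamily_sizes=(("G", 4), ("L", 3), ("C", 1)),
        decoys_per_chromosome=3,
        fillers_per_chromosome=8,
        duplicate_pairs=(
            DuplicateSpec(ks=0.4, ka=0.08, tandem=True, n_intervening=2),
            DuplicateSpec(ks=0.3, ka=0.06, tandem=False),
        ),
        group_sizes=(2, 3, 3),
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle_small")
    cfg = small_config()
    truth = generate_bundle(cfg, out, seed=7)
    return cfg, out, truth


@pytest.fixture(scope="session")
def family_bundle(tmp_path_factory):
    """The full-size default bundle: 46 members, 7 chromosomes."""
    out = tmp_path_factory.mktemp("bundle_family")
    cfg = SynthConfig()
    truth = generate_bundle(cfg, out, seed=11)
    return cfg, out, truth
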