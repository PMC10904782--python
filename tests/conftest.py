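import pytest

from vamp.amg import load_default_pathway_map
from vamp.synthdata import CommunityConfig, PlantedAmg, generate_community

#: every curation outcome the generator can force
ALL_CONTEXTS = (
    "flanked",
    "terminal",
    "not_flanked",
    "transposon",
    "inconsistent",
    "no_ko",
    "host_region",
)


@pytest.fixture(scope="session")
def pathway_map():
    return load_default_pathway_map()


def planted_amg_set(pathway_map, n: int = 21):
    """n planted AMGs cycling through every genomic context, distinct KOs."""
    kos = sorted(ko for ko, pf in pathway_map.ko_to_pfams.items() if pf)
    assert len(kos) >= n
    return tuple(
        PlantedAmg(ko=kos[i], context=ALL_CONTEXTS[i % len(ALL_CONTEXTS)], n_syn=2, n_nonsyn=3)
        for i in range(n)
    )


@pytest.fixture(scope="session")
def zero_noise_config(pathway_map):
    return CommunityConfig(
        seed=11,
        n_mags=4,
        n_viral_contigs=12,
        n_decoy_contigs=6,
        planted_amgs=planted_amg_set(pathway_map, 21),
    )


@pytest.fixture(scope="session")
def zero_noise_bundle(zero_noise_config):
    return generate_community(zero_noise_config)
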