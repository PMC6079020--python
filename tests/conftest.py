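import numpy as np
import pytest

from redsnow.sim import SimConfig, build_metacommunity, simulate_reads


def small_config(**overrides):
    """A fast, fully featured simulator configuration for tests."""
    kw = dict(
        reads_per_sample=600,
        endemic_counts={"Antarctica": 8, "Svalbard": 5, "Greenland": 3, "Alaska": 9},
        arctic_shared_counts={"Svalbard+Greenland": 2, "Svalbard+Alaska": 2,
                              "Greenland+Alaska": 2},
        entire_arctic_count=2,
        bipolar_count=4,
        phylotypes_per_otu=2,
        n_species=2,
        seed=11,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small simulated survey shared by pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("smallsim")
    cfg = small_config()
    meta = build_metacommunity(cfg)
    truth = simulate_reads(meta, outdir)
    return {"config": cfg, "meta": meta, "truth": truth, "dir": outdir}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def mutate_at(seq, positions, rng, alphabet="ACGT"):
    s = list(seq)
    for p in positions:
        s[p] = alphabet[(alphabet.index(s[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(s)
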