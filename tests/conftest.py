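import itertools

import numpy as np
import pytest

from dnatape.tape_sim import TapeConfig, TapeState


@pytest.fixture
def tape1_2site() -> TapeConfig:
    return TapeConfig(n_sites=2, name="2x")


@pytest.fixture
def tape1_5site() -> TapeConfig:
    return TapeConfig(n_sites=5, name="5x")


@pytest.fixture
def tape1_5site_3bc() -> TapeConfig:
    return TapeConfig(n_sites=5, barcode_len=3, name="5x3bc")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def random_config(rng: np.random.Generator) -> TapeConfig:
    key_len = int(rng.integers(2, 5))
    barcode_len = int(rng.integers(2, 7))
    mono_len = int(rng.integers(max(key_len + 3, 10), 20))
    return TapeConfig(
        monomer=random_dna(rng, mono_len),
        key=random_dna(rng, key_len),
        barcode_len=barcode_len,
        n_sites=int(rng.integers(1, 21)),
    )


def random_state(rng: np.random.Generator, cfg: TapeConfig,
                 with_target_bc: bool = False) -> TapeState:
    k = int(rng.integers(0, cfg.n_sites + 1))
    inserts = tuple(random_dna(rng, cfg.barcode_len) for _ in range(k))
    tbc = random_dna(rng, 8) if with_target_bc else ""
    return TapeState(config=cfg, inserts=inserts, target_bc=tbc)


def all_kmer_barcodes(k: int, n: int):
    pool = ("".join(p) for p in itertools.product("ACGT", repeat=k))
    return list(itertools.islice(pool, n))
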