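from __future__ import annotations

import numpy as np
import pytest

from pancomp.genome_io import GenomeRecord


BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(BASES[rng.integers(0, 4, n)]).decode()


def mutate_dna(seq: str, rng: np.random.Generator, sub_rate: float = 0.0, n_indels: int = 0,
               max_indel: int = 30) -> str:
    """Substitutions plus a few random indels, for alignment fixtures."""
    arr = bytearray(seq.encode())
    if sub_rate > 0:
        for p in np.nonzero(rng.random(len(arr)) < sub_rate)[0]:
            alts = [b for b in b"ACGT" if b != arr[p]]
            arr[p] = alts[int(rng.integers(0, 3))]
    s = arr.decode()
    for _ in range(n_indels):
        pos = int(rng.integers(0, max(1, len(s))))
        size = int(rng.integers(1, max_indel + 1))
        if rng.random() < 0.5:
            s = s[:pos] + random_dna(rng, size) + s[pos:]
        else:
            s = s[:pos] + s[pos + size :]
    return s


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def small_genome(rng) -> GenomeRecord:
    return GenomeRecord("g1", random_dna(rng, 2000))
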