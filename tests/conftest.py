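import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from coevdimer.asa import ASAProfile
from coevdimer.msa import GAP, RESIDUES, AlignedFamily, PairedMSA


def random_family(
    rng: np.random.Generator,
    n_seq: int,
    width: int,
    gap_rate: float = 0.1,
    family_id: str = "fam",
    query_index: int = 0,
) -> AlignedFamily:
    residues = np.array(list(RESIDUES))
    rows = []
    for k in range(n_seq):
        chars = residues[rng.integers(0, len(residues), size=width)]
        if k != query_index and gap_rate > 0:
            chars = np.where(rng.random(width) < gap_rate, GAP, chars)
        rows.append("".join(chars))
    species = [f"sp{k + 1:04d}" for k in range(n_seq)]
    return AlignedFamily(family_id, rows, species, query_index)


def random_pair(
    rng: np.random.Generator,
    n_seq: int,
    w1: int,
    w2: int,
    gap_rate: float = 0.1,
    dimer_id: str = "dimer",
    label: str | None = None,
) -> PairedMSA:
    fam_a = random_family(rng, n_seq, w1, gap_rate, family_id=f"{dimer_id}_A")
    fam_b = random_family(rng, n_seq, w2, gap_rate, family_id=f"{dimer_id}_B")
    return PairedMSA(dimer_id, fam_a, fam_b, label=label)


def random_asa(rng: np.random.Generator, width: int, protein_id: str = "prot") -> ASAProfile:
    return ASAProfile(protein_id, rng.random(width))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
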