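import numpy as np
import pytest

from sawyerflow import AlignedSeqSet, SimConfig, fixture_from_tables, simulate_dataset


def make_alignment(pop_seqs: dict[str, list[str]]) -> AlignedSeqSet:
    """Build an alignment from {population: [sequence, ...]}."""
    records = []
    for pop, seqs in pop_seqs.items():
        for i, s in enumerate(seqs):
            records.append((f"{pop}_{i + 1}", pop, s))
    return AlignedSeqSet(records, populations=list(pop_seqs))


def random_toy_pops(rng: np.random.Generator, n_sites: int = 20):
    """Two random small populations with guaranteed molecular variance."""
    while True:
        na, nb = rng.integers(3, 7), rng.integers(3, 7)
        base = "".join(rng.choice(list("ACGT"), size=n_sites))
        seqs = []
        for _ in range(na + nb):
            s = list(base)
            for k in rng.choice(n_sites, size=rng.integers(0, 5), replace=False):
                s[k] = rng.choice([c for c in "ACGT" if c != s[k]])
            seqs.append("".join(s))
        if len(set(seqs)) > 1:
            return seqs[:na], seqs[na:]


@pytest.fixture(scope="session")
def published_tables():
    return fixture_from_tables()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across tests (6 demes of 6, 400 bp)."""
    cfg = SimConfig(n_demes=6, n_per_deme=6, seq_length=400, transport_m=0.2, seed=1234)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def survey_sim():
    """A survey-shaped simulated dataset: 14 demes x 10 individuals, 1200 bp."""
    return simulate_dataset(SimConfig(transport_m=0.15, seed=99))
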