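"""Shared fixtures: small pedigrees, compiled example models, random structures."""

import pytest

from pedsem import Individual, Pedigree, build_model_matrices, parse_model
from pedsem.examples import ALL_EXAMPLES

TRIO_CSV = """family,id,father,mother,sex,proband,P1
F1,dad,0,0,1,0,1.2
F1,mom,0,0,2,0,0.7
F1,kid,dad,mom,1,1,2.1
"""


@pytest.fixture()
def trio_csv(tmp_path):
    path = tmp_path / "trio.csv"
    path.write_text(TRIO_CSV)
    return path


def make_trio():
    return Pedigree("F1", [
        Individual("dad", sex="male"),
        Individual("mom", sex="female"),
        Individual("kid", "dad", "mom", sex="male"),
    ])


@pytest.fixture()
def trio():
    return make_trio()


def sib_pair():
    return Pedigree("S1", [
        Individual("f", sex="male"), Individual("m", sex="female"),
        Individual("s1", "f", "m"), Individual("s2", "f", "m"),
    ])


def random_pedigree(rng, n_members=10, n_founder_pairs=2):
    """A random valid pedigree: founders first, then random matings."""
    members = []
    for i in range(2 * n_founder_pairs):
        members.append(Individual(
            f"i{i}", sex="male" if i % 2 == 0 else "female"))
    while len(members) < n_members:
        i = len(members)
        males = [m.person_id for m in members if m.sex == "male"]
        females = [m.person_id for m in members if m.sex == "female"]
        if not males or not females:
            members.append(Individual(
                f"i{i}", sex="male" if i % 2 == 0 else "female"))
            continue
        members.append(Individual(
            f"i{i}", str(rng.choice(males)), str(rng.choice(females)),
            sex="male" if rng.random() < 0.5 else "female"))
    return Pedigree("R1", members)


@pytest.fixture(scope="session")
def example_models():
    return {name: build_model_matrices(parse_model(fn()))
            for name, fn in ALL_EXAMPLES.items()}
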