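import numpy as np
import pytest

from xciskew import build_pedigree


@pytest.fixture
def trio():
    return build_pedigree(
        [
            ("dad", None, None, "male"),
            ("mom", None, None, "female"),
            ("girl", "dad", "mom", "female"),
        ]
    )


@pytest.fixture
def cousin_pedigree():
    """Two sibs married to unrelated spouses; their children are first cousins."""
    return build_pedigree(
        [
            ("gf", None, None, "male"),
            ("gm", None, None, "female"),
            ("p1", "gf", "gm", "male"),
            ("p2", "gf", "gm", "female"),
            ("s1", None, None, "female"),
            ("s2", None, None, "male"),
            ("c1", "p1", "s1", "female"),
            ("c2", "s2", "p2", "female"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230543)


def random_pedigree(rng, n_founders=4, n_children=6):
    """Random valid pedigree: founder couples plus children of random couples."""
    records = []
    males, females = [], []
    for k in range(n_founders):
        sex = "male" if k % 2 == 0 else "female"
        (males if sex == "male" else females).append(f"f{k}")
        records.append((f"f{k}", None, None, sex))
    for k in range(n_children):
        if not males or not females:
            break
        father = males[rng.integers(len(males))]
        mother = females[rng.integers(len(females))]
        sex = "male" if rng.random() < 0.5 else "female"
        cid = f"c{k}"
        records.append((cid, father, mother, sex))
        (males if sex == "male" else females).append(cid)
    return build_pedigree(records)
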