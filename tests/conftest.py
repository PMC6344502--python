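import numpy as np
import pytest

from hopclass.core import (
    HopeConfig,
    SignatureSet,
    build_template_bank,
    hebb_weights_hope,
)


@pytest.fixture
def two_class_signatures():
    """p = 2, three genes per class: the smallest balanced problem."""
    return SignatureSet.from_dict(
        {"A": ["g1", "g2", "g3"], "B": ["g4", "g5", "g6"]}
    )


@pytest.fixture
def two_class_bank(two_class_signatures):
    return build_template_bank(two_class_signatures)


@pytest.fixture
def two_class_weights(two_class_bank):
    return hebb_weights_hope(two_class_bank)


@pytest.fixture
def three_class_signatures():
    """p = 3, balanced 5-gene signatures (template-stable layout)."""
    return SignatureSet.from_dict(
        {
            "alpha": [f"a{i}" for i in range(5)],
            "beta": [f"b{i}" for i in range(5)],
            "gamma": [f"c{i}" for i in range(5)],
        }
    )


@pytest.fixture
def fast_config():
    return HopeConfig(replicas=10, n_permutations=50, null_replicas=5, seed=7)


def random_disjoint_signatures(rng, p=None, max_size=6):
    """Random non-overlapping signature layout for property tests."""
    if p is None:
        p = int(rng.integers(2, 6))
    sizes = rng.integers(1, max_size + 1, size=p)
    mapping = {}
    gene = 0
    for mu in range(p):
        mapping[f"cls{mu}"] = [f"g{gene + j}" for j in range(sizes[mu])]
        gene += sizes[mu]
    return SignatureSet.from_dict(mapping)
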