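import numpy as np
import pytest

import rpcascade as rp


@pytest.fixture
def tiny_table():
    return rp.ScoreTable.from_pairs(
        [
            ("m1", "g1", 0.9),
            ("m1", "g2", 0.5),
            ("m1", "g3", 0.1),
            ("m2", "g1", 0.7),
            ("m2", "g3", 0.3),
        ]
    )


@pytest.fixture
def random_table():
    rng = np.random.default_rng(42)
    pairs = []
    for i in range(20):
        for j in range(50):
            if rng.random() < 0.5:
                pairs.append((f"m{i:02d}", f"g{j:02d}", float(rng.random())))
    return rp.ScoreTable.from_pairs(pairs)


@pytest.fixture(scope="session")
def sim_default():
    """One shared draw of the default synthetic study conditions."""
    return rp.generate(rp.SynthConfig(seed=7))


def write_tsv(path, rows):
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path
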