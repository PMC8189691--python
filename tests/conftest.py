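import numpy as np
import pytest

from chromdelta import (
    EmissionMatrix,
    SampleGroup,
    SegmentationMap,
    StateAlphabet,
    build_dataset,
)


def rt_bruteforce(scores):
    """Independent oracle for maximal scoring subsequences.

    Repeatedly extracts the highest-scoring subsegment (ties: shortest,
    then leftmost) and recurses on the flanks; only positive-sum
    segments are kept. O(n^2) per extraction, for small inputs only.
    """
    scores = list(scores)
    out = []

    def best(lo, hi):
        top = None
        for i in range(lo, hi):
            total = 0
            for j in range(i, hi):
                total += scores[j]
                key = (total, -(j + 1 - i), -i)
                if top is None or key > top[0]:
                    top = (key, i, j + 1)
        return top

    def recurse(lo, hi):
        if lo >= hi:
            return
        top = best(lo, hi)
        if top is None or top[0][0] <= 0:
            return
        _, a, b = top
        recurse(lo, a)
        out.append((a, b, top[0][0]))
        recurse(b, hi)

    recurse(0, len(scores))
    return sorted(out)


@pytest.fixture
def toy_alphabet():
    return StateAlphabet(
        ("E1", "E2", "E3", "E4"),
        background_state=3,
        functional_labels={"E1": "enh_on", "E2": "enh_off", "E3": "txn"},
    )


@pytest.fixture
def toy_emissions(toy_alphabet):
    # distinct, peaked rows; last row is the low-signal background
    probs = np.array(
        [
            [0.9, 0.1, 0.05],
            [0.05, 0.9, 0.1],
            [0.1, 0.1, 0.9],
            [0.02, 0.02, 0.02],
        ]
    )
    return EmissionMatrix(toy_alphabet, ("m1", "m2", "m3"), probs)


def make_map(sample_id, chrom_vectors, bin_size=200):
    return SegmentationMap(
        sample_id,
        bin_size,
        {chrom: np.asarray(vec) for chrom, vec in chrom_vectors.items()},
    )


@pytest.fixture
def toy_dataset(toy_emissions):
    rng = np.random.default_rng(123)
    n = 400
    base_x = rng.integers(0, 4, size=n)
    base_y = base_x.copy()
    base_y[100:120] = 1  # a deliberate block difference
    base_x[100:120] = 0
    maps = [
        make_map("X-1", {"chr1": base_x}),
        make_map("X-2", {"chr1": base_x}),
        make_map("Y-1", {"chr1": base_y}),
    ]
    groups = {
        "X": SampleGroup("X", ("X-1", "X-2")),
        "Y": SampleGroup("Y", ("Y-1",)),
    }
    return build_dataset(maps, toy_emissions, groups)
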