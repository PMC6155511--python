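import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import repenroll as rp


@pytest.fixture(scope="session")
def null_model():
    """Packaged synthetic screener population (intermediate matrix built once)."""
    return rp.default_null_model()


@pytest.fixture
def tiny_schemas():
    return [
        rp.FieldSchema(name="item1", categories=(1, 2, 3, 4, 5),
                       weights={1: 0, 2: 1, 3: 2, 4: 3, 5: 4}),
        rp.FieldSchema(name="item2", categories=(1, 2, 3, 4, 5),
                       weights={1: 0, 2: 2, 3: 4, 4: 6, 5: 8}),
        rp.FieldSchema(name="age", kind="integer", categories=tuple(range(18, 26))),
    ]


@pytest.fixture
def tiny_survey(tiny_schemas):
    values = np.array(
        [
            [1, 2, 19],
            [3, 3, 22],
            [5, 4, 25],
            [2, 2, 20],
            [4, 5, 18],
        ],
        dtype=float,
    )
    return rp.SurveyMatrix(values, tiny_schemas)


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_complete_linkage(d: np.ndarray):
    """O(N^3) greedy agglomeration: merge the pair of clusters with the
    smallest maximum inter-point distance; returns [(set, set, height), ...]."""
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        merges.append((clusters[i], clusters[j], h))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def scipy_linkage_to_merges(z: np.ndarray, n: int):
    """Convert a scipy linkage matrix to [(set, set, height), ...]."""
    nodes = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_idx, (left, right, height, _) in enumerate(z):
        a, b = nodes[int(left)], nodes[int(right)]
        merges.append((a, b, float(height)))
        nodes[n + row_idx] = a | b
    return merges


def naive_silhouette(d: np.ndarray, labels: np.ndarray):
    """Direct per-observation evaluation of s(i) = (b - a) / max(a, b)."""
    n = d.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = np.flatnonzero((labels == labels[i]) & (np.arange(n) != i))
        if own.size == 0:
            continue
        a = d[i, own].mean()
        b = min(
            d[i, labels == c].mean() for c in np.unique(labels) if c != labels[i]
        )
        s[i] = (b - a) / max(a, b)
    return s
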