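import numpy as np
import pytest

from mapdh.fixtures import watermelon_image


@pytest.fixture(scope="session")
def watermelon():
    """The four-color 355x355 pixel-art image and its ground-truth manifest."""
    return watermelon_image()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def between_class_variances(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent Otsu oracle: between-class variance of every split point
    of a 256-bin histogram, by exhaustive scan.

    Returns ``(variances, centers)`` where ``variances[i]`` is the
    between-class variance of splitting after histogram bin ``i`` (class 0
    = bins 0..i) and ``centers`` are the bin centers. A candidate Otsu
    threshold is optimal iff its split attains ``variances.max()``; ties
    across empty bins make the threshold itself non-unique.
    """
    arr = np.asarray(img, dtype=np.float64).ravel()
    hist, edges = np.histogram(arr, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    variances = np.full(255, -np.inf)
    for i in range(1, 256):
        w0, w1 = hist[:i].sum(), hist[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:i] * centers[:i]).sum() / w0
        m1 = (hist[i:] * centers[i:]).sum() / w1
        variances[i - 1] = w0 * w1 * (m0 - m1) ** 2
    return variances, centers


def otsu_is_optimal(img: np.ndarray, threshold: float) -> bool:
    """Check that a threshold attains the exhaustive-scan variance maximum."""
    variances, centers = between_class_variances(img)
    split = int(np.searchsorted(centers, threshold, side="right")) - 1
    if not 0 <= split < variances.size:
        return False
    return bool(np.isclose(variances[split], variances.max(), rtol=1e-9))


def exhaustive_min_sse(points: np.ndarray, k: int) -> float:
    """Global minimum within-cluster SSE over all assignments of the points
    into at most k clusters, by exhaustive enumeration (tiny n only)."""
    from itertools import product

    n = len(points)
    best = np.inf
    for assign in product(range(k), repeat=n):
        sse = 0.0
        for c in range(k):
            idx = [i for i, a in enumerate(assign) if a == c]
            if idx:
                pts = points[idx]
                sse += ((pts - pts.mean(axis=0)) ** 2).sum()
        if sse < best:
            best = sse
    return float(best)


def partition_sse(points: np.ndarray, labels: np.ndarray) -> float:
    """SSE of a partition with centroids at the cluster means."""
    sse = 0.0
    for c in np.unique(labels):
        pts = points[labels == c]
        sse += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(sse)
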