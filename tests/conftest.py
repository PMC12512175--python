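import numpy as np
import pytest

from mosaic_order import Field, PointPattern, generate_hardcore


@pytest.fixture
def field():
    return Field(400.0, 400.0)


def inset_hardcore(n: int, r_min: float, outer: float, margin: float, seed: int) -> PointPattern:
    """Hard-core pattern kept ``margin`` μm away from the window border.

    Used for rendering/detection round trips: spots whose blobs are clipped
    by the image border have biased centroids, which is a property of the
    scene, not of the detector.
    """
    inner = generate_hardcore(n, r_min, Field(outer - 2 * margin, outer - 2 * margin), seed)
    return PointPattern(inner.points + margin, Field(outer, outer), inner.subtype)


def brute_force_min_distance(points: np.ndarray) -> float:
    pts = np.asarray(points)
    best = np.inf
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            best = min(best, float(np.linalg.norm(pts[i] - pts[j])))
    return best
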