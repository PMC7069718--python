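import numpy as np
import pytest

from dsgcdend.morphology import Morphology, generate_synthetic_morphology, place_rois


def straight_cable(n_edges: int, step: float = 2.0, radius: float = 0.5) -> Morphology:
    """Unbranched cable along +x with ``n_edges`` segments of ``step`` µm."""
    n = n_edges + 1
    ids = np.arange(1, n + 1)
    labels = np.full(n, 3)
    labels[0] = 1
    xyz = np.column_stack([np.arange(n) * step, np.zeros(n), np.zeros(n)])
    rad = np.full(n, radius)
    parents = np.concatenate([[-1], ids[:-1]])
    return Morphology(ids, labels, xyz, rad, parents)


def y_tree(arm: float = 10.0, step: float = 2.0) -> Morphology:
    """Root --(10 µm)--> branch point --> two 10 µm arms at ±45°."""
    ids, labels, xyz, rad, par = [1], [1], [[0.0, 0.0, 0.0]], [1.0], [-1]
    nid = 1
    # trunk along +x
    n_tr = int(round(arm / step))
    for k in range(1, n_tr + 1):
        nid += 1
        ids.append(nid); labels.append(3)
        xyz.append([k * step, 0.0, 0.0]); rad.append(0.5); par.append(nid - 1)
    bp = nid
    for sgn in (+1, -1):
        prev = bp
        for k in range(1, n_tr + 1):
            nid += 1
            ids.append(nid); labels.append(3)
            dx = k * step / np.sqrt(2)
            xyz.append([arm + dx, sgn * dx, 0.0]); rad.append(0.4); par.append(prev)
            prev = nid
    return Morphology(np.array(ids), np.array(labels), np.array(xyz),
                      np.array(rad), np.array(par))


@pytest.fixture(scope="session")
def arbor():
    return generate_synthetic_morphology(220.0, 4, seed=1)


@pytest.fixture(scope="session")
def arbor_rois(arbor):
    return place_rois(arbor, 8.0, seed=2)


@pytest.fixture(scope="session")
def cable_50():
    """50-ROI imaging cable used by the noise-correlation analyses."""
    m = straight_cable(51, step=2.0)
    rois = place_rois(m, 2.0, seed=0)
    return m, rois


@pytest.fixture(scope="session")
def cable_50_distances(cable_50):
    m, rois = cable_50
    return rois.cable_distance_matrix(m)
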