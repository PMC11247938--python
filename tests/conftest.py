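import numpy as np
import pytest

from ancmorph.swc_io import NeuriteTrace, SWCNode


def build_trace(rows, name="t", group="untagged", reaches_skin=False):
    """Trace from (id, x, y, z, parent) or (id, x, y, z, radius, parent) rows."""
    nodes = []
    for row in rows:
        if len(row) == 5:
            nid, x, y, z, parent = row
            radius = 1.0
        else:
            nid, x, y, z, radius, parent = row
        nodes.append(SWCNode(nid, 0, float(x), float(y), float(z),
                             float(radius), parent))
    return NeuriteTrace(name, nodes, group=group, reaches_skin=reaches_skin)


def random_rotation(rng):
    """Uniform random 3D rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def straight_path():
    """Three collinear nodes along z: 0, 5, 10 μm."""
    return build_trace([(1, 0, 0, 0, -1), (2, 0, 0, 5, 1), (3, 0, 0, 10, 2)])


@pytest.fixture
def y_tree():
    """Root → (0,0,50), then children at (±30, 0, 90): edges 50 + 2·50 μm."""
    return build_trace([
        (1, 0, 0, 0, -1),
        (2, 0, 0, 50, 1),
        (3, 30, 0, 90, 2),
        (4, -30, 0, 90, 2),
    ])
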