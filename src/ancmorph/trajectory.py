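"""Average exit-trajectory vectors of traced nerves.

A nerve's exit direction is summarised by the vector from its root (the
point where it leaves the axial nerve cord) to the centre of its traced
points.  Two centroid conventions are offered: the plain mean of the node
coordinates (the default, matching point lists pulled straight from a
tracer) and the arc-length-weighted centroid of the polyline, which is
robust to uneven node density in manual traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .swc_io import NeuriteTrace


@dataclass
class TrajectoryVector:
    """Root-to-centroid displacement of one trace."""

    trace_name: str
    group: str
    origin: np.ndarray  # trace root, μm
    vector: np.ndarray  # μm, or dimensionless when normalized
    norm_length: float | None = None

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector))


def average_trajectory(trace: NeuriteTrace,
                       weighting: str = "nodes") -> TrajectoryVector:
    """Vector from the trace root to the centre of the traced process.

    Parameters
    ----------
    trace
        Nerve with at least two nodes.
    weighting
        ``"nodes"``: centre is the unweighted mean of all node coordinates,
        root included.  ``"arc_length"``: centre is the line-density centroid
        of the polyline (each edge contributes its midpoint weighted by its
        length), insensitive to how densely the tracer dropped points.
    """
    if len(trace.nodes) < 2:
        raise DegenerateInputError(
            f"trace {trace.name!r} has fewer than 2 nodes; no trajectory"
        )
    root = trace.root.xyz
    if weighting == "nodes":
        center = trace.coords().mean(axis=0)
    elif weighting == "arc_length":
        e = trace.edges()
        lengths = np.linalg.norm(e[:, 1] - e[:, 0], axis=1)
        if lengths.sum() <= 0:
            raise DegenerateInputError(
                f"trace {trace.name!r} has zero total edge length"
            )
        midpoints = e.mean(axis=1)
        center = (midpoints * lengths[:, None]).sum(axis=0) / lengths.sum()
    else:
        raise ParameterError(
            f"weighting must be 'nodes' or 'arc_length', got {weighting!r}"
        )
    return TrajectoryVector(
        trace_name=trace.name,
        group=trace.group,
        origin=root,
        vector=center - root,
    )


def normalize_trajectories(vs: Iterable[TrajectoryVector],
                           norm_length: float) -> list[TrajectoryVector]:
    """Divide each vector by ``norm_length`` (the skin-reaching nerve length)."""
    if norm_length <= 0:
        raise ParameterError(f"norm_length must be positive, got {norm_length}")
    return [
        replace(v, vector=v.vector / norm_length, norm_length=norm_length)
        for v in vs
    ]
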