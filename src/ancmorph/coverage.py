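"""Circular angular-coverage statistics for labelled nerve-tip sets.

Sucker innervation is quantified by a "suckerotopy" statistic: the traced
tips of the oral nerves are centred on their own centroid, projected to the
plane of the sucker circle, normalized to unit vectors, and the circle is
partitioned among the tip groups (external side, ExA, versus internal side,
InA).  Each group's angular extent divided by 360° is the fraction of the
sucker that group covers.

The partition places a boundary at the circular midpoint between each
adjacent pair of differently-labelled tips, which is identical to assigning
every angle on the circle to the group of its nearest tip in circular
distance; by construction the group extents always sum to 360°.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .swc_io import TipSet

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class CircleTips:
    """Tips reduced to unit vectors on the circle, with group labels.

    Angles are degrees in [0, 360), counter-clockwise from the +x axis of
    the projected frame (the first coordinate axis remaining after the
    projection axis is dropped).
    """

    angles_deg: np.ndarray
    labels: list[str]
    trace_names: list[str]
    projection_axis: str

    def __len__(self) -> int:
        return len(self.labels)

    def unit_vectors(self) -> np.ndarray:
        th = np.deg2rad(self.angles_deg)
        return np.column_stack([np.cos(th), np.sin(th)])


@dataclass
class CoverageResult:
    """Partition of the circle among tip groups."""

    extent_deg: dict[str, float]  # per-group angular extent, sums to 360
    fraction: dict[str, float]  # extent / 360, sums to 1
    boundaries_deg: np.ndarray  # sorted boundary angles
    tip_angles_deg: np.ndarray  # sorted tip angles
    tip_labels: list[str]  # labels in tip-angle order


def center_and_normalize(tips: TipSet) -> CircleTips:
    """Centre tips on their centroid, project, and scale to the unit circle.

    The centroid of all tips is translated to the origin, the projection
    axis coordinate is dropped, and each remaining 2D vector is scaled to
    magnitude 1 so the tips lie on a circle.  A tip that coincides with the
    centroid in the projected plane has no direction and is rejected.
    """
    if len(tips) < 2:
        raise DegenerateInputError("need at least 2 tips to form a circle")
    pts = tips.points()
    if np.allclose(pts, pts[0]):
        raise DegenerateInputError("all tips coincide; no circle can be formed")
    axis = tips.projection_axis
    if axis not in _AXIS_INDEX:
        raise ParameterError(f"projection_axis must be one of x/y/z, got {axis!r}")
    centered = pts - pts.mean(axis=0)
    keep = [i for i in range(3) if i != _AXIS_INDEX[axis]]
    planar = centered[:, keep]
    norms = np.linalg.norm(planar, axis=1)
    bad = np.nonzero(norms < 1e-12)[0]
    if bad.size:
        i = int(bad[0])
        raise DegenerateInputError(
            f"tip {i} (trace {tips.tips[i].trace_name!r}) coincides with the "
            "tip centroid in the projected plane; its angle is undefined"
        )
    angles = np.degrees(np.arctan2(planar[:, 1], planar[:, 0])) % 360.0
    return CircleTips(
        angles_deg=angles,
        labels=list(tips.groups()),
        trace_names=[t.trace_name for t in tips.tips],
        projection_axis=axis,
    )


def angular_coverage(tips: CircleTips | TipSet) -> CoverageResult:
    """Partition the circle among tip groups by nearest tip.

    Adjacent tips with the same label pass their whole separating arc to
    that group; between differently-labelled tips a boundary is placed at
    the circular midpoint and each side takes half the arc.  With a single
    group present that group covers 100% (a warning is issued); ties (two
    differently-labelled tips at one angle) give zero-width arcs with the
    boundary at that angle.
    """
    if isinstance(tips, TipSet):
        tips = center_and_normalize(tips)
    n = len(tips)
    if n == 0:
        raise ParameterError("empty tip set")
    order = np.argsort(tips.angles_deg, kind="stable")
    angles = tips.angles_deg[order]
    labels = [tips.labels[i] for i in order]
    groups = sorted(set(labels))

    extent = {g: 0.0 for g in groups}
    boundaries: list[float] = []
    if len(groups) == 1:
        warnings.warn(
            f"only one tip group ({groups[0]!r}) present; it covers the "
            "full circle",
            stacklevel=2,
        )
        extent[groups[0]] = 360.0
    else:
        # consecutive arcs in sorted order; the last wraps past 0°
        arcs = np.empty(n)
        arcs[: n - 1] = np.diff(angles)
        arcs[n - 1] = 360.0 - (angles[-1] - angles[0])
        for i in range(n):
            j = (i + 1) % n
            arc = arcs[i]
            if labels[i] == labels[j]:
                extent[labels[i]] += arc
            else:
                extent[labels[i]] += arc / 2.0
                extent[labels[j]] += arc / 2.0
                boundaries.append((angles[i] + arc / 2.0) % 360.0)

    return CoverageResult(
        extent_deg=extent,
        fraction={g: e / 360.0 for g, e in extent.items()},
        boundaries_deg=np.sort(np.array(boundaries)),
        tip_angles_deg=angles,
        tip_labels=labels,
    )


def coverage_report(result: CoverageResult) -> dict:
    """Human-readable summary: percentages to 0.1, boundaries, tip counts."""
    groups = sorted(result.extent_deg)
    pct = {g: round(100.0 * result.fraction[g], 1) for g in groups}
    counts = {g: result.tip_labels.count(g) for g in groups}
    return {
        "percent": pct,
        "extent_deg": {g: result.extent_deg[g] for g in groups},
        "boundaries_deg": [float(b) for b in result.boundaries_deg],
        "tip_counts": counts,
        "text": ", ".join(f"{g} {pct[g]:.1f}%" for g in groups),
    }


def coverage_by_grid(tips: CircleTips, n_grid: int = 36000) -> dict[str, float]:
    """Brute-force nearest-tip assignment on a uniform angular grid.

    Independent cross-check of :func:`angular_coverage`: each of ``n_grid``
    angles is assigned to the group of its nearest tip in circular distance
    and per-group fractions of grid points are returned (as extents in
    degrees).  Agreement is within 360°/n_grid of the exact partition.
    """
    grid = np.arange(n_grid) * (360.0 / n_grid)
    d = np.abs(grid[:, None] - tips.angles_deg[None, :])
    d = np.minimum(d, 360.0 - d)
    nearest = np.argmin(d, axis=1)
    labels = np.array(tips.labels)
    out = {}
    for g in sorted(set(tips.labels)):
        out[g] = 360.0 * float(np.mean(labels[nearest] == g))
    return out
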