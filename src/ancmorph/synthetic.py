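"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to this package are microscopy-derived: manually traced nerves
(SWC), measurement tables typed in from image tools, and DAPI image patches.
None are distributable with the package, so each generator here emulates
the *statistical structure* the analysis assumes and emits machine-readable
ground truth alongside:

* rooted branching trees with shell-crossing counts from an independent
  dense-resampling oracle;
* planar tip sets drawn from known angular arcs per group, with the exact
  coverage fractions the arcs imply;
* segment-measurement tables with proximal→distal taper, an ExA−InA width
  offset and Gaussian noise, with the generating parameters attached;
* images of disjoint Gaussian blobs with known counts and centroids.

Every generator is a pure function of its spec (seed included); each draws
from its own named pseudo-random stream so adding a generator never
perturbs existing fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .nuclei import NucleiImage
from .sholl import ShollProfile
from .swc_io import NeuriteTrace, SWCNode, Tip, TipSet

# stable per-generator stream ids (never renumber)
_STREAMS = {"trace": 1, "tipset": 2, "table": 3, "image": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(_STREAMS[stream],)
    ))


# ---------------------------------------------------------------------------
# dense-resampling Sholl oracle
# ---------------------------------------------------------------------------

def sholl_profile_dense(trace: NeuriteTrace, step: float = 10.0,
                        spacing: float = 0.01,
                        center: Sequence[float] | None = None) -> ShollProfile:
    """Sholl counts by brute-force resampling of the polyline.

    Each edge is sampled every ``spacing`` μm (endpoints included) and sign
    changes of (distance-to-center − r) between consecutive samples are
    counted per shell.  A node lying exactly on a shell is counted once iff
    the last nonzero sign on its parent edge differs from the first nonzero
    sign on some child edge.  Deliberately independent of the analytic
    quadratic solver in :mod:`ancmorph.sholl`; used as ground truth.
    """
    if step <= 0 or spacing <= 0:
        raise ParameterError("step and spacing must be positive")
    c = trace.root.xyz if center is None else np.asarray(center, dtype=float)
    idx = {n.node_id: k for k, n in enumerate(trace.nodes)}
    coords = trace.coords()
    node_dist = np.linalg.norm(coords - c, axis=1)
    max_dist = float(node_dist.max())
    if max_dist <= 1e-9:
        return ShollProfile(trace.name, c, step, radii=np.array([step]),
                            counts=np.zeros(1, dtype=int))
    n_shells = max(1, int(np.ceil(max_dist / step - 1e-9)))
    radii = step * np.arange(1, n_shells + 1, dtype=float)

    # sample every edge; record which samples belong to which edge
    dists, edge_slices, edge_child = [], [], []
    offset = 0
    for n in trace.nodes:
        if n.parent_id == -1:
            continue
        p = coords[idx[n.parent_id]]
        q = coords[idx[n.node_id]]
        L = float(np.linalg.norm(q - p))
        m = max(1, int(np.ceil(L / spacing)))
        ts = np.linspace(0.0, 1.0, m + 1)
        # also sample the point of closest approach to the centre, so dips
        # narrower than the spacing still register a sign change
        d = q - p
        dd = float(d @ d)
        if dd > 0:
            t_star = float(-((p - c) @ d) / dd)
            if 0.0 < t_star < 1.0:
                ts = np.sort(np.append(ts, t_star))
        pts = p[None, :] + ts[:, None] * (q - p)[None, :]
        dists.append(np.linalg.norm(pts - c, axis=1))
        edge_slices.append((offset, offset + len(ts)))
        edge_child.append(n.node_id)
        offset += len(ts)
    all_d = np.concatenate(dists)
    # sample pairs that are consecutive within one edge
    within = np.ones(len(all_d) - 1, dtype=bool)
    for (lo, hi) in edge_slices:
        if hi < len(all_d):
            within[hi - 1] = False

    kids = trace.children_map()
    parent_edge = {child: k for k, child in enumerate(edge_child)}

    counts = np.zeros(n_shells, dtype=int)
    for k, r in enumerate(radii):
        tol = 1e-9 * max(1.0, r)
        z = all_d - r
        s = np.where(np.abs(z) <= tol, 0, np.sign(z)).astype(int)
        if (s == 0).any():
            # zeros occur only when nodes sit exactly on a shell: fall back
            # to a per-edge count dropping zero samples
            total = 0
            for (lo, hi) in edge_slices:
                seq = s[lo:hi]
                seq = seq[seq != 0]
                if len(seq) > 1:
                    total += int(np.sum(seq[1:] != seq[:-1]))
            # node-on-shell crossings
            for n in trace.nodes:
                if n.parent_id == -1 or not kids[n.node_id]:
                    continue
                if abs(node_dist[idx[n.node_id]] - r) > tol:
                    continue
                lo, hi = edge_slices[parent_edge[n.node_id]]
                before = s[lo:hi]
                before = before[before != 0]
                if len(before) == 0:
                    continue
                s_in = before[-1]
                for ch in kids[n.node_id]:
                    lo2, hi2 = edge_slices[parent_edge[ch]]
                    after = s[lo2:hi2]
                    after = after[after != 0]
                    if len(after) and after[0] == -s_in:
                        total += 1
                        break
            counts[k] = total
        else:
            counts[k] = int(np.sum((s[1:] * s[:-1] == -1) & within))
    return ShollProfile(trace.name, c, step, radii=radii, counts=counts)


# ---------------------------------------------------------------------------
# trace generators
# ---------------------------------------------------------------------------

@dataclass
class TraceSpec:
    """Recipe for a synthetic nerve trace.

    kind ``straight``: a radial path of ``length`` μm split into ``n_nodes``
    nodes.  kind ``y_tree``: one stem to ``bifurcation_radius`` then two
    branches whose tips sit exactly at ``tip_radius`` from the root.  kind
    ``random_tree``: a stochastic branching tree (``max_depth`` levels,
    segment lengths uniform on ``edge_length_range``).  kind
    ``radial_cone``: ``n_branches`` near-radial paths inside a cone of
    ``cone_half_angle_deg`` about ``cone_axis``.
    """

    kind: str = "random_tree"
    seed: int = 0
    name: str = "synthetic"
    group: str = "untagged"
    length: float = 95.0
    n_nodes: int = 10
    bifurcation_radius: float = 50.0
    tip_radius: float = 100.0
    max_depth: int = 3
    branch_prob: float = 0.6
    edge_length_range: tuple[float, float] = (5.0, 15.0)
    segments_per_branch: int = 4
    cone_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    cone_half_angle_deg: float = 30.0
    n_branches: int = 5
    step: float = 10.0


def _nodes_from_polylines(polylines: list[np.ndarray]) -> list[SWCNode]:
    """Join polylines (each starting at an existing point or the origin)."""
    # first polyline starts at the root; subsequent ones attach to the node
    # nearest their first point (exact match expected)
    nodes: list[SWCNode] = []
    coord_to_id: dict[tuple, int] = {}
    next_id = 1

    def add(pt: np.ndarray, parent: int) -> int:
        nonlocal next_id
        nid = next_id
        nodes.append(SWCNode(nid, 0, float(pt[0]), float(pt[1]), float(pt[2]),
                             0.5, parent))
        coord_to_id[tuple(np.round(pt, 9))] = nid
        next_id += 1
        return nid

    for poly in polylines:
        key = tuple(np.round(poly[0], 9))
        if key in coord_to_id:
            parent = coord_to_id[key]
            start = 1
        else:
            parent = -1
            start = 0 if not nodes else 1
            if nodes:  # disconnected start: attach to root (should not happen)
                parent = 1
        for pt in poly[start:] if parent != -1 else poly:
            parent = add(pt, parent)
    return nodes


def gen_trace(spec: TraceSpec) -> tuple[NeuriteTrace, ShollProfile]:
    """Generate a synthetic trace and its oracle Sholl profile.

    The ground-truth profile is computed with the 0.01 μm dense-resampling
    oracle, never with the analytic solver under test.
    """
    rng = _rng(spec.seed, "trace")
    if spec.length <= 0 or spec.tip_radius <= 0:
        raise ParameterError("lengths must be positive")

    if spec.kind == "straight":
        direction = np.array([0.0, 0.0, 1.0])
        ts = np.linspace(0.0, spec.length, max(2, spec.n_nodes))
        poly = ts[:, None] * direction[None, :]
        nodes = _nodes_from_polylines([poly])
    elif spec.kind == "y_tree":
        if spec.tip_radius <= spec.bifurcation_radius:
            raise ParameterError("tip_radius must exceed bifurcation_radius")
        b, t = spec.bifurcation_radius, spec.tip_radius
        stem = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, b]])
        # tips at exactly distance t from the root: (±0.6 t, 0, 0.8 t)
        left = np.array([[0.0, 0.0, b], [-0.6 * t, 0.0, 0.8 * t]])
        right = np.array([[0.0, 0.0, b], [0.6 * t, 0.0, 0.8 * t]])
        nodes = _nodes_from_polylines([stem, left, right])
    elif spec.kind == "random_tree":
        polylines = []

        def grow(start: np.ndarray, direction: np.ndarray, depth: int) -> None:
            pts = [start]
            d = direction / np.linalg.norm(direction)
            for _ in range(spec.segments_per_branch):
                L = rng.uniform(*spec.edge_length_range)
                d = d + 0.4 * rng.normal(size=3)
                d /= np.linalg.norm(d)
                pts.append(pts[-1] + L * d)
            poly = np.array(pts)
            polylines.append(poly)
            if depth < spec.max_depth:
                for _ in range(2):
                    if rng.random() < spec.branch_prob:
                        grow(poly[-1], d + rng.normal(size=3), depth + 1)

        grow(np.zeros(3), np.array([0.0, 0.0, 1.0]) + 0.3 * rng.normal(size=3), 1)
        nodes = _nodes_from_polylines(polylines)
    elif spec.kind == "radial_cone":
        axis = np.asarray(spec.cone_axis, dtype=float)
        axis /= np.linalg.norm(axis)
        half = np.deg2rad(spec.cone_half_angle_deg)
        # orthonormal frame around the axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(axis @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(axis, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        polylines = []
        for _ in range(spec.n_branches):
            theta = rng.uniform(0, half)
            phi = rng.uniform(0, 2 * np.pi)
            d = (np.cos(theta) * axis
                 + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2))
            ts = np.linspace(0.0, spec.length, max(2, spec.n_nodes))
            polylines.append(np.zeros(3)[None, :] + ts[:, None] * d[None, :])
        nodes = _nodes_from_polylines(polylines)
    else:
        raise ParameterError(f"unknown trace kind {spec.kind!r}")

    trace = NeuriteTrace(spec.name, nodes, group=spec.group)
    truth = sholl_profile_dense(trace, step=spec.step)
    return trace, truth


# ---------------------------------------------------------------------------
# tip-set generator
# ---------------------------------------------------------------------------

@dataclass
class TipSpec:
    """Recipe for a labelled tip set drawn from angular arcs.

    ``arcs`` maps each group to one ``(start_deg, width_deg)`` arc; arcs
    must not overlap.  Tips are uniform in angle within their group's arc,
    at radius ``radius`` with Gaussian radial jitter, and with Gaussian
    jitter along the projection (proximal–distal) axis.

    With ``allocation="proportional"`` (default) each group's tip count is
    proportional to its arc width, so the angular density is uniform around
    the circle — the radially symmetric decoration real suckers show, and
    the regime in which the tip centroid is a consistent estimator of the
    circle centre (the centering step of the coverage statistic assumes
    this).  ``allocation="equal"`` gives every group ``n_per_group`` tips
    regardless of width; with unequal arcs this displaces the centroid and
    biases the recovered fractions.
    """

    arcs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ExA": (0.0, 216.0), "InA": (216.0, 144.0)}
    )
    n_per_group: int = 100
    allocation: str = "proportional"
    radius: float = 50.0
    radial_jitter: float = 5.0
    axial_jitter: float = 10.0
    projection_axis: str = "z"
    seed: int = 0


def _arc_ground_truth(arcs: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Limit coverage fraction per group: arc width + half adjacent gaps.

    A gap between two arcs of the same group belongs wholly to that group;
    a gap between arcs of different groups is split at its midpoint (where
    the nearest-tip boundary converges as n → ∞).
    """
    items = sorted(arcs.items(), key=lambda kv: kv[1][0])
    n = len(items)
    extent = {g: 0.0 for g in arcs}
    for g, (_, width) in items:
        extent[g] += width
    for i in range(n):
        g_i, (s_i, w_i) = items[i]
        g_j, (s_j, _) = items[(i + 1) % n]
        end_i = s_i + w_i
        gap = (s_j - end_i) % 360.0 if n > 1 else 360.0 - w_i
        if i == n - 1:
            gap = (items[0][1][0] + 360.0) - end_i
        if g_i == g_j:
            extent[g_i] += gap
        else:
            extent[g_i] += gap / 2.0
            extent[g_j] += gap / 2.0
    return {g: e / 360.0 for g, e in extent.items()}


def gen_tipset(spec: TipSpec) -> tuple[TipSet, dict[str, float]]:
    """Generate labelled tips on arcs plus the exact limiting fractions."""
    items = sorted(spec.arcs.items(), key=lambda kv: kv[1][0])
    for (g1, (s1, w1)), (g2, (s2, _)) in zip(items, items[1:]):
        if w1 <= 0:
            raise ParameterError(f"arc width for {g1!r} must be positive")
        if s1 + w1 > s2 + 1e-12:
            raise ParameterError(f"arcs for {g1!r} and {g2!r} overlap")
    g_last, (s_last, w_last) = items[-1]
    if len(items) > 1 and s_last + w_last > items[0][1][0] + 360.0 + 1e-12:
        raise ParameterError(f"arc for {g_last!r} wraps onto the first arc")

    rng = _rng(spec.seed, "tipset")
    ax = {"x": 0, "y": 1, "z": 2}[spec.projection_axis]
    plane = [i for i in range(3) if i != ax]
    if spec.allocation == "proportional":
        mean_width = np.mean([w for _, w in spec.arcs.values()])
        counts = {g: max(1, int(round(spec.n_per_group * w / mean_width)))
                  for g, (_, w) in spec.arcs.items()}
    elif spec.allocation == "equal":
        counts = {g: spec.n_per_group for g in spec.arcs}
    else:
        raise ParameterError(
            f"allocation must be 'proportional' or 'equal', got "
            f"{spec.allocation!r}"
        )
    tips = []
    for g, (start, width) in items:
        n_g = counts[g]
        theta = np.deg2rad(start + width * rng.random(n_g))
        r = spec.radius + spec.radial_jitter * rng.normal(size=n_g)
        axial = spec.axial_jitter * rng.normal(size=n_g)
        for k in range(n_g):
            pt = np.zeros(3)
            pt[plane[0]] = r[k] * np.cos(theta[k])
            pt[plane[1]] = r[k] * np.sin(theta[k])
            pt[ax] = axial[k]
            tips.append(Tip(tuple(pt), g, f"synthetic_{g}_{k}"))
    return (TipSet(tips, projection_axis=spec.projection_axis),
            _arc_ground_truth(spec.arcs))


def gen_random_circle_tips(n_tips: int, groups: Sequence[str] = ("ExA", "InA"),
                           seed: int = 0):
    """Random labelled tips already in unit-circle form, grid-commensurate.

    Angles are drawn without replacement from the lattice
    ``{0.005° + k·0.02°}``, so every midpoint boundary between two tips
    falls exactly halfway between points of a 36,000-point (0.01°) grid.  A
    nearest-tip grid assignment at that resolution then measures each arc
    exactly, making the grid cross-check of the midpoint partition free of
    discretization error.
    """
    from .coverage import CircleTips

    if n_tips > 18000:
        raise ParameterError("lattice supports at most 18000 distinct tips")
    rng = _rng(seed, "tipset")
    k = rng.choice(18000, size=n_tips, replace=False)
    angles = 0.005 + 0.02 * k.astype(float)
    labels = [str(g) for g in rng.choice(list(groups), size=n_tips)]
    return CircleTips(angles_deg=angles, labels=labels,
                      trace_names=[f"lattice_{i}" for i in range(n_tips)],
                      projection_axis="z")


def gen_random_tipset(n_tips: int, groups: Sequence[str] = ("ExA", "InA"),
                      seed: int = 0) -> TipSet:
    """Tips at uniform random angles with uniform random labels (no arcs)."""
    rng = _rng(seed, "tipset")
    theta = rng.uniform(0, 2 * np.pi, size=n_tips)
    r = rng.uniform(20.0, 60.0, size=n_tips)
    labels = rng.choice(list(groups), size=n_tips)
    tips = [
        Tip((r[k] * np.cos(theta[k]), r[k] * np.sin(theta[k]),
             rng.normal() * 5.0), str(labels[k]), f"rnd_{k}")
        for k in range(n_tips)
    ]
    return TipSet(tips, projection_axis="z")


# ---------------------------------------------------------------------------
# measurement-table generator
# ---------------------------------------------------------------------------

@dataclass
class TableSpec:
    """Recipe for synthetic segment and sucker measurement tables.

    Defaults emulate the measured structure of the octopus arm axial nerve
    cord: about 7.5 segments per sucker, segment widths tapering from
    proximal to distal, external-side (ExA) segments wider than internal
    (InA), and 24 replicates per condition.  They are synthetic defaults
    informed by that structure, not data.
    """

    n_suckers: int = 6
    segments_per_sucker_target: float = 7.5
    base_width: float = 40.0  # μm, proximal InA mean
    taper_rate: float = 8.0  # μm lost per position step
    territory_offset: float = 5.0  # ExA − InA, μm
    noise_sd: float = 3.0  # μm
    count_sd: float = 0.0  # sd of total segment counts per six-sucker run
    acetabulum_base: float = 300.0  # μm
    acetabulum_taper: float = 60.0  # μm per position step
    replicates: int = 24  # per (position, territory) cell
    seed: int = 0


@dataclass
class SyntheticTables:
    segments: pd.DataFrame
    suckers: pd.DataFrame
    spec: TableSpec


_POSITIONS = ("proximal", "intermediate", "distal")
_SIDES = ("anterior", "posterior")
_TERRITORIES = ("ExA", "InA")


def gen_segment_table(spec: TableSpec) -> SyntheticTables:
    """Tidy segment and sucker tables with the generating parameters attached.

    Widths follow ``base − taper·position + offset·1[ExA] + N(0, sd)``; the
    ``replicates`` per (position, territory) cell are split evenly between
    the anterior and posterior sides.  Negative draws are resampled with a
    warning.  Sucker-run segment counts are drawn so that
    ``segments_per_sucker`` hits the target on average (exactly, when
    ``count_sd`` is 0).
    """
    if spec.replicates < 1:
        raise ParameterError("replicates must be >= 1")
    rng = _rng(spec.seed, "table")
    seg_rows = []
    for p_idx, pos in enumerate(_POSITIONS):
        for terr in _TERRITORIES:
            mean = (spec.base_width - spec.taper_rate * p_idx
                    + (spec.territory_offset if terr == "ExA" else 0.0))
            for rep in range(spec.replicates):
                side = _SIDES[rep % 2]
                w = mean + spec.noise_sd * rng.normal()
                tries = 0
                while w <= 0:
                    tries += 1
                    if tries == 1:
                        warnings.warn(
                            "negative width drawn; resampling", stacklevel=2
                        )
                    if tries > 1000:
                        raise ParameterError(
                            "cannot draw positive widths; lower noise_sd"
                        )
                    w = mean + spec.noise_sd * rng.normal()
                seg_rows.append({
                    "arm_id": "synthetic", "position": pos, "side": side,
                    "territory": terr, "width": float(w),
                })
    seg = pd.DataFrame(seg_rows)

    suck_rows = []
    total_target = spec.segments_per_sucker_target * spec.n_suckers
    for p_idx, pos in enumerate(_POSITIONS):
        counts = {}
        for s in _SIDES:
            val = total_target + spec.count_sd * rng.normal()
            counts[s] = max(0, int(round(val)))
        for k in range(spec.n_suckers):
            suck_rows.append({
                "arm_id": "synthetic", "position": pos, "sucker_index": k,
                "acetabulum_width": float(
                    spec.acetabulum_base - spec.acetabulum_taper * p_idx
                    + 0.05 * spec.acetabulum_base * rng.normal()
                ),
                "count_anterior": counts["anterior"],
                "count_posterior": counts["posterior"],
            })
    return SyntheticTables(seg, pd.DataFrame(suck_rows), spec)


# ---------------------------------------------------------------------------
# nuclei-image generator
# ---------------------------------------------------------------------------

def gen_nuclei_image(n_blobs: int, blob_sigma: float = 3.0,
                     image_size: tuple[int, int] = (128, 128),
                     pixel_size: float = 1.0,
                     seed: int = 0) -> tuple[NucleiImage, np.ndarray]:
    """Image of disjoint Gaussian blobs (peak 1, background 0) plus centroids.

    Blob centres are rejection-sampled to stay ≥ 8·σ apart and ≥ 4·σ from
    the border, so components are disjoint at any threshold above the
    inter-blob background.  Raises if placement fails in 10,000 attempts.
    Returned centroids are in μm, (row, col) order.
    """
    if n_blobs < 0 or blob_sigma <= 0:
        raise ParameterError("n_blobs must be >= 0 and blob_sigma positive")
    rng = _rng(seed, "image")
    h, w = image_size
    margin = 4.0 * blob_sigma
    min_sep = 8.0 * blob_sigma
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_blobs:
        attempts += 1
        if attempts > 10_000:
            raise ParameterError(
                f"could not place {n_blobs} blobs of sigma {blob_sigma} in a "
                f"{h}x{w} image without overlap"
            )
        cand = np.array([rng.uniform(margin, h - margin),
                         rng.uniform(margin, w - margin)])
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
    img = np.zeros((h, w), dtype=float)
    if centers:
        rr, cc = np.mgrid[0:h, 0:w]
        for c in centers:
            d2 = (rr - c[0]) ** 2 + (cc - c[1]) ** 2
            img = np.maximum(img, np.exp(-d2 / (2.0 * blob_sigma ** 2)))
    truth = np.array(centers, dtype=float).reshape(-1, 2) * pixel_size
    return NucleiImage(img, pixel_size=pixel_size), truth
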