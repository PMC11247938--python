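"""3D Sholl analysis of neurite traces.

The branching profile of a nerve is summarised by counting, for a series of
concentric spheres centred at the nerve's exit point (the trace root) and
spaced ``step`` μm apart, how many times the traced polyline crosses each
sphere.  Crossings are computed exactly from the quadratic in the segment
parameter of each parent→child edge, so the counts are free of sampling
error.  Profiles are optionally fit with a polynomial and their radii
normalized so the longest nerve (the one that reaches the skin) has length 1.

Conventions, chosen so the counts agree with a limit of perturbed geometry:

* an edge crossing the same sphere twice (re-entrant edge) contributes 2;
* a tangential touch (double root of the quadratic) contributes 0;
* a non-root node lying exactly on a sphere contributes a single crossing
  iff the signed distance-minus-radius strictly changes sign across it,
  i.e. the incoming parent side and at least one outgoing child side have
  opposite signs; a root or leaf exactly on a sphere contributes 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .swc_io import NeuriteTrace, TraceSet, path_length

__all__ = [
    "ShollProfile",
    "PolyFit",
    "sholl_profile",
    "fit_profile",
    "normalize_profiles",
]

# relative tolerance used to decide that a squared-distance expression is zero
_REL_TOL = 1e-9


@dataclass
class ShollProfile:
    """Intersection counts versus shell radius around one trace root."""

    trace_name: str
    center: np.ndarray
    step: float
    radii: np.ndarray  # increasing; (i+1)*step before normalization
    counts: np.ndarray  # non-negative ints, one per radius
    normalized: bool = False
    norm_length: float | None = None

    def denormalized(self) -> "ShollProfile":
        """Undo :func:`normalize_profiles`; identity on raw profiles."""
        if not self.normalized:
            return self
        return replace(
            self,
            radii=self.radii * self.norm_length,
            normalized=False,
            norm_length=None,
        )


@dataclass
class PolyFit:
    """Ordinary least-squares polynomial fit of a Sholl profile."""

    degree: int
    coefficients: np.ndarray  # ascending powers, length degree+1
    domain: tuple[float, float]

    def __call__(self, r: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(r, self.coefficients)


def _shell_radii(max_dist: float, step: float) -> np.ndarray:
    """Arithmetic radii step, 2·step, … up to the smallest multiple ≥ max_dist."""
    n = max(1, int(np.ceil(max_dist / step - _REL_TOL)))
    return step * np.arange(1, n + 1, dtype=float)


def _sign_with_tol(value: float, scale: float) -> int:
    tol = _REL_TOL * max(1.0, scale)
    if value > tol:
        return 1
    if value < -tol:
        return -1
    return 0


def _edge_quadratic(u: np.ndarray, d: np.ndarray) -> tuple[float, float, float]:
    """Coefficients of g(t) = |u + t d|^2 (minus r^2 goes in the constant)."""
    a = float(d @ d)
    b = float(2.0 * (u @ d))
    c = float(u @ u)
    return a, b, c


def _interior_crossings(a: float, b: float, c0: float, scale: float,
                        p_on_shell: bool, q_on_shell: bool) -> int:
    """Simple roots of a t² + b t + c0 strictly inside (0, 1).

    Roots coincident with an endpoint that lies on the shell are excluded
    here; those crossings are attributed to the node itself.
    """
    tol = _REL_TOL * max(1.0, scale)
    if a <= tol:  # zero-length edge
        return 0
    disc = b * b - 4.0 * a * c0
    if disc <= tol * scale:  # no real roots, or tangential double root
        return 0
    sq = np.sqrt(disc)
    count = 0
    for t in ((-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)):
        if not (1e-12 < t < 1.0 - 1e-12):
            continue
        if p_on_shell and t <= 1e-6:
            continue
        if q_on_shell and t >= 1.0 - 1e-6:
            continue
        count += 1
    return count


def sholl_profile(trace: NeuriteTrace, step: float = 10.0,
                  center: Sequence[float] | None = None) -> ShollProfile:
    """Exact 3D Sholl profile of a trace.

    Parameters
    ----------
    trace
        The nerve reconstruction.
    step
        Shell spacing in μm (default 10, the spacing used for nerve
        branching profiles around the axial-nerve-cord exit).
    center
        Sphere centre; defaults to the trace root (the nerve exit point).

    Returns
    -------
    ShollProfile
        Counts at radii step, 2·step, … extending to the smallest multiple
        of ``step`` at or beyond the most distant node.
    """
    if step <= 0:
        raise ParameterError(f"step must be positive, got {step}")
    c = trace.root.xyz if center is None else np.asarray(center, dtype=float)

    coords = trace.coords()
    node_ids = [n.node_id for n in trace.nodes]
    rel = coords - c
    node_dist = np.linalg.norm(rel, axis=1)
    max_dist = float(node_dist.max())

    if max_dist <= _REL_TOL:  # root-only or fully coincident trace
        return ShollProfile(trace.name, c, step,
                            radii=np.array([step]),
                            counts=np.zeros(1, dtype=int))

    radii = _shell_radii(max_dist, step)
    counts = np.zeros(len(radii), dtype=int)

    idx = {nid: k for k, nid in enumerate(node_ids)}
    kids = trace.children_map()

    # per-edge quadratics, keyed by the child node id
    edge_q: dict[int, tuple[float, float, float]] = {}
    for n in trace.nodes:
        if n.parent_id == -1:
            continue
        u = rel[idx[n.parent_id]]
        d = rel[idx[n.node_id]] - u
        edge_q[n.node_id] = _edge_quadratic(u, d)

    for k, r in enumerate(radii):
        r2 = r * r
        scale = max(1.0, r2)
        on_shell = {nid: _sign_with_tol(node_dist[idx[nid]] ** 2 - r2, scale) == 0
                    for nid in node_ids}
        total = 0
        for child_id, (a, b, cc) in edge_q.items():
            parent_id = trace.node(child_id).parent_id
            total += _interior_crossings(
                a, b, cc - r2, scale, on_shell[parent_id], on_shell[child_id]
            )
        # node-on-shell crossings: strict sign change across the node
        for nid in node_ids:
            if not on_shell[nid]:
                continue
            node = trace.node(nid)
            if node.parent_id == -1 or not kids[nid]:
                continue  # root or leaf exactly on a sphere: no sign change across
            a, b, _ = edge_q[nid]
            gprime_in = 2.0 * a + b  # dg/dt at t=1 on the incoming edge
            s_in = -_sign_with_tol(gprime_in, scale)
            if s_in == 0:
                s_in = 1  # quadratic opens upward: g(1−ε) > 0
            for child in kids[nid]:
                a_c, b_c, _ = edge_q[child]
                s_out = _sign_with_tol(b_c, scale)
                if s_out == 0:
                    s_out = 1
                if s_out == -s_in:
                    total += 1
                    break
        counts[k] = total

    return ShollProfile(trace.name, c, step, radii=radii, counts=counts)


def fit_profile(profile: ShollProfile, degree: int = 5) -> PolyFit:
    """Ordinary least-squares polynomial fit over (radius, count) pairs.

    The default degree of 5 matches the standard summary of nerve branching
    profiles.  Fitting is refused (not silently downgraded) when the profile
    has fewer than ``degree + 1`` shells.
    """
    n = len(profile.radii)
    if n < degree + 1:
        raise DegenerateInputError(
            f"profile has {n} shells; a degree-{degree} fit needs at least "
            f"{degree + 1}"
        )
    # Vandermonde least squares in a scaled domain for conditioning, then
    # convert back to plain ascending-power coefficients.
    series = np.polynomial.Polynomial.fit(
        profile.radii, profile.counts.astype(float), deg=degree
    )
    coeffs = series.convert().coef
    if len(coeffs) < degree + 1:
        coeffs = np.pad(coeffs, (0, degree + 1 - len(coeffs)))
    return PolyFit(
        degree=degree,
        coefficients=coeffs,
        domain=(0.0, float(profile.radii[-1])),
    )


def normalization_length(traces: TraceSet | Iterable[NeuriteTrace]) -> float:
    """Length of the skin-reaching nerve, or the longest nerve as fallback.

    Radii of Sholl profiles and trajectory vectors are expressed relative to
    the longest nerve in a preparation, identified anatomically as the nerve
    that reaches the skin.  If no trace carries the ``reaches_skin`` flag the
    maximum cable length in the set is used and a warning is issued.
    """
    traces = list(traces)
    flagged = [t for t in traces if t.reaches_skin]
    if flagged:
        return max(path_length(t) for t in flagged)
    warnings.warn(
        "no trace flagged reaches_skin; normalizing by the maximum path "
        "length in the set",
        stacklevel=2,
    )
    return max(path_length(t) for t in traces)


def normalize_profiles(profiles: Iterable[ShollProfile],
                       traces: TraceSet | Iterable[NeuriteTrace]) -> list[ShollProfile]:
    """Express profile radii as fractions of the skin-reaching nerve length.

    Counts are unchanged; each returned profile records the normalization
    length so the operation can be inverted.
    """
    norm = normalization_length(traces)
    if norm <= 0:
        raise ParameterError("normalization length must be positive")
    out = []
    for p in profiles:
        out.append(replace(p, radii=p.radii / norm, normalized=True,
                           norm_length=norm))
    return out
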