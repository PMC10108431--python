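"""Open-chain knot typing by geometric reduction and stochastic closure.

An open protein backbone has no well-defined knot type; it is assigned
the distribution of knot types obtained by closing the chain through
random points on a large sphere surrounding it and typing each closed
curve with the HOMFLY-PT engine.  The most frequent type across closures
is the chain's dominant knot.

Before typing, curves are simplified with KMT reduction (iterative
removal of vertices whose spanning triangle is pierced by no other
segment), which preserves the topology of a closed or end-fixed curve
while cutting the vertex count by an order of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .invariants import (
    DEFAULT_CROSSING_CAP,
    ClosedCurve,
    CrossingCapExceeded,
    DegenerateProjection,
    KnotLabel,
    UNKNOT,
    homfly,
    label_from_polynomial,
    project_to_diagram,
)
from .structures_io import BackboneChain

__all__ = [
    "KnotSpectrum",
    "kmt_reduce",
    "random_closure",
    "closure_point",
    "dominant_knot",
    "label_closed_curve",
    "DEFAULT_N_CLOSURES",
    "CLOSURE_RADIUS_FACTOR",
]

#: number of random closures for the headline (full-chain) call
DEFAULT_N_CLOSURES = 200

#: closure sphere radius as a multiple of the maximal centroid distance
CLOSURE_RADIUS_FACTOR = 10.0

_EPS = 1e-9


# ---------------------------------------------------------------------------
# KMT reduction
# ---------------------------------------------------------------------------

def _orient2(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _coplanar_segment_hits_triangle(
    p: np.ndarray, q: np.ndarray,
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    nrm: np.ndarray,
) -> bool:
    """2-D overlap test for a segment lying in the triangle's plane.

    Conservative: touching counts as a hit; used when the 3-D test
    degenerates because the whole neighbourhood is flat.
    """
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ nrm) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(nrm, ref)
    u /= np.linalg.norm(u)
    v = np.cross(nrm, u)
    to2 = lambda x: np.array([(x - a) @ u, (x - a) @ v])
    P, Q = to2(p), to2(q)
    A, B, C = to2(a), to2(b), to2(c)
    scale = max(np.abs(np.concatenate([P, Q, B, C]))) + 1e-12
    tol = 1e-9 * scale * scale

    def inside(X):
        s1 = _orient2(A, B, X)
        s2 = _orient2(B, C, X)
        s3 = _orient2(C, A, X)
        return (s1 >= -tol and s2 >= -tol and s3 >= -tol) or \
               (s1 <= tol and s2 <= tol and s3 <= tol)

    if inside(P) or inside(Q):
        return True
    for U, V in ((A, B), (B, C), (C, A)):
        d1 = _orient2(P, Q, U)
        d2 = _orient2(P, Q, V)
        d3 = _orient2(U, V, P)
        d4 = _orient2(U, V, Q)
        if d1 * d2 < -tol and d3 * d4 < -tol:
            return True
        # touching / collinear overlap: conservative hit when a point of
        # one segment lies (almost) on the other within its span
        for X, dd in ((U, d1), (V, d2)):
            if abs(dd) <= tol and min(P[0], Q[0]) - tol <= X[0] <= max(P[0], Q[0]) + tol \
                    and min(P[1], Q[1]) - tol <= X[1] <= max(P[1], Q[1]) + tol:
                return True
    return False


def _triangles_pierced(points: np.ndarray, closed: bool, idx: np.ndarray) -> np.ndarray:
    """Whether the triangle spanned at each candidate vertex is pierced.

    For candidate vertex i the triangle is (i-1, i, i+1) (cyclic when
    ``closed``).  A segment counts as piercing when it crosses the
    triangle's plane strictly inside the triangle, with conservative
    tolerances (borderline hits count as pierced, so the vertex is
    kept — correctness over aggressiveness).
    """
    n = len(points)
    if closed:
        seg_a = points
        seg_b = np.roll(points, -1, axis=0)
    else:
        seg_a = points[:-1]
        seg_b = points[1:]
    nseg = len(seg_a)
    out = np.zeros(len(idx), dtype=bool)
    for k, i in enumerate(idx):
        a = points[(i - 1) % n]
        b = points[i]
        c = points[(i + 1) % n]
        nrm = np.cross(b - a, c - a)
        area2 = np.linalg.norm(nrm)
        if area2 < 1e-12:
            continue  # degenerate triangle: removal is a no-op geometrically
        nrm = nrm / area2
        # segments sharing a vertex with the triangle cannot pierce it
        if closed:
            skip = {(i - 2) % n, (i - 1) % n, i % n, (i + 1) % n}
        else:
            skip = {j for j in (i - 2, i - 1, i, i + 1) if 0 <= j < nseg}
        d1 = (seg_a - a) @ nrm
        d2 = (seg_b - a) @ nrm
        cand = np.nonzero(d1 * d2 < 1e-12)[0]
        for j in cand:
            if j in skip:
                continue
            denom = d1[j] - d2[j]
            if abs(denom) < _EPS:
                # segment parallel to (and in) the triangle plane
                if _coplanar_segment_hits_triangle(seg_a[j], seg_b[j], a, b, c, nrm):
                    out[k] = True
                    break
                continue
            t = d1[j] / denom
            x = seg_a[j] + t * (seg_b[j] - seg_a[j])
            # barycentric containment with a conservative margin
            v0, v1, v2 = c - a, b - a, x - a
            d00 = v0 @ v0; d01 = v0 @ v1; d11 = v1 @ v1
            d20 = v2 @ v0; d21 = v2 @ v1
            den = d00 * d11 - d01 * d01
            if abs(den) < 1e-15:
                out[k] = True
                break
            u = (d11 * d20 - d01 * d21) / den
            v = (d00 * d21 - d01 * d20) / den
            if u >= -1e-9 and v >= -1e-9 and u + v <= 1 + 1e-9:
                out[k] = True
                break
    return out


def _segment_hits_triangle(p: np.ndarray, q: np.ndarray,
                           a: np.ndarray, b: np.ndarray, c: np.ndarray) -> bool:
    """Conservative single segment vs triangle intersection test."""
    nrm = np.cross(b - a, c - a)
    area2 = np.linalg.norm(nrm)
    if area2 < 1e-12:
        return False
    nrm = nrm / area2
    d1 = float((p - a) @ nrm)
    d2 = float((q - a) @ nrm)
    if d1 * d2 > 1e-12:
        return False
    denom = d1 - d2
    if abs(denom) < _EPS:
        return _coplanar_segment_hits_triangle(p, q, a, b, c, nrm)
    t = d1 / denom
    x = p + t * (q - p)
    v0, v1, v2 = c - a, b - a, x - a
    d00 = v0 @ v0; d01 = v0 @ v1; d11 = v1 @ v1
    d20 = v2 @ v0; d21 = v2 @ v1
    den = d00 * d11 - d01 * d01
    if abs(den) < 1e-15:
        return True
    u = (d11 * d20 - d01 * d21) / den
    v = (d00 * d21 - d01 * d20) / den
    return u >= -1e-9 and v >= -1e-9 and u + v <= 1 + 1e-9


def kmt_reduce(points: np.ndarray, fixed_ends: bool = True) -> np.ndarray:
    """Reduce a polygonal curve by iterative triangle elimination.

    Vertex i is removed when the triangle (i-1, i, i+1) is not pierced
    by any other segment of the current curve; the move is a topology
    preserving deformation.  With ``fixed_ends`` the curve is open and
    its endpoints are never removed; otherwise the curve is treated as
    closed (cyclic neighbours).  Iterates to a fixed point.

    Removals within one pass are committed one at a time: a candidate
    whose triangle was vetted against the old segments is re-checked
    against the chords created by removals committed earlier in the
    same pass (a new chord may pierce a triangle the old segments
    missed), and skipped when a neighbour was already removed.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    closed = not fixed_ends
    while True:
        n = len(pts)
        if closed and n <= 3:
            break
        if not closed and n <= 2:
            break
        cand = np.arange(n) if closed else np.arange(1, n - 1)
        pierced = _triangles_pierced(pts, closed, cand)
        removable = cand[~pierced]
        if len(removable) == 0:
            break
        keep = np.ones(n, dtype=bool)
        new_chords: list[tuple[np.ndarray, np.ndarray]] = []
        removed_any = False
        removable_set = set(int(r) for r in removable)
        for i in sorted(removable_set):
            prev_i = (i - 1) % n
            next_i = (i + 1) % n
            # neighbours must be intact, or the vetted triangle is stale
            if not (keep[prev_i] and keep[next_i]):
                continue
            tri = (pts[prev_i], pts[i], pts[next_i])
            if any(_segment_hits_triangle(p, q, *tri) for p, q in new_chords):
                continue
            keep[i] = False
            removed_any = True
            new_chords.append((pts[prev_i], pts[next_i]))
        if not removed_any:
            break
        pts = pts[keep]
    return pts


# ---------------------------------------------------------------------------
# stochastic closure
# ---------------------------------------------------------------------------

def closure_point(coords: np.ndarray, rng: np.random.Generator,
                  radius_factor: float = CLOSURE_RADIUS_FACTOR) -> np.ndarray:
    """Uniformly random point on the closure sphere around a chain.

    The sphere is centred at the chain centroid with radius
    ``radius_factor`` times the maximal centroid-to-Cα distance, which
    keeps the closure arc well outside the structure.
    """
    centroid = coords.mean(axis=0)
    rmax = float(np.linalg.norm(coords - centroid, axis=1).max())
    if rmax < _EPS:
        raise ValueError("degenerate chain: all points coincide")
    u = rng.normal(size=3)
    nu = np.linalg.norm(u)
    while nu < _EPS:
        u = rng.normal(size=3)
        nu = np.linalg.norm(u)
    return centroid + (radius_factor * rmax / nu) * u


def random_closure(chain: BackboneChain | np.ndarray,
                   rng: np.random.Generator,
                   radius_factor: float = CLOSURE_RADIUS_FACTOR) -> ClosedCurve:
    """Close an open chain through one random point on the closure sphere.

    Appends the segments C-terminus -> sphere point -> N-terminus; the
    returned curve is implicitly closed.
    """
    coords = chain.coords if isinstance(chain, BackboneChain) else np.asarray(chain, float)
    if len(coords) < 3:
        raise ValueError("need at least 3 residues to close a chain")
    point = closure_point(coords, rng, radius_factor)
    return ClosedCurve(np.vstack([coords, point]))


def label_closed_curve(curve: ClosedCurve, rng: np.random.Generator,
                       crossing_cap: int = DEFAULT_CROSSING_CAP,
                       n_direction_retries: int = 3) -> KnotLabel:
    """Knot label of a closed curve: KMT reduction, projection, HOMFLY.

    Retries a few alternative projection directions on degenerate
    projections or crossing-cap overflows; if all fail the curve is
    labelled "other".
    """
    reduced = kmt_reduce(curve.vertices, fixed_ends=False)
    if len(reduced) <= 3:
        return UNKNOT
    small = ClosedCurve(reduced)
    for _ in range(1 + n_direction_retries):
        direction = rng.normal(size=3)
        try:
            return label_from_polynomial(
                homfly(project_to_diagram(small, direction), crossing_cap=crossing_cap)
            )
        except (DegenerateProjection, CrossingCapExceeded):
            continue
    return "other"


# ---------------------------------------------------------------------------
# dominant knot spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnotSpectrum:
    """Closure-frequency distribution over knot labels for one chain."""

    frequencies: Mapping[KnotLabel, float]
    n_closures: int
    dominant: KnotLabel
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", dict(self.frequencies))
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, expected 1")

    def frequency(self, label: KnotLabel) -> float:
        return self.frequencies.get(label, 0.0)

    @property
    def nontrivial_fraction(self) -> float:
        """Fraction of closures that formed any nontrivial knot."""
        return 1.0 - self.frequency(UNKNOT)

    @property
    def is_knotted(self) -> bool:
        """Nontrivial dominant type: knotted more often than trivial."""
        return self.dominant != UNKNOT


def _pick_dominant(counts: Mapping[KnotLabel, int]) -> KnotLabel:
    best = max(counts.values())
    tied = sorted(label for label, c in counts.items() if c == best)
    if UNKNOT in tied:
        return UNKNOT
    return tied[0]


def dominant_knot(chain: BackboneChain | np.ndarray,
                  n_closures: int = DEFAULT_N_CLOSURES,
                  seed: int = 0,
                  radius_factor: float = CLOSURE_RADIUS_FACTOR,
                  crossing_cap: int = DEFAULT_CROSSING_CAP) -> KnotSpectrum:
    """Dominant knot type of an open chain over random closures.

    Each closure gets its own RNG stream derived from (seed, closure
    index), so the spectrum is independent of evaluation order and
    bit-reproducible for a fixed seed.  The open chain is KMT-reduced
    once with fixed ends (a topology-preserving move for every closure,
    since the closure arc stays outside the structure); each closed
    curve is then reduced again in closed mode before projection.
    """
    if n_closures < 1:
        raise ValueError("n_closures must be >= 1")
    coords = chain.coords if isinstance(chain, BackboneChain) else np.asarray(chain, float)
    if len(coords) < 3:
        raise ValueError("need at least 3 residues")
    centroid = coords.mean(axis=0)
    rmax = float(np.linalg.norm(coords - centroid, axis=1).max())
    if rmax < _EPS:
        raise ValueError("degenerate chain: all points coincide")
    reduced_open = kmt_reduce(coords, fixed_ends=True)

    counts: dict[KnotLabel, int] = {}
    for i in range(n_closures):
        rng = np.random.default_rng((int(seed), i))
        point = closure_point(coords, rng, radius_factor)
        curve = ClosedCurve(np.vstack([reduced_open, point]))
        label = label_closed_curve(curve, rng, crossing_cap=crossing_cap)
        counts[label] = counts.get(label, 0) + 1
    freqs = {label: c / n_closures for label, c in counts.items()}
    return KnotSpectrum(freqs, n_closures, _pick_dominant(counts), int(seed))
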