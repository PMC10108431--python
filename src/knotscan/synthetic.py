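"""Synthetic backbone models with planted topology.

Generates single-chain Cα traces that emulate AlphaFold-style models:
a knotted (or unknotted) core with prescribed span, self-avoiding
random-walk tails of tunable length, Gaussian coordinate noise, and a
per-residue confidence (pLDDT) profile.  Geometry is idealised — bonds
rescaled to the Cα-Cα virtual bond length of 3.8 Å and a 4 Å minimum
separation between non-adjacent residues — with no secondary structure;
only the topology and the confidence structure of real models are
emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np

from .detection import UNKNOT as UNKNOT_LABEL, dominant_knot
from .invariants import ClosedCurve
from .structures_io import BackboneChain, write_synthetic_model

__all__ = [
    "SyntheticSpec",
    "PlddtProfile",
    "torus_knot_curve",
    "braid_closure_curve",
    "embed_as_backbone",
    "make_backbone",
    "random_coil",
    "slipknot_backbone",
    "emit_fixture_set",
    "BOND_LENGTH",
    "MIN_SEPARATION",
]

#: Cα-Cα virtual bond length (Å)
BOND_LENGTH = 3.8

#: minimum separation enforced between residues with |i - j| >= 3 (Å)
MIN_SEPARATION = 4.0

_MIN_SEP_SPAN = 3


@dataclass(frozen=True)
class PlddtProfile:
    """Confidence profile: uniform, or a distinct value over the core.

    ``low_core(40, 90)`` emulates an artifact whose knotted core sits in
    a low-confidence region; ``uniform(90)`` a well-predicted model.
    """

    core_value: float
    rest_value: float

    @classmethod
    def uniform(cls, value: float) -> "PlddtProfile":
        return cls(value, value)

    @classmethod
    def low_core(cls, core_value: float, rest_value: float) -> "PlddtProfile":
        return cls(core_value, rest_value)


#: core window sizes that give the knot tube enough clearance for a
#: 3.8 Å-bond, 4 Å self-avoiding backbone; more complex knots need more
#: residues to close at protein-like density
RECOMMENDED_CORE_LENGTH = {
    "0_1": 61, "3_1": 61, "4_1": 91, "5_1": 91, "5_2": 91,
    "6_1": 91, "6_2": 91, "6_3": 91, "7_1": 131, "3_1#3_1": 91,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic backbone with a planted knot."""

    knot: str = "3_1"
    n_tail: int = 10
    c_tail: int = 10
    core_length: int = 61
    noise_sd: float = 0.2
    plddt: PlddtProfile = field(default_factory=lambda: PlddtProfile.uniform(90.0))
    seed: int = 0

    @classmethod
    def for_knot(cls, knot: str, **kwargs) -> "SyntheticSpec":
        """Spec with the recommended core window for the knot type."""
        kwargs.setdefault("core_length", RECOMMENDED_CORE_LENGTH.get(knot, 91))
        return cls(knot=knot, **kwargs)

    @property
    def n_residues(self) -> int:
        return self.n_tail + self.core_length + self.c_tail

    @property
    def core_span(self) -> tuple[int, int]:
        """Embedded core window in 1-based residue numbering, inclusive.

        The minimal knotted subchain sits inside this window, usually a
        few residues short of it; see :func:`planted_core_span`.
        """
        return (self.n_tail + 1, self.n_tail + self.core_length)


# ---------------------------------------------------------------------------
# reference closed curves
# ---------------------------------------------------------------------------

def torus_knot_curve(p: int, q: int, n_vertices: int = 120,
                     R: float = 2.0, r: float = 1.0) -> ClosedCurve:
    """(p, q) torus knot sampled uniformly in parameter.

    Yields the 3_1 knot for (2, 3), 5_1 for (2, 5), 7_1 for (2, 7) and
    the unknot whenever min(|p|, |q|) == 1.
    """
    if p == 0 or q == 0 or math.gcd(abs(p), abs(q)) != 1:
        raise ValueError("p and q must be non-zero and coprime")
    if n_vertices < 3 * max(abs(p), abs(q)):
        raise ValueError("n_vertices too small to resolve the winding")
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    rad = R + r * np.cos(q * t)
    xyz = np.column_stack([rad * np.cos(p * t), rad * np.sin(p * t), r * np.sin(q * t)])
    return ClosedCurve(xyz)


#: braid words realised geometrically by braid_closure_curve; the same
#: validated words that generate the HOMFLY reference table
def braid_closure_curve(braid_word: Sequence[int],
                        n_vertices_per_crossing: int = 6,
                        validate: bool = True) -> ClosedCurve:
    """Piecewise-linear 3-D embedding of a braid closure.

    Strands run along +z at unit x-spacing; each braid letter swaps two
    adjacent strands with an over/under excursion in y.  Closure arcs
    return behind the braid (large negative y) in separate planes, so
    they add no crossings.  With ``validate`` the word must be one of
    the reference words (or a mirror/concatenation used by the
    generators); unvalidated words raise.
    """
    from .invariants import reference_braid_words, _SQUARE_KNOT_BRAID

    word = tuple(int(g) for g in braid_word)
    if not word or any(g == 0 for g in word):
        raise ValueError("braid word must be non-empty with non-zero letters")
    if validate:
        allowed = set(reference_braid_words().values()) | {_SQUARE_KNOT_BRAID}
        allowed |= {tuple(-g for g in w) for w in allowed}
        if word not in allowed:
            raise ValueError(
                f"braid word {word} is not in the validated reference list; "
                "pass validate=False only for internally generated words"
            )
    n = max(abs(g) for g in word) + 1
    dz = 1.3
    over_y, under_y = 1.0, -1.0

    pos = list(range(n))                      # strand at each x-position
    paths: dict[int, list[tuple[float, float, float]]] = {
        s: [(float(s), 0.0, 0.0)] for s in range(n)
    }
    z = 0.0
    for g in word:
        i = abs(g) - 1
        a, b = pos[i], pos[i + 1]
        ya, yb = (over_y, under_y) if g > 0 else (under_y, over_y)
        zm = z + 0.5 * dz
        z += dz
        paths[a].append((i + 0.5, ya, zm))
        paths[a].append((float(i + 1), 0.0, z))
        paths[b].append((i + 0.5, yb, zm))
        paths[b].append((float(i), 0.0, z))
        # uninvolved strands go straight
        for k in range(n):
            if k not in (a, b):
                paths[k].append((float(pos.index(k)), 0.0, z))
        pos[i], pos[i + 1] = b, a
    z_top = z + dz
    for s in range(n):
        paths[s].append((float(pos.index(s)), 0.0, z_top))

    # closure: from the top of each strand, swing behind the braid at a
    # strand-specific y-depth and come back to that strand's start
    pieces: list[np.ndarray] = []
    order: list[int] = []
    nxt = {pos[p]: p for p in range(n)}       # strand s continues as strand nxt[s]
    visited: set[int] = set()
    chains: list[list[int]] = []
    for s0 in range(n):
        if s0 in visited:
            continue
        cyc = []
        s = s0
        while s not in visited:
            visited.add(s)
            cyc.append(s)
            s = nxt[s]
        chains.append(cyc)
    if len(chains) != 1:
        raise ValueError("braid closure is a link, not a knot; unsupported here")
    cyc = chains[0]
    pts: list[tuple[float, float, float]] = []
    for s in cyc:
        pts.extend(paths[s])
        # return arc for strand s: it ended at x-position nxt-of-s
        end_x = float(pos.index(s))
        start_x = float(nxt[s])
        depth = -2.5 - 1.2 * s
        pts.append((end_x, depth, z_top))
        pts.append((start_x, depth, 0.0))
    curve = np.asarray(pts, dtype=float)
    # drop consecutive duplicates
    keep = [0]
    for i in range(1, len(curve)):
        if np.linalg.norm(curve[i] - curve[keep[-1]]) > 1e-9:
            keep.append(i)
    if np.linalg.norm(curve[keep[-1]] - curve[keep[0]]) < 1e-9:
        keep.pop()
    curve = curve[keep]
    if n_vertices_per_crossing > 6:
        curve = _resample_closed(curve, n_vertices_per_crossing * len(word))
    return ClosedCurve(curve)


def _resample_closed(vertices: np.ndarray, n_out: int) -> np.ndarray:
    """Arclength resampling of a closed polyline (keeps corners dense)."""
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.linspace(0.0, total, n_out, endpoint=False)
    out = np.empty((n_out, 3))
    j = 0
    for k, s in enumerate(targets):
        while cum[j + 1] < s:
            j += 1
        f = (s - cum[j]) / max(cum[j + 1] - cum[j], 1e-12)
        out[k] = closed[j] + f * (closed[j + 1] - closed[j])
    return out


def _resample_open(vertices: np.ndarray, n_out: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n_out)
    out = np.empty((n_out, 3))
    j = 0
    for k, s in enumerate(targets):
        while j < len(seg) - 1 and cum[j + 1] < s:
            j += 1
        f = (s - cum[j]) / max(cum[j + 1] - cum[j], 1e-12)
        out[k] = vertices[j] + f * (vertices[j + 1] - vertices[j])
    return out


def figure_eight_curve(n_vertices: int = 160) -> ClosedCurve:
    """Classic smooth parametrization of the figure-eight (4_1) knot."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    xyz = np.column_stack([
        (2.0 + np.cos(2 * t)) * np.cos(3 * t),
        (2.0 + np.cos(2 * t)) * np.sin(3 * t),
        np.sin(4 * t),
    ])
    return ClosedCurve(xyz)


# --- clearance-guarded relaxation of piecewise-linear braid closures ------
#
# Raw braid embeddings are far from "tube-like": their clearance-to-length
# ratio is too small to carry a 3.8 Å-bond backbone that stays 4 Å
# self-avoiding.  A short geometric equilibration fixes that: Laplacian
# smoothing plus segment-segment repulsion, with per-vertex displacement
# capped at 0.3x the current minimal segment clearance.  The cap makes a
# strand passage within one step geometrically impossible, so the knot
# type is preserved; the resulting label is verified by the invariant
# engine before the curve is trusted.

def _segment_clearance(v: np.ndarray):
    n = len(v)
    q = np.roll(v, -1, axis=0)
    I, J = np.triu_indices(n, 2)
    mask = ~((I == 0) & (J == n - 1))
    I, J = I[mask], J[mask]
    p1, q1, p2, q2 = v[I], q[I], v[J], q[J]
    d1 = q1 - p1; d2 = q2 - p2; r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    den = a * e - b * b
    s = np.where(den > 1e-12, np.clip((b * f - c * e) / np.where(den > 1e-12, den, 1), 0, 1), 0.0)
    t = (b * s + f) / np.where(e > 1e-12, e, 1)
    s = np.where(t < 0, np.clip(-c / np.where(a > 1e-12, a, 1), 0, 1),
                 np.where(t > 1, np.clip((b - c) / np.where(a > 1e-12, a, 1), 0, 1), s))
    t = np.clip(t, 0, 1)
    diff = p1 + s[:, None] * d1 - (p2 + t[:, None] * d2)
    dist = np.sqrt((diff ** 2).sum(1))
    return I, J, s, t, diff, dist


def _equilibrate_closed(v: np.ndarray, iters: int = 800) -> np.ndarray:
    v = v.copy()
    n = len(v)
    L0 = float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())
    for _ in range(iters):
        I, J, s, t, diff, dist = _segment_clearance(v)
        c0 = float(dist.min())
        mid = 0.5 * (np.roll(v, 1, axis=0) + np.roll(v, -1, axis=0))
        force = 0.3 * (mid - v)
        d_rep = max(1.6 * c0, 0.02 * L0)
        close = dist < d_rep
        if close.any():
            w = ((d_rep - dist[close]) / d_rep)[:, None]
            u = diff[close] / np.maximum(dist[close], 1e-9)[:, None]
            push = 0.25 * d_rep * w * u
            sc, tc = s[close], t[close]
            for k, (i, j) in enumerate(zip(I[close], J[close])):
                force[i] += push[k] * (1 - sc[k])
                force[(i + 1) % n] += push[k] * sc[k]
                force[j] -= push[k] * (1 - tc[k])
                force[(j + 1) % n] -= push[k] * tc[k]
        cap = 0.3 * c0
        nn = np.linalg.norm(force, axis=1)
        force *= np.minimum(1.0, cap / np.maximum(nn, 1e-12))[:, None]
        v2 = v + force
        L = float(np.linalg.norm(np.roll(v2, -1, axis=0) - v2, axis=1).sum())
        v2 *= L0 / L
        if float(_segment_clearance(v2)[5].min()) > 0.5 * c0:
            v = v2
    return v


#: seed curves for the tube relaxation; everything else comes from the
#: validated braid closures
_SEED_CURVES = {
    "3_1": lambda: torus_knot_curve(2, 3, 120),
    "4_1": lambda: figure_eight_curve(160),
    "5_1": lambda: torus_knot_curve(2, 5, 160),
    "7_1": lambda: torus_knot_curve(2, 7, 200),
}


@lru_cache(maxsize=None)
def _core_curve(knot: str) -> ClosedCurve:
    """Tight, self-avoiding closed curve of the requested knot type.

    Seed geometry (a torus-knot or figure-eight parametrization where
    one exists, a braid closure otherwise) is relaxed into a near-ideal
    tube by :func:`_equilibrate_closed`.  Tightness matters twice: it
    maximises the clearance available for a 3.8 Å-bond backbone, and it
    leaves no slack, so the minimal knotted subchain of the embedded
    backbone coincides with the planted core span.  The relaxed curve's
    type is verified by the invariant engine before use; knots whose
    embedding cannot be stabilised this way (7_2) are rejected.
    """
    if knot == UNKNOT_LABEL:
        return torus_knot_curve(1, 2, 60)
    if knot in _SEED_CURVES:
        raw = _SEED_CURVES[knot]().vertices
    else:
        from .invariants import reference_braid_words

        words = reference_braid_words()
        if knot not in words:
            raise ValueError(f"no generator for knot type {knot!r}")
        raw = braid_closure_curve(words[knot], n_vertices_per_crossing=10).vertices
    from .invariants import homfly_of_curve, label_from_polynomial

    relaxed = ClosedCurve(_equilibrate_closed(_resample_closed(raw, 80)))
    label = label_from_polynomial(
        homfly_of_curve(relaxed, np.random.default_rng(0x3E1A))
    )
    if label != knot:
        raise ValueError(
            f"no stable backbone embedding for {knot!r}: relaxation yielded "
            f"{label}; use braid_closure_curve for the closed-curve geometry"
        )
    return relaxed


# ---------------------------------------------------------------------------
# backbone embedding
# ---------------------------------------------------------------------------

def _min_separation_ok(coords: np.ndarray, min_sep: float = MIN_SEPARATION,
                       span: int = _MIN_SEP_SPAN) -> bool:
    n = len(coords)
    for i in range(n):
        d = np.linalg.norm(coords[i + span:] - coords[i], axis=1)
        if d.size and d.min() < min_sep:
            return False
    return True


def _grow_tail(start: np.ndarray, away_from: np.ndarray, n_steps: int,
               existing: np.ndarray, rng: np.random.Generator,
               max_attempts: int = 60) -> np.ndarray:
    """Self-avoiding escape-biased random-walk tail.

    Steps have length 3.8 Å along a fixed escape ray (pointing from the
    structure centroid through the chain end, jittered per tail) with
    per-step noise, so the tail leaves the knotted region instead of
    threading back through it; each step is rejected when it comes
    within 4 Å of any existing (non-adjacent) residue.
    """
    if n_steps == 0:
        return np.empty((0, 3))
    exit_dir = start - away_from
    nrm = np.linalg.norm(exit_dir)
    exit_dir = exit_dir / nrm if nrm > 1e-9 else rng.normal(size=3)
    exit_dir = exit_dir + rng.normal(scale=0.8, size=3)
    exit_dir /= np.linalg.norm(exit_dir)
    out: list[np.ndarray] = []
    pts = start.copy()
    for k in range(n_steps):
        placed = False
        for _ in range(max_attempts):
            step = exit_dir * 2.2 + rng.normal(scale=0.55, size=3)
            step = step / np.linalg.norm(step) * BOND_LENGTH
            cand = pts + step
            block = np.vstack([existing, np.asarray(out)]) if out else existing
            prior = block[:-_MIN_SEP_SPAN + 1] if len(block) > _MIN_SEP_SPAN - 1 else np.empty((0, 3))
            near = block[-(_MIN_SEP_SPAN - 1):] if len(block) else np.empty((0, 3))
            ok = True
            if len(prior):
                ok = np.linalg.norm(prior - cand, axis=1).min() >= MIN_SEPARATION
            if ok and len(near):
                # immediate neighbours only need to avoid overlap
                ok = np.linalg.norm(near - cand, axis=1).min() >= 1.5
            if ok:
                out.append(cand)
                pts = cand
                placed = True
                break
        if not placed:
            raise RuntimeError("tail growth failed to stay self-avoiding")
    return np.asarray(out)


_OPENED_CORE_CACHE: dict[tuple, np.ndarray] = {}


def _probe_seed(spec: "SyntheticSpec", attempt: int) -> int:
    return (int(spec.seed) * 7_919 + attempt * 104_729 + 17) % (2**31)


def _open_core(curve: ClosedCurve, knot: str, core_length: int) -> np.ndarray:
    """Open a closed knot into a deeply knotted chain of ``core_length`` Cαs.

    The closed curve is resampled to core_length + 1 vertices and every
    cut (dropping one vertex, so the termini sit two bonds apart) is
    screened by quick stochastic-closure typing; the first cut whose
    opened chain re-types as the planted knot in >= 90% of probe
    closures is kept.  Screening is deterministic and cached per
    (curve, knot, core_length) — planted core geometry is identical
    across backbone seeds.
    """
    from .detection import dominant_knot

    key = (hash(np.round(curve.vertices, 6).tobytes()), knot, core_length)
    hit = _OPENED_CORE_CACHE.get(key)
    if hit is not None:
        return hit
    closed = _resample_closed(curve.vertices, core_length + 1)
    mean_bond = float(np.linalg.norm(
        np.diff(np.vstack([closed, closed[:1]]), axis=0), axis=1).mean())
    closed = closed * (BOND_LENGTH / mean_bond)
    n = len(closed)
    best: tuple[float, np.ndarray] | None = None
    for k in range(n):
        rolled = np.roll(closed, -(k + 1), axis=0)
        opened = rolled[:-1]                 # drop the cut vertex
        if not _min_separation_ok(opened, MIN_SEPARATION + 0.2):
            continue
        spectrum = dominant_knot(opened, n_closures=20, seed=0x0C07)
        score = spectrum.frequency(knot)
        if best is None or score > best[0]:
            best = (score, opened)
        if score >= 0.9:
            break
    if best is None or best[0] < 0.9:
        got = f"{best[0]:.2f}" if best else "n/a"
        raise RuntimeError(
            f"no opening of the {knot} core at {core_length} residues stays "
            f"knotted under closure (best fraction {got}); use a longer core"
        )
    _OPENED_CORE_CACHE[key] = best[1]
    return best[1]


def embed_as_backbone(curve: ClosedCurve, spec: SyntheticSpec) -> BackboneChain:
    """Open a closed reference curve into a protein-like backbone.

    The curve is opened at a screened cut point (one that keeps the
    open chain deeply knotted), rescaled to 3.8 Å bonds at the requested
    core length, extended by self-avoiding random-walk tails, perturbed
    with Gaussian noise, and assigned the pLDDT profile.  Deterministic
    per (spec, seed); retries with derived sub-seeds when noise violates
    the 4 Å self-avoidance.
    """
    if spec.core_length < 3:
        raise ValueError("core_length must be >= 3")
    opened = _open_core(curve, spec.knot, spec.core_length)
    def _attach_tail(body: np.ndarray, n_steps: int, at_start: bool,
                     attempt: int, tries: int = 12) -> np.ndarray | None:
        """Grow one tail, re-drawing its escape direction until a quick
        closure probe confirms the planted knot survived (tails can
        thread back through the core and untie it)."""
        if n_steps == 0:
            return body
        for sub in range(tries):
            rng = np.random.default_rng(
                (int(spec.seed), 0xC0DE, attempt, int(at_start), sub)
            )
            anchor = body[::-1] if at_start else body
            try:
                tail = _grow_tail(anchor[-1], body.mean(axis=0), n_steps, anchor, rng)
            except RuntimeError:
                continue
            cand = np.vstack([tail[::-1], body]) if at_start else np.vstack([body, tail])
            if not _min_separation_ok(cand):
                continue
            probe = dominant_knot(
                cand, n_closures=20,
                seed=_probe_seed(spec, attempt * 31 + sub * 2 + int(at_start)),
            )
            if probe.dominant == spec.knot:
                return cand
        return None

    def _types_as_planted(points: np.ndarray, probe: int) -> bool:
        spectrum = dominant_knot(points, n_closures=20,
                                 seed=_probe_seed(spec, probe))
        return spectrum.dominant == spec.knot

    for attempt in range(20):
        rng = np.random.default_rng((int(spec.seed), 0xC0DE, attempt))
        core = opened + rng.normal(scale=spec.noise_sd, size=opened.shape)
        if not _min_separation_ok(core):
            continue
        # the noise itself must not degrade the planted core
        if not _types_as_planted(core, attempt * 977 + 1):
            continue
        coords = _attach_tail(core, spec.n_tail, True, attempt)
        if coords is None:
            continue
        coords = _attach_tail(coords, spec.c_tail, False, attempt)
        if coords is None:
            continue
        # tails must be removable: the knot lives in the core, not in a
        # tail that threaded a loop while preserving the overall type
        n_core_end = spec.n_tail + spec.core_length
        if spec.n_tail and not _types_as_planted(coords[spec.n_tail:],
                                                 attempt * 977 + 3):
            continue
        if spec.c_tail and not _types_as_planted(coords[:n_core_end],
                                                 attempt * 977 + 5):
            continue
        n = len(coords)
        s0, s1 = spec.core_span
        plddt = np.full(n, spec.plddt.rest_value, dtype=float)
        plddt[s0 - 1:s1] = spec.plddt.core_value
        return BackboneChain(
            chain_id="A",
            residue_numbers=np.arange(1, n + 1),
            coords=coords,
            plddt=plddt,
        )
    raise RuntimeError(
        f"could not embed a self-avoiding backbone for {spec} after repeated attempts"
    )


def make_backbone(spec: SyntheticSpec) -> BackboneChain:
    """Backbone with the planted knot type of ``spec`` (convenience)."""
    return embed_as_backbone(_core_curve(spec.knot), spec)


_PLANTED_SPAN_CACHE: dict[tuple[str, int], tuple[int, int]] = {}


def planted_core_span(spec: SyntheticSpec) -> tuple[int, int]:
    """Reference knot-core span of a planted backbone, in residue numbers.

    A chain opened from a closed tight knot always keeps a little slack
    near its termini (the closure re-completes a short arc), so the
    minimal knotted subchain is slightly smaller than the embedded core
    window.  The reference span is therefore measured once, on the
    clean opened core (no noise, no tails), with a fixed probe seed; it
    is deterministic per (knot, core_length) and shared by every seed of
    the same recipe.
    """
    from .fingerprint import fingerprint, knot_core

    key = (spec.knot, spec.core_length)
    hit = _PLANTED_SPAN_CACHE.get(key)
    if hit is None:
        opened = _open_core(_core_curve(spec.knot), spec.knot, spec.core_length)
        chain = BackboneChain(
            chain_id="A",
            residue_numbers=np.arange(1, len(opened) + 1),
            coords=opened,
            plddt=np.full(len(opened), 90.0),
        )
        fp = fingerprint(chain, coarse_step=10, closures_per_cell=40,
                         seed=0x5EED, n_closures_full=60)
        core = knot_core(fp, chain)
        hit = (core.start, core.end)
        _PLANTED_SPAN_CACHE[key] = hit
    return (hit[0] + spec.n_tail, hit[1] + spec.n_tail)


def random_coil(n_residues: int, seed: int = 0) -> BackboneChain:
    """Self-avoiding random walk with 3.8 Å steps (negative control).

    Short walks (n <= 150) are overwhelmingly unknotted.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng((int(seed), 0xC011))
    for _ in range(200):
        pts = [np.zeros(3)]
        ok = True
        for _ in range(n_residues - 1):
            placed = False
            for _ in range(80):
                step = rng.normal(size=3)
                step = step / np.linalg.norm(step) * BOND_LENGTH
                cand = pts[-1] + step
                arr = np.asarray(pts)
                prior = arr[:-_MIN_SEP_SPAN + 1] if len(arr) > _MIN_SEP_SPAN - 1 else None
                if prior is not None and len(prior) and \
                        np.linalg.norm(prior - cand, axis=1).min() < MIN_SEPARATION:
                    continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            coords = np.asarray(pts)
            return BackboneChain(
                chain_id="A",
                residue_numbers=np.arange(1, n_residues + 1),
                coords=coords,
                plddt=np.full(n_residues, 90.0),
            )
    raise RuntimeError("self-avoiding walk generation failed")


def slipknot_backbone(seed: int = 0, core_length: int = 61,
                      offset: float = 6.0) -> BackboneChain:
    """Chain whose subchain is trefoil-knotted while the whole is not.

    Built by following an open trefoil arc and then returning parallel
    to it at a fixed offset: the doubled arc bounds a thin ribbon, so
    the full chain closes to an unknot, while the subchain covering only
    the outbound arc keeps the trefoil.
    """
    rng = np.random.default_rng((int(seed), 0x511F))
    curve = torus_knot_curve(2, 3, 240)
    verts = curve.vertices
    centroid = verts.mean(axis=0)
    k = int(np.argmax(np.linalg.norm(verts - centroid, axis=1)))
    opened = np.roll(verts, -k - 1, axis=0)
    core = _resample_open(opened, core_length)
    mean_bond = float(np.linalg.norm(np.diff(core, axis=0), axis=1).mean())
    core = core * (BOND_LENGTH / mean_bond)
    # return path: offset copy of the arc, walked backwards; offset along
    # the local normal obtained by projecting the radial direction out of
    # the tangent
    centroid = core.mean(axis=0)
    tangents = np.gradient(core, axis=0)
    radial = core - centroid
    normal = radial - (np.sum(radial * tangents, axis=1, keepdims=True)
                       / np.maximum(np.sum(tangents * tangents, axis=1, keepdims=True), 1e-12)
                       ) * tangents
    nn = np.linalg.norm(normal, axis=1, keepdims=True)
    normal = normal / np.maximum(nn, 1e-9)
    ret = (core + offset * normal)[::-1]
    coords = np.vstack([core, ret])
    coords = coords + rng.normal(scale=0.05, size=coords.shape)
    n = len(coords)
    return BackboneChain(
        chain_id="A",
        residue_numbers=np.arange(1, n + 1),
        coords=coords,
        plddt=np.full(n, 90.0),
    )


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------

def emit_fixture_set(specs: Sequence[SyntheticSpec], out_dir: str | Path) -> Path:
    """Write one PDB per spec plus a manifest TSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["file\tknot\tcore_start\tcore_end\tn_tail\tc_tail\tplddt_core\tplddt_rest\tseed"]
    for i, spec in enumerate(specs):
        chain = make_backbone(spec)
        name = f"model_{i:03d}_{spec.knot.replace('#', 'x')}_s{spec.seed}.pdb"
        write_synthetic_model(chain, out_dir / name)
        s0, s1 = spec.core_span
        rows.append(
            f"{name}\t{spec.knot}\t{s0}\t{s1}\t{spec.n_tail}\t{spec.c_tail}"
            f"\t{spec.plddt.core_value:g}\t{spec.plddt.rest_value:g}\t{spec.seed}"
        )
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
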