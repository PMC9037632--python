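"""Curvilinear helical axis, global bending, kink geometry and the
COM-chord angular-change coordinate theta.

The axis is the polyline of per-step screw-decomposition foot points with
boxcar smoothing; the global bending angle is measured between the mean
axis directions of the first and last windows of the retained (terminal-
excluded) region; a kink is the best two-segment line fit of the axis
points, reported when it reduces the single-line residual by a fixed
fraction; theta is the angle between successive vectors joining the
heavy-atom centroids of consecutive base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import Frame, PairingMap, infer_pairing
from .geometry import angle_between, rotation_angle, rotation_axis, unit
from .io import Conformation, StructureError

__all__ = [
    "HelicalAxis",
    "BendingResult",
    "KinkResult",
    "ThetaProfile",
    "helical_axis",
    "bending_angle",
    "kink_angle",
    "theta_profile",
    "bend_category",
]

#: Bent-state categories: moderately (< 40 deg), strongly (40-50), extremely (> 50).
_CATEGORY_EDGES = (40.0, 50.0)


def bend_category(angle: float) -> str:
    if angle < _CATEGORY_EDGES[0]:
        return "moderate"
    if angle < _CATEGORY_EDGES[1]:
        return "strong"
    return "extreme"


@dataclass(frozen=True)
class HelicalAxis:
    """Curvilinear axis polyline.

    Raw per-step screw foot points/directions are stored; the public
    ``axis_points``/``axis_vectors`` views are boxcar-smoothed over
    ``smoothing_window``.  Restriction (terminal exclusion) slices the raw
    arrays *before* smoothing, so excluded terminal pairs can never leak
    into the retained region through the smoothing kernel.
    """

    raw_points: np.ndarray  # (n_steps, 3)
    raw_vectors: np.ndarray  # (n_steps, 3), unit
    smoothing_window: int

    def __len__(self) -> int:
        return len(self.raw_points)

    @property
    def axis_points(self) -> np.ndarray:
        return _boxcar(self.raw_points, self.smoothing_window)

    @property
    def axis_vectors(self) -> np.ndarray:
        v = _boxcar(self.raw_vectors, self.smoothing_window)
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def restrict(self, exclude_terminal_pairs: int) -> "HelicalAxis":
        """Drop axis steps that involve excluded terminal base pairs."""
        e = exclude_terminal_pairs
        n_pairs = len(self.raw_points) + 1
        lo, hi = e, (n_pairs - 1) - e  # step s (1-based) retained iff lo < s <= hi
        if hi - lo < 1:
            raise StructureError("helix too short after terminal exclusion")
        return HelicalAxis(
            raw_points=self.raw_points[lo:hi],
            raw_vectors=self.raw_vectors[lo:hi],
            smoothing_window=self.smoothing_window,
        )


@dataclass(frozen=True)
class BendingResult:
    bending_angle: float
    excluded_terminal_pairs: int
    category: str


@dataclass(frozen=True)
class KinkResult:
    kink_detected: bool
    kink_step: int
    kink_angle: float
    segment_axes: tuple[np.ndarray, np.ndarray]
    fit_residual_gain: float


@dataclass(frozen=True)
class ThetaProfile:
    theta: np.ndarray  # (n_pairs - 2,)
    com_points: np.ndarray  # (n_pairs, 3)


def _boxcar(arr: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return arr
    out = np.empty_like(arr)
    h = window // 2
    n = len(arr)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        out[i] = arr[lo:hi].mean(axis=0)
    return out


def helical_axis(frames: list[Frame], smoothing_window: int = 5) -> HelicalAxis:
    """Per-step local helix axis from the screw decomposition of consecutive
    pair frames; degenerate (near-zero-rotation) steps inherit neighboring
    directions."""
    if len(frames) < 4:
        raise StructureError("need at least 4 pair frames for a helical axis")
    n_steps = len(frames) - 1
    points = np.empty((n_steps, 3))
    vectors = np.full((n_steps, 3), np.nan)
    for s in range(n_steps):
        f1, f2 = frames[s], frames[s + 1]
        R = f2.rotation @ f1.rotation.T
        gamma = rotation_angle(R)
        mid = 0.5 * (f1.origin + f2.origin)
        if gamma < 0.5:  # degenerate: pure translation step
            points[s] = mid
            continue
        u = rotation_axis(R)
        if np.dot(u, f1.z + f2.z) < 0:
            u = -u
        d = f2.origin - R @ f1.origin
        d_perp = d - np.dot(d, u) * u
        p, *_ = np.linalg.lstsq(np.eye(3) - R, d_perp, rcond=None)
        p = p + np.dot(mid - p, u) * u  # foot point nearest the step midpoint
        points[s] = p
        vectors[s] = u
    # fill degenerate steps from nearest defined neighbors
    defined = np.isfinite(vectors[:, 0])
    if not np.any(defined):
        raise StructureError("all steps degenerate: no helical axis")
    idx = np.arange(n_steps)
    for k in idx[~defined]:
        near = idx[defined][np.argmin(np.abs(idx[defined] - k))]
        vectors[k] = vectors[near]
    return HelicalAxis(points, vectors, smoothing_window)


def bending_angle(
    axis: HelicalAxis, exclude_terminal: int = 5, window: int = 3
) -> BendingResult:
    """Global bending: angle between the mean axis directions over the first
    and last windows of the retained (terminal-excluded) region.

    The end directions average the raw per-step directions over an
    effective window of ``window + smoothing_window - 1`` steps — the raw
    support of a ``window`` mean of smoothed vectors — taken strictly
    inside the retained region, so excluded terminal pairs have exactly no
    influence."""
    restricted = axis.restrict(exclude_terminal) if exclude_terminal else axis
    v = restricted.raw_vectors
    if len(v) < 2 * window:
        raise StructureError("helix too short after terminal exclusion")
    w_eff = min(window + restricted.smoothing_window - 1, len(v) // 2)
    v1 = unit(v[:w_eff].mean(axis=0))
    v2 = unit(v[-w_eff:].mean(axis=0))
    ang = angle_between(v1, v2)
    return BendingResult(
        bending_angle=ang,
        excluded_terminal_pairs=exclude_terminal,
        category=bend_category(ang),
    )


def _line_fit_ss(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Sum of squared perpendicular distances to the best-fit 3D line."""
    center = points.mean(axis=0)
    X = points - center
    _, svals, Vt = np.linalg.svd(X, full_matrices=False)
    direction = Vt[0]
    ss = float(np.sum(svals[1:] ** 2))
    return ss, direction


def kink_angle(
    axis: HelicalAxis,
    min_segment: int = 4,
    residual_gain_threshold: float = 0.4,
    noise_floor: float = 0.5,
    max_segment_rms: float = 1.0,
) -> KinkResult:
    """Best two-segment partition of the axis polyline.

    A kink is reported when (a) the two-line fit reduces the single-line
    residual by at least ``residual_gain_threshold``, (b) the single-line
    RMS residual exceeds ``noise_floor`` (straight helices under coordinate
    noise otherwise trigger spurious detections), and (c) both segments are
    individually straight (RMS residual at most ``max_segment_rms``) —
    a continuously curved axis also gains from a two-segment fit, but its
    halves stay curved, which is exactly the bent/kinked distinction.
    The kink angle is the angle between the two segment directions, both
    oriented along the chain.
    """
    pts = axis.axis_points
    n = len(pts)
    if n < 10:
        raise StructureError("need at least 10 axis steps for kink analysis")
    ss1, dir1 = _line_fit_ss(pts)
    rms1 = float(np.sqrt(ss1 / n))
    best = None
    for k in range(min_segment, n - min_segment + 1):
        ssa, da = _line_fit_ss(pts[:k])
        ssb, db = _line_fit_ss(pts[k:])
        if best is None or ssa + ssb < best[0]:
            best = (ssa + ssb, k, da, db)
    ss2, split, da, db = best
    gain = 1.0 - ss2 / ss1 if ss1 > 0 else 0.0
    chain_dir_a = pts[split - 1] - pts[0]
    chain_dir_b = pts[-1] - pts[split]
    if np.dot(da, chain_dir_a) < 0:
        da = -da
    if np.dot(db, chain_dir_b) < 0:
        db = -db
    ang = angle_between(da, db)
    ssa, _ = _line_fit_ss(pts[:split])
    ssb, _ = _line_fit_ss(pts[split:])
    seg_rms = max(np.sqrt(ssa / split), np.sqrt(ssb / (n - split)))
    detected = (
        rms1 > noise_floor
        and gain >= residual_gain_threshold
        and seg_rms <= max_segment_rms
    )
    return KinkResult(
        kink_detected=bool(detected),
        kink_step=int(split),
        kink_angle=float(ang),
        segment_axes=(da, db),
        fit_residual_gain=float(gain),
    )


def theta_profile(c: Conformation, pm: PairingMap | None = None) -> ThetaProfile:
    """Angular change between successive base-pair centroid chord vectors."""
    if pm is None:
        pm = infer_pairing(c)
    n = pm.n_pairs
    if n < 3:
        raise StructureError("need at least 3 base pairs for a theta profile")
    arr = c.atoms
    coords = c.coords
    coms = np.empty((n, 3))
    for i, j, _ in pm.pairs:
        m = ((arr.chain_id == pm.chain_i) & (arr.res_id == i)) | (
            (arr.chain_id == pm.chain_ii) & (arr.res_id == j)
        )
        coms[i - 1] = coords[m].mean(axis=0)
    chords = np.diff(coms, axis=0)
    theta = np.array(
        [angle_between(chords[k], chords[k + 1]) for k in range(n - 2)]
    )
    return ThetaProfile(theta=theta, com_points=coms)
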